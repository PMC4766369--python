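"""Plane linear-elastic FEM for turgor-pressurized cell-wall sections.

Displacement finite elements on bilinear quadrilaterals with selective
reduced (mean-dilatation / B-bar) integration of the volumetric term, so
the quasi-incompressible wall (Poisson ratio 0.45) does not lock.  The
turgor load is a dead pressure applied to the lumen-facing wall surface of
the undeformed geometry; the inner periclinal wall is fully constrained by
default.

Unit system: lengths in μm, stresses and moduli in Pa, unit out-of-plane
thickness.  This is internally consistent for linear elasticity and makes
displacements come out directly in μm (forces carry units of Pa·μm²).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import PlanarMesh, _GAUSS_2x2, _dshape

__all__ = [
    "WallMaterial",
    "LoadCase",
    "FemSolution",
    "SingularSystemError",
    "assemble_system",
    "apply_pressure",
    "apply_edge_traction",
    "solve",
    "compute_stresses",
    "principal_stresses",
    "convergence_study",
    "quarter_annulus_mesh",
    "lame_radial_displacement",
]

BAR_TO_PA = 1e5


@dataclass(frozen=True)
class WallMaterial:
    """Isotropic linear-elastic wall material."""

    elastic_modulus: float  # Pa
    poisson_ratio: float

    def __post_init__(self) -> None:
        if not self.elastic_modulus > 0:
            raise ValueError("elastic_modulus must be > 0")
        if not 0 < self.poisson_ratio < 0.5:
            raise ValueError("poisson_ratio must lie in (0, 0.5)")

    def softened(self, factor: float) -> "WallMaterial":
        """Material with stiffness divided by ``factor`` (factor >= 1)."""
        if factor < 1:
            raise ValueError("softening factor must be >= 1")
        return WallMaterial(self.elastic_modulus / factor, self.poisson_ratio)

    def d_matrix(self, plane: str = "strain") -> np.ndarray:
        """3x3 constitutive matrix for (exx, eyy, gxy) -> (sxx, syy, txy)."""
        E, nu = self.elastic_modulus, self.poisson_ratio
        if plane == "strain":
            c = E / ((1 + nu) * (1 - 2 * nu))
            return c * np.array(
                [[1 - nu, nu, 0], [nu, 1 - nu, 0], [0, 0, (1 - 2 * nu) / 2]]
            )
        if plane == "stress":
            c = E / (1 - nu**2)
            return c * np.array([[1, nu, 0], [nu, 1, 0], [0, 0, (1 - nu) / 2]])
        raise ValueError(f"unknown plane assumption {plane!r}")


@dataclass
class LoadCase:
    """Turgor pressure plus kinematic constraints.

    ``pressure_edges`` are (element, local_edge) pairs on lumen-facing
    boundaries; ``constrained_nodes`` have both displacement components
    fixed; the per-axis sets allow symmetry conditions.
    """

    turgor_pressure: float  # Pa
    pressure_edges: np.ndarray
    constrained_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    fixed_x_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    fixed_y_nodes: np.ndarray = field(default_factory=lambda: np.empty(0, int))

    def __post_init__(self) -> None:
        if self.turgor_pressure < 0:
            raise ValueError("turgor_pressure must be >= 0")

    def fixed_dofs(self) -> np.ndarray:
        c = np.asarray(self.constrained_nodes, dtype=int)
        fx = np.asarray(self.fixed_x_nodes, dtype=int)
        fy = np.asarray(self.fixed_y_nodes, dtype=int)
        dofs = np.concatenate([2 * c, 2 * c + 1, 2 * fx, 2 * fy + 1])
        if dofs.size == 0:
            raise ValueError("load case fixes no degrees of freedom")
        return np.unique(dofs)


@dataclass
class FemSolution:
    """Nodal displacements with centroidal stresses and principal values."""

    displacements: np.ndarray  # (n_nodes, 2), μm
    element_stress: np.ndarray  # (n_elements, 3): sxx, syy, txy, Pa
    sigma1: np.ndarray  # max principal stress per element, Pa
    sigma2: np.ndarray
    residual: float
    reactions: np.ndarray  # (n_fixed_dofs,) forces at fixed dofs

    @property
    def max_displacement(self) -> float:
        return float(np.linalg.norm(self.displacements, axis=1).max())


class SingularSystemError(RuntimeError):
    """Stiffness is singular after constraints (unremoved rigid-body modes)."""


def _element_b_matrices(xy: np.ndarray):
    """B-bar strain-displacement matrices at the 2x2 Gauss points.

    Returns (Bbar[(4)](m,3,8), detJ[(4)](m,)) with the volumetric part of
    every B replaced by its centroid evaluation (mean dilatation).
    """
    m = xy.shape[0]

    def grads(xi, eta):
        dN = _dshape(xi, eta)
        J = np.einsum("eni,nj->eij", xy, dN)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        invJ = np.empty_like(J)
        invJ[:, 0, 0] = J[:, 1, 1]
        invJ[:, 1, 1] = J[:, 0, 0]
        invJ[:, 0, 1] = -J[:, 0, 1]
        invJ[:, 1, 0] = -J[:, 1, 0]
        invJ /= detJ[:, None, None]
        g = np.einsum("nj,eji->eni", dN, invJ)  # (m, 4, 2): dN/dx, dN/dy
        return g, detJ

    g0, _ = grads(0.0, 0.0)  # centroid gradients for the volumetric part

    out = []
    for xi, eta in _GAUSS_2x2:
        g, detJ = grads(xi, eta)
        B = np.zeros((m, 3, 8))
        gx, gy = g[..., 0], g[..., 1]
        g0x, g0y = g0[..., 0], g0[..., 1]
        cols_u = np.arange(0, 8, 2)
        cols_v = cols_u + 1
        # u_I columns
        B[:, 0, cols_u] = 0.5 * (gx + g0x)
        B[:, 1, cols_u] = 0.5 * (g0x - gx)
        B[:, 2, cols_u] = gy
        # v_I columns
        B[:, 0, cols_v] = 0.5 * (g0y - gy)
        B[:, 1, cols_v] = 0.5 * (gy + g0y)
        B[:, 2, cols_v] = gx
        out.append((B, detJ))
    return out


def _region_d_matrices(
    mesh: PlanarMesh, materials: dict[str, WallMaterial], plane: str
) -> np.ndarray:
    """(m, 3, 3) constitutive matrix per element."""
    missing = set(np.unique(mesh.region)) - set(materials)
    if missing:
        raise ValueError(f"no material for region(s): {sorted(missing)}")
    D = np.empty((mesh.n_elements, 3, 3))
    for name, mat in materials.items():
        D[mesh.region == name] = mat.d_matrix(plane)
    return D


def assemble_system(
    mesh: PlanarMesh,
    materials: dict[str, WallMaterial],
    plane: str = "strain",
) -> sp.csr_array:
    """Assemble the global stiffness (2n x 2n, symmetric)."""
    xy = mesh.element_coords()
    D = _region_d_matrices(mesh, materials, plane)
    Ke = np.zeros((mesh.n_elements, 8, 8))
    for B, detJ in _element_b_matrices(xy):
        if np.any(detJ <= 0):
            bad = int(np.flatnonzero(detJ <= 0)[0])
            raise ValueError(f"non-positive Jacobian in element {bad}")
        Ke += np.einsum("eki,ekl,elj,e->eij", B, D, B, detJ, optimize=True)

    dofs = np.empty((mesh.n_elements, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    n = 2 * mesh.n_nodes
    K = sp.coo_array((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()
    return K


def apply_pressure(
    mesh: PlanarMesh, edges: np.ndarray, pressure: float
) -> np.ndarray:
    """Consistent nodal forces for a uniform pressure on boundary edges.

    An edge of length L receives a total force ``pressure * L`` directed
    opposite its outward normal (from the pressurized side into the wall),
    split equally between its two nodes.
    """
    f = np.zeros(2 * mesh.n_nodes)
    if pressure == 0 or len(edges) == 0:
        return f
    pairs = mesh.edge_nodes(np.asarray(edges))
    p1, p2 = mesh.nodes[pairs[:, 0]], mesh.nodes[pairs[:, 1]]
    t = p2 - p1
    L = np.linalg.norm(t, axis=1)
    if np.any(L <= 0):
        raise ValueError("pressure boundary contains a zero-length edge")
    # outward normal of a CCW element edge
    normal = np.column_stack([t[:, 1], -t[:, 0]]) / L[:, None]
    fnode = -0.5 * pressure * L[:, None] * normal  # per node
    for col in range(2):
        np.add.at(f, 2 * pairs[:, col], fnode[:, 0])
        np.add.at(f, 2 * pairs[:, col] + 1, fnode[:, 1])
    return f


def apply_edge_traction(
    mesh: PlanarMesh, edges: np.ndarray, traction: np.ndarray
) -> np.ndarray:
    """Nodal forces for a uniform traction vector (Pa) on boundary edges."""
    f = np.zeros(2 * mesh.n_nodes)
    t = np.asarray(traction, dtype=float)
    pairs = mesh.edge_nodes(np.asarray(edges))
    p1, p2 = mesh.nodes[pairs[:, 0]], mesh.nodes[pairs[:, 1]]
    L = np.linalg.norm(p2 - p1, axis=1)
    for col in range(2):
        np.add.at(f, 2 * pairs[:, col], 0.5 * L * t[0])
        np.add.at(f, 2 * pairs[:, col] + 1, 0.5 * L * t[1])
    return f


def solve(
    mesh: PlanarMesh,
    materials: dict[str, WallMaterial],
    load: LoadCase,
    plane: str = "strain",
    extra_forces: np.ndarray | None = None,
) -> FemSolution:
    """Solve the constrained linear system and evaluate stresses.

    Raises :class:`SingularSystemError` when constraints leave rigid-body
    modes; checks the free-dof residual to 1e-8 relative.
    """
    K = assemble_system(mesh, materials, plane)
    f = apply_pressure(mesh, load.pressure_edges, load.turgor_pressure)
    if extra_forces is not None:
        f = f + extra_forces

    n = 2 * mesh.n_nodes
    fixed = load.fixed_dofs()
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)

    Kff = K[free][:, free].tocsc()
    u = np.zeros(n)
    with warnings.catch_warnings():
        warnings.simplefilter("error", spla.MatrixRankWarning)
        try:
            lu = spla.splu(Kff)
            uf = lu.solve(f[free])
        except (RuntimeError, spla.MatrixRankWarning) as exc:
            raise SingularSystemError(
                "stiffness singular after constraints (rigid-body-mode failure)"
            ) from exc
    if not np.all(np.isfinite(uf)):
        raise SingularSystemError("solver produced non-finite displacements")
    # self-equilibrated loads are consistent even for a rank-deficient
    # stiffness, so a successful factorization is not proof of a
    # well-posed problem: estimate the condition number explicitly
    inv_norm = spla.onenormest(
        spla.LinearOperator(
            Kff.shape,
            matvec=lu.solve,
            rmatvec=lambda x: lu.solve(x, trans="T"),
        )
    )
    cond_est = inv_norm * abs(Kff).sum(axis=0).max()
    if cond_est > 1e13:
        raise SingularSystemError(
            f"stiffness numerically singular (cond ~ {cond_est:.1e}): "
            "constraints leave rigid-body modes"
        )
    u[free] = uf

    fnorm = np.linalg.norm(f[free])
    resid = np.linalg.norm(Kff @ uf - f[free]) / (fnorm if fnorm > 0 else 1.0)
    if resid > 1e-8:
        raise SingularSystemError(f"linear solve residual {resid:.3e} > 1e-8")

    stress = compute_stresses(mesh, materials, u.reshape(-1, 2), plane)
    s1, s2 = principal_stresses(stress)
    reactions = (K @ u - f)[fixed]
    return FemSolution(
        displacements=u.reshape(-1, 2),
        element_stress=stress,
        sigma1=s1,
        sigma2=s2,
        residual=float(resid),
        reactions=reactions,
    )


def compute_stresses(
    mesh: PlanarMesh,
    materials: dict[str, WallMaterial],
    displacements: np.ndarray,
    plane: str = "strain",
) -> np.ndarray:
    """Centroidal stress (sxx, syy, txy) per element from the material law."""
    xy = mesh.element_coords()
    D = _region_d_matrices(mesh, materials, plane)
    dN = _dshape(0.0, 0.0)
    J = np.einsum("eni,nj->eij", xy, dN)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1]
    invJ[:, 1, 1] = J[:, 0, 0]
    invJ[:, 0, 1] = -J[:, 0, 1]
    invJ[:, 1, 0] = -J[:, 1, 0]
    invJ /= detJ[:, None, None]
    g = np.einsum("nj,eji->eni", dN, invJ)
    ue = displacements[mesh.elements]  # (m, 4, 2)
    exx = np.einsum("en,en->e", g[..., 0], ue[..., 0])
    eyy = np.einsum("en,en->e", g[..., 1], ue[..., 1])
    gxy = np.einsum("en,en->e", g[..., 1], ue[..., 0]) + np.einsum(
        "en,en->e", g[..., 0], ue[..., 1]
    )
    strain = np.column_stack([exx, eyy, gxy])
    return np.einsum("eij,ej->ei", D, strain)


def principal_stresses(stress: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(sigma1, sigma2) eigenvalues of each 2x2 stress tensor, sigma1 >= sigma2."""
    s = np.atleast_2d(stress)
    mean = 0.5 * (s[:, 0] + s[:, 1])
    rad = np.sqrt((0.5 * (s[:, 0] - s[:, 1])) ** 2 + s[:, 2] ** 2)
    return mean + rad, mean - rad


def convergence_study(run, h_values, metrics=("distension", "energy"),
                      rtol: float = 0.02):
    """Successive-refinement convergence table.

    ``run(h)`` must return a dict of scalar metrics.  Returns a pandas
    DataFrame with one row per h and relative changes between successive
    refinements; ``converged`` flags where every tracked change < rtol.
    """
    import pandas as pd

    hs = list(h_values)
    if len(hs) < 2:
        raise ValueError("need at least 2 mesh sizes")
    rows = []
    prev: dict | None = None
    for h in hs:
        vals = run(h)
        row = {"h": h, **vals}
        if prev is not None:
            changes = []
            for k in metrics:
                denom = abs(vals[k]) if vals[k] != 0 else 1.0
                change = abs(vals[k] - prev[k]) / denom
                row[f"delta_{k}"] = change
                changes.append(change)
            row["converged"] = all(c < rtol for c in changes)
        rows.append(row)
        prev = vals
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# thick-walled ring benchmark (closed-form validation target)

def lame_radial_displacement(
    r: np.ndarray, a: float, b: float, pressure: float,
    material: WallMaterial, plane: str = "strain",
) -> np.ndarray:
    """Closed-form radial displacement of a pressurized thick-walled cylinder.

    Internal pressure at r=a, traction-free at r=b.
    """
    E, nu = material.elastic_modulus, material.poisson_ratio
    r = np.asarray(r, dtype=float)
    c = pressure * a**2 / (b**2 - a**2)
    if plane == "strain":
        return (1 + nu) / E * c * ((1 - 2 * nu) * r + b**2 / r)
    return c / E * ((1 - nu) * r + (1 + nu) * b**2 / r)


def quarter_annulus_mesh(a: float, b: float, nr: int, ntheta: int) -> PlanarMesh:
    """Structured quad mesh of a quarter annulus in the first quadrant.

    Boundary sets: ``inner`` (r=a, pressurized) and ``outer`` (r=b); node
    sets for symmetry constraints are recovered by coordinate (y=0: fix
    u_y; x=0: fix u_x).
    """
    rr = np.linspace(a, b, nr + 1)
    tt = np.linspace(0.0, np.pi / 2, ntheta + 1)
    R, T = np.meshgrid(rr, tt, indexing="ij")
    nodes = np.column_stack([(R * np.cos(T)).ravel(), (R * np.sin(T)).ravel()])
    nid = lambda i, j: i * (ntheta + 1) + j
    I, J = np.meshgrid(np.arange(nr), np.arange(ntheta), indexing="ij")
    I, J = I.ravel(), J.ravel()
    elements = np.column_stack(
        [nid(I, J), nid(I + 1, J), nid(I + 1, J + 1), nid(I, J + 1)]
    ).astype(np.int64)
    region = np.full(elements.shape[0], "ring", dtype="U16")
    inner = np.flatnonzero(I == 0)
    outer = np.flatnonzero(I == nr - 1)
    boundary = {
        "inner": np.column_stack([inner, np.full(len(inner), 3)]),
        "outer": np.column_stack([outer, np.full(len(outer), 1)]),
    }
    return PlanarMesh(
        nodes=nodes, elements=elements, region=region,
        boundary_edges=boundary, h=(b - a) / nr, domain=None,
    )
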