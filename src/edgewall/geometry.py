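"""Idealized 2D cross-section of a file of root epidermal cells.

The modeled section is a row of rectangular cells whose walls form a
rectilinear frame: an outer periclinal wall (facing the organ surface), an
inner periclinal wall, and anticlinal walls shared between neighboring
cells.  Cell *vertices* -- the cross-sectional traces of geometric edges,
where an anticlinal wall meets a periclinal wall -- are identified as the
intersections of wall midlines, and a disc of configurable radius around
each vertex can be tagged as a distinct material region (the softened
domain).

All lengths are in micrometers.  The geometry is rectilinear by design, so
a boundary-conforming tensor-product grid meshes it exactly with linear
quadrilaterals and no geometric approximation error.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "REGION_VERTEX",
    "REGION_ANTICLINAL",
    "REGION_OUTER",
    "REGION_INNER",
    "CellRowSpec",
    "WallDomain",
    "PlanarMesh",
    "build_cell_row",
    "mesh_domain",
    "tag_vertex_regions",
    "min_scaled_jacobian",
]

REGION_VERTEX = "vertex"
REGION_ANTICLINAL = "anticlinal"
REGION_OUTER = "periclinal_outer"
REGION_INNER = "periclinal_inner"

#: (x0, y0, x1, y1) axis-aligned rectangle
Rect = tuple[float, float, float, float]

_TOL = 1e-9


@dataclass(frozen=True)
class CellRowSpec:
    """Dimensions of an idealized file of epidermal cells (μm).

    ``cell_width``/``cell_height`` are the outer envelope of a single cell;
    anticlinal walls between neighbors are shared, end walls sit just
    inside the envelope.
    """

    n_cells: int = 5
    cell_width: float = 20.0
    cell_height: float = 20.0
    outer_wall_thickness: float = 0.5
    anticlinal_wall_thickness: float = 0.3
    inner_wall_thickness: float = 0.3

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        t = {
            "cell_width": self.cell_width,
            "cell_height": self.cell_height,
            "outer_wall_thickness": self.outer_wall_thickness,
            "anticlinal_wall_thickness": self.anticlinal_wall_thickness,
            "inner_wall_thickness": self.inner_wall_thickness,
        }
        for name, v in t.items():
            if not v > 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        half_w, half_h = self.cell_width / 2, self.cell_height / 2
        for name in (
            "outer_wall_thickness",
            "anticlinal_wall_thickness",
            "inner_wall_thickness",
        ):
            v = getattr(self, name)
            if v >= half_w or v >= half_h:
                raise ValueError(
                    f"{name}={v} too thick for cell {self.cell_width}x"
                    f"{self.cell_height}: walls would self-intersect"
                )
        if self.inner_wall_thickness + self.outer_wall_thickness >= self.cell_height:
            raise ValueError("periclinal walls overlap: lumen height <= 0")

    @property
    def total_width(self) -> float:
        return self.n_cells * self.cell_width

    @property
    def thinnest_wall(self) -> float:
        return min(
            self.outer_wall_thickness,
            self.anticlinal_wall_thickness,
            self.inner_wall_thickness,
        )


@dataclass(frozen=True)
class WallDomain:
    """Watertight multi-rectangle wall domain with region labels.

    ``region_rects`` partitions the wall material; ``lumens`` holds one
    rectangle per cell interior.  Vertex points are midline intersections
    on the outer and inner periclinal walls.
    """

    spec: CellRowSpec
    region_rects: dict[str, tuple[Rect, ...]]
    lumens: tuple[Rect, ...]
    vertex_points_outer: np.ndarray  # (n_cells+1, 2)
    vertex_points_inner: np.ndarray
    bbox: Rect

    def region_area(self, region: str) -> float:
        return float(
            sum((x1 - x0) * (y1 - y0) for x0, y0, x1, y1 in self.region_rects[region])
        )

    @property
    def wall_area(self) -> float:
        return float(sum(self.region_area(r) for r in self.region_rects))

    @property
    def vertex_points(self) -> np.ndarray:
        """All vertex points, outer side first."""
        return np.vstack([self.vertex_points_outer, self.vertex_points_inner])


def build_cell_row(spec: CellRowSpec) -> WallDomain:
    """Construct the wall domain for a file of ``spec.n_cells`` cells.

    Interior anticlinal walls are centered on the shared cell boundary at
    ``x = k * cell_width``; the two end walls sit flush inside the outer
    envelope.  Vertex points are the intersections of anticlinal and
    periclinal wall midlines.
    """
    n = spec.n_cells
    W, H = spec.cell_width, spec.cell_height
    ta, ti, to = (
        spec.anticlinal_wall_thickness,
        spec.inner_wall_thickness,
        spec.outer_wall_thickness,
    )
    width = spec.total_width

    outer: tuple[Rect, ...] = ((0.0, H - to, width, H),)
    inner: tuple[Rect, ...] = ((0.0, 0.0, width, ti),)

    anticlinal: list[Rect] = []
    midlines: list[float] = []
    for j in range(n + 1):
        if j == 0:
            x0, x1 = 0.0, ta
        elif j == n:
            x0, x1 = width - ta, width
        else:
            x0, x1 = j * W - ta / 2, j * W + ta / 2
        anticlinal.append((x0, ti, x1, H - to))
        midlines.append((x0 + x1) / 2)

    lumens: list[Rect] = []
    for k in range(n):
        x0 = anticlinal[k][2]
        x1 = anticlinal[k + 1][0]
        if x1 - x0 <= 0:
            raise ValueError(
                f"invalid thickness combination: lumen {k} has width {x1 - x0}"
            )
        lumens.append((x0, ti, x1, H - to))

    mid = np.asarray(midlines)
    v_outer = np.column_stack([mid, np.full(n + 1, H - to / 2)])
    v_inner = np.column_stack([mid, np.full(n + 1, ti / 2)])

    return WallDomain(
        spec=spec,
        region_rects={
            REGION_OUTER: outer,
            REGION_INNER: inner,
            REGION_ANTICLINAL: tuple(anticlinal),
        },
        lumens=tuple(lumens),
        vertex_points_outer=v_outer,
        vertex_points_inner=v_inner,
        bbox=(0.0, 0.0, width, H),
    )


@dataclass
class PlanarMesh:
    """All-quad planar mesh with per-element region labels.

    Element node ordering is counterclockwise; local edge ``k`` connects
    local nodes ``k`` and ``(k + 1) % 4``.  Boundary edge sets map a set
    name to an ``(m, 2)`` integer array of ``(element, local_edge)`` pairs.
    """

    nodes: np.ndarray  # (n_nodes, 2) float64, μm
    elements: np.ndarray  # (n_elements, 4) int64, CCW
    region: np.ndarray  # (n_elements,) unicode
    boundary_edges: dict[str, np.ndarray] = field(default_factory=dict)
    h: float = 0.0
    domain: WallDomain | None = None

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elements(self) -> int:
        return self.elements.shape[0]

    def element_coords(self) -> np.ndarray:
        """(n_elements, 4, 2) nodal coordinates per element."""
        return self.nodes[self.elements]

    def element_centroids(self) -> np.ndarray:
        return self.element_coords().mean(axis=1)

    def element_areas(self) -> np.ndarray:
        """Shoelace area of every (convex, CCW) quad."""
        xy = self.element_coords()
        x, y = xy[..., 0], xy[..., 1]
        xn, yn = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return 0.5 * np.sum(x * yn - xn * y, axis=1)

    def region_elements(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)

    def region_area(self, region: str) -> float:
        return float(self.element_areas()[self.region == region].sum())

    def edge_nodes(self, edges: np.ndarray) -> np.ndarray:
        """(m, 2) global node pairs for (element, local_edge) pairs."""
        e, le = edges[:, 0], edges[:, 1]
        return np.column_stack(
            [self.elements[e, le], self.elements[e, (le + 1) % 4]]
        )

    def nodes_on_inner_wall(self) -> np.ndarray:
        """Node indices of the inner periclinal wall (fully constrained set)."""
        if self.domain is None:
            raise ValueError("mesh has no attached wall domain")
        ti = self.domain.spec.inner_wall_thickness
        mask = self.nodes[:, 1] <= ti + _TOL
        return np.flatnonzero(mask)

    def nodes_on_outer_surface(self) -> np.ndarray:
        """Node indices on the exterior face of the outer periclinal wall."""
        if self.domain is None:
            raise ValueError("mesh has no attached wall domain")
        H = self.domain.spec.cell_height
        return np.flatnonzero(np.abs(self.nodes[:, 1] - H) <= _TOL)


def _interval_breaks(faces: list[float], thick: list[tuple[float, float]],
                     h: float) -> np.ndarray:
    """Grid coordinates covering [faces[0], faces[-1]] with step <= h.

    Intervals listed in ``thick`` (wall thicknesses) get at least two
    subdivisions so every wall is at least two elements across.
    """
    faces = sorted(set(faces))
    coords = [faces[0]]
    for a, b in itertools.pairwise(faces):
        is_thick = any(a >= ta - _TOL and b <= tb + _TOL for ta, tb in thick)
        nsub = max(1, int(np.ceil((b - a) / h - 1e-9)))
        if is_thick:
            nsub = max(nsub, 2)
        coords.extend(np.linspace(a, b, nsub + 1)[1:])
    return np.asarray(coords)


def mesh_domain(domain: WallDomain, target_h: float) -> PlanarMesh:
    """Mesh the wall domain with linear quadrilaterals of size ~``target_h``.

    Because the domain is rectilinear, a tensor-product grid whose lines
    include every wall face meshes it exactly; grid cells falling in a
    lumen are dropped.  Guarantees at least two elements across each wall
    thickness and populates the ``lumen_pressure`` and ``exterior``
    boundary-edge sets.
    """
    spec = domain.spec
    if not target_h > 0:
        raise ValueError("target_h must be > 0")
    if target_h > spec.thinnest_wall + _TOL:
        raise ValueError(
            f"target_h={target_h} exceeds thinnest wall {spec.thinnest_wall}"
        )

    xf = [0.0, spec.total_width]
    x_thick: list[tuple[float, float]] = []
    for x0, _, x1, _ in domain.region_rects[REGION_ANTICLINAL]:
        xf += [x0, x1]
        x_thick.append((x0, x1))
    H, ti, to = spec.cell_height, spec.inner_wall_thickness, spec.outer_wall_thickness
    yf = [0.0, ti, H - to, H]
    y_thick = [(0.0, ti), (H - to, H)]

    gx = _interval_breaks(xf, x_thick, target_h)
    gy = _interval_breaks(yf, y_thick, target_h)
    nx, ny = len(gx) - 1, len(gy) - 1

    cx = 0.5 * (gx[:-1] + gx[1:])
    cy = 0.5 * (gy[:-1] + gy[1:])
    CX, CY = np.meshgrid(cx, cy, indexing="ij")  # (nx, ny)

    in_lumen = np.zeros((nx, ny), dtype=bool)
    for x0, y0, x1, y1 in domain.lumens:
        in_lumen |= (CX > x0) & (CX < x1) & (CY > y0) & (CY < y1)

    region = np.empty((nx, ny), dtype="U16")
    region[:] = REGION_ANTICLINAL
    region[CY > H - to] = REGION_OUTER
    region[CY < ti] = REGION_INNER

    keep = ~in_lumen
    # grid node ids on the (nx+1, ny+1) lattice
    nid = lambda i, j: i * (ny + 1) + j
    I, J = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    Ik, Jk = I[keep], J[keep]
    quads = np.column_stack(
        [nid(Ik, Jk), nid(Ik + 1, Jk), nid(Ik + 1, Jk + 1), nid(Ik, Jk + 1)]
    )
    used, inv = np.unique(quads, return_inverse=True)
    elements = inv.reshape(quads.shape).astype(np.int64)
    gi, gj = used // (ny + 1), used % (ny + 1)
    nodes = np.column_stack([gx[gi], gy[gj]])

    mesh = PlanarMesh(
        nodes=nodes,
        elements=elements,
        region=region[keep],
        h=float(target_h),
        domain=domain,
    )
    mesh.boundary_edges = _classify_boundary(mesh, domain)
    return mesh


def _classify_boundary(mesh: PlanarMesh, domain: WallDomain) -> dict[str, np.ndarray]:
    """Split boundary edges into lumen-facing and exterior sets."""
    elems = mesh.elements
    m = elems.shape[0]
    e_idx = np.repeat(np.arange(m), 4)
    le_idx = np.tile(np.arange(4), m)
    n1 = elems[e_idx, le_idx]
    n2 = elems[e_idx, (le_idx + 1) % 4]
    key = np.sort(np.column_stack([n1, n2]), axis=1)
    _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
    on_boundary = counts[inv] == 1

    be, ble = e_idx[on_boundary], le_idx[on_boundary]
    mids = 0.5 * (mesh.nodes[n1[on_boundary]] + mesh.nodes[n2[on_boundary]])

    on_lumen = np.zeros(len(be), dtype=bool)
    for x0, y0, x1, y1 in domain.lumens:
        inside = (
            (mids[:, 0] >= x0 - _TOL)
            & (mids[:, 0] <= x1 + _TOL)
            & (mids[:, 1] >= y0 - _TOL)
            & (mids[:, 1] <= y1 + _TOL)
        )
        edge = (
            (np.abs(mids[:, 0] - x0) < _TOL)
            | (np.abs(mids[:, 0] - x1) < _TOL)
            | (np.abs(mids[:, 1] - y0) < _TOL)
            | (np.abs(mids[:, 1] - y1) < _TOL)
        )
        on_lumen |= inside & edge

    pairs = np.column_stack([be, ble])
    return {
        "lumen_pressure": pairs[on_lumen],
        "exterior": pairs[~on_lumen],
    }


def tag_vertex_regions(
    mesh: PlanarMesh,
    vertex_points: np.ndarray,
    radius: float,
) -> PlanarMesh:
    """Label every element whose centroid lies within ``radius`` of a vertex.

    Returns a new mesh sharing node/element arrays; only the region array
    is replaced.  ``radius = 0`` tags nothing, a radius exceeding the
    domain diameter tags everything.
    """
    if radius < 0:
        raise ValueError("radius must be >= 0")
    vp = np.atleast_2d(np.asarray(vertex_points, dtype=float))
    cent = mesh.element_centroids()
    d2 = ((cent[:, None, :] - vp[None, :, :]) ** 2).sum(axis=2)
    within = (d2.min(axis=1) <= radius**2 + _TOL)
    region = mesh.region.copy()
    region[within] = REGION_VERTEX
    return PlanarMesh(
        nodes=mesh.nodes,
        elements=mesh.elements,
        region=region,
        boundary_edges=mesh.boundary_edges,
        h=mesh.h,
        domain=mesh.domain,
    )


# bilinear quad shape-function derivatives wrt (xi, eta) at a point
def _dshape(xi: float, eta: float) -> np.ndarray:
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [+(1 - eta), -(1 + xi)],
            [+(1 + eta), +(1 + xi)],
            [-(1 + eta), +(1 - xi)],
        ]
    )


_GAUSS_2x2 = [(-1 / np.sqrt(3), -1 / np.sqrt(3)), (1 / np.sqrt(3), -1 / np.sqrt(3)),
              (1 / np.sqrt(3), 1 / np.sqrt(3)), (-1 / np.sqrt(3), 1 / np.sqrt(3))]


def min_scaled_jacobian(mesh: PlanarMesh) -> float:
    """Smallest Jacobian determinant over all 2x2 Gauss points, scaled by
    element area; positive for a valid CCW quad mesh."""
    xy = mesh.element_coords()
    areas = mesh.element_areas()
    worst = np.inf
    for xi, eta in _GAUSS_2x2:
        dN = _dshape(xi, eta)  # (4, 2)
        J = np.einsum("eni,nj->eij", xy, dN)  # (m, 2, 2)
        detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
        worst = min(worst, float((detJ / (areas / 4.0)).min()))
    return worst
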