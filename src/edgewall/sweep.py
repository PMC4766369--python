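"""In-silico vertex-softening experiment on the pressurized cell file.

Sweeps the stiffness-reduction factor f and softened-disc radius r around
the cell vertices, solving the turgid wall section for each case, and
summarizes two readouts: radial distension of the outer periclinal wall
and the relocation of maximum principal stress between the vertex and
outer-face regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fem, geometry
from .geometry import REGION_OUTER, REGION_VERTEX, CellRowSpec, PlanarMesh
from .fem import FemSolution, LoadCase, WallMaterial

__all__ = [
    "SofteningSpec",
    "build_case",
    "radial_distension",
    "load_relocation",
    "run_sweep",
]


@dataclass(frozen=True)
class SofteningSpec:
    """Vertex softening: stiffness divisor ``factor`` applied within
    ``radius`` μm of each tagged vertex point."""

    factor: float = 1.0
    radius: float = 0.5
    sides: str = "outer"  # which vertices get softened: outer | inner | both

    def __post_init__(self) -> None:
        if self.factor < 1:
            raise ValueError("softening factor must be >= 1 (stiffness divisor)")
        if self.radius < 0:
            raise ValueError("softening radius must be >= 0")
        if self.sides not in ("outer", "inner", "both"):
            raise ValueError("sides must be one of outer|inner|both")


def _vertex_points(mesh: PlanarMesh, sides: str) -> np.ndarray:
    dom = mesh.domain
    if dom is None:
        raise ValueError("mesh has no attached wall domain")
    if sides == "outer":
        return dom.vertex_points_outer
    if sides == "inner":
        return dom.vertex_points_inner
    return dom.vertex_points


def build_case(
    spec: CellRowSpec,
    softening: SofteningSpec,
    target_h: float,
    pressure: float,
) -> tuple[PlanarMesh, LoadCase]:
    """Mesh the cell file, tag the softened vertex discs, and set up the
    turgor load with the inner periclinal wall fully constrained."""
    mesh = geometry.mesh_domain(geometry.build_cell_row(spec), target_h)
    mesh = geometry.tag_vertex_regions(
        mesh, _vertex_points(mesh, softening.sides), softening.radius
    )
    load = LoadCase(
        turgor_pressure=pressure,
        pressure_edges=mesh.boundary_edges["lumen_pressure"],
        constrained_nodes=mesh.nodes_on_inner_wall(),
    )
    return mesh, load


def radial_distension(sol: FemSolution, mesh: PlanarMesh) -> tuple[float, float]:
    """(max, mean) outward-normal displacement of the outer wall surface (μm).

    The outer periclinal surface of the cell file is its top face, so the
    outward normal is +y and the readout is the vertical displacement of
    the exterior surface nodes.
    """
    nodes = mesh.nodes_on_outer_surface()
    if nodes.size == 0:
        raise ValueError("outer-surface node set is empty")
    uy = sol.displacements[nodes, 1]
    return float(uy.max()), float(uy.mean())


def _region_mean_sigma1(sol: FemSolution, mesh: PlanarMesh, region: str) -> float:
    """Area-weighted mean maximum principal stress over a region."""
    idx = mesh.region == region
    if not idx.any():
        return float("nan")
    w = mesh.element_areas()[idx]
    return float(np.average(sol.sigma1[idx], weights=w))


def load_relocation(
    baseline: FemSolution, softened: FemSolution, mesh: PlanarMesh
) -> tuple[float, float]:
    """Change in area-weighted mean sigma1 in (vertex, outer-face) regions.

    Relocation of load from vertices to faces is confirmed when the first
    component is negative and the second positive.
    """
    if baseline.displacements.shape != softened.displacements.shape or (
        baseline.sigma1.shape != softened.sigma1.shape
    ):
        raise ValueError("solutions come from different meshes")
    dv = _region_mean_sigma1(softened, mesh, REGION_VERTEX) - _region_mean_sigma1(
        baseline, mesh, REGION_VERTEX
    )
    df = _region_mean_sigma1(softened, mesh, REGION_OUTER) - _region_mean_sigma1(
        baseline, mesh, REGION_OUTER
    )
    return dv, df


def run_sweep(
    spec: CellRowSpec,
    material: WallMaterial,
    pressure: float,
    factors=(1.0, 3.0, 10.0),
    radii=(0.5, 1.0),
    target_h: float = 0.1,
    plane: str = "strain",
    sides: str = "outer",
) -> pd.DataFrame:
    """Solve every (factor, radius) case and tabulate the readouts.

    A baseline row (factor 1) is always computed per radius; stress means
    are area-weighted; output ordering and values are deterministic.
    """
    factors = sorted(set(float(f) for f in factors) | {1.0})
    rows = []
    for r in radii:
        mesh, load = build_case(spec, SofteningSpec(1.0, r, sides), target_h, pressure)
        baseline = None
        for f in factors:
            materials = {
                name: material for name in (REGION_OUTER, geometry.REGION_INNER,
                                            geometry.REGION_ANTICLINAL)
            }
            materials[REGION_VERTEX] = material.softened(f)
            try:
                sol = fem.solve(mesh, materials, load, plane=plane)
            except fem.SingularSystemError as exc:
                raise RuntimeError(
                    f"sweep aborted: solve failed at factor={f}, radius={r}: {exc}"
                ) from exc
            if f == 1.0:
                baseline = sol
            dmax, dmean = radial_distension(sol, mesh)
            dsv, dsf = load_relocation(baseline, sol, mesh)
            rows.append(
                {
                    "factor": f,
                    "radius": r,
                    "max_distension": dmax,
                    "mean_distension": dmean,
                    "sigma1_vertex_mean": _region_mean_sigma1(sol, mesh, REGION_VERTEX),
                    "sigma1_face_mean": _region_mean_sigma1(sol, mesh, REGION_OUTER),
                    "delta_sigma1_vertex": dsv,
                    "delta_sigma1_face": dsf,
                    "n_elements": mesh.n_elements,
                }
            )
    return pd.DataFrame(rows)
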