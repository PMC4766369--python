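"""Mesh and solution export: legacy VTK ASCII and CSV pairs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PlanarMesh

__all__ = ["write_vtk", "write_mesh_csv"]

_REGION_CODES = {"periclinal_outer": 0, "periclinal_inner": 1,
                 "anticlinal": 2, "vertex": 3}


def write_vtk(
    path,
    mesh: PlanarMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the quad mesh as a legacy VTK unstructured grid (ASCII).

    2D points are padded with z = 0; vector point data with a third zero
    component.  The region label is always written as an integer cell
    field (see ``_REGION_CODES``; unknown regions get code -1).
    """
    n, m = mesh.n_nodes, mesh.n_elements
    lines = [
        "# vtk DataFile Version 3.0",
        "edgewall mesh",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for x, y in mesh.nodes:
        lines.append(f"{x:.10g} {y:.10g} 0")
    lines.append(f"CELLS {m} {5 * m}")
    for quad in mesh.elements:
        lines.append("4 " + " ".join(str(int(i)) for i in quad))
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["9"] * m)  # VTK_QUAD

    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, arr in point_data.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                lines.append(f"VECTORS {name} double")
                for row in arr:
                    vals = list(row) + [0.0] * (3 - len(row))
                    lines.append(" ".join(f"{v:.10g}" for v in vals))
            else:
                lines.append(f"SCALARS {name} double 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.10g}" for v in arr)

    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(_REGION_CODES.get(r, -1)) for r in mesh.region)
    for name, arr in (cell_data or {}).items():
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines.extend(f"{v:.10g}" for v in np.asarray(arr))

    Path(path).write_text("\n".join(lines) + "\n")


def write_mesh_csv(outdir, mesh: PlanarMesh) -> None:
    """Write nodes.csv (id, x, y) and elements.csv (id, n0..n3, region)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {"id": np.arange(mesh.n_nodes),
         "x": mesh.nodes[:, 0], "y": mesh.nodes[:, 1]}
    ).to_csv(outdir / "nodes.csv", index=False)
    pd.DataFrame(
        {
            "id": np.arange(mesh.n_elements),
            "n0": mesh.elements[:, 0],
            "n1": mesh.elements[:, 1],
            "n2": mesh.elements[:, 2],
            "n3": mesh.elements[:, 3],
            "region": mesh.region,
        }
    ).to_csv(outdir / "elements.csv", index=False)
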