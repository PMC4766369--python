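"""Plain-text key-value configuration for the mechanical model.

Schema (all keys optional; lengths in μm unless noted)::

    # geometry
    n_cells = 5
    cell_width = 20.0
    cell_height = 20.0
    outer_wall_thickness = 0.5
    anticlinal_wall_thickness = 0.3
    inner_wall_thickness = 0.3
    # material
    elastic_modulus_pa = 5e8
    poisson_ratio = 0.45
    # load
    turgor_pressure_bar = 5.0      # or turgor_pressure_pa
    # softening
    soften_factor = 1.0
    soften_radius = 0.5
    soften_sides = outer           # outer | inner | both
    # meshing
    target_h = 0.1

Lines starting with ``#`` and blank lines are ignored.
"""

from __future__ import annotations

from pathlib import Path

from .fem import BAR_TO_PA, WallMaterial
from .geometry import CellRowSpec
from .sweep import SofteningSpec

__all__ = ["parse_config", "spec_from_config", "material_from_config",
           "pressure_from_config", "softening_from_config"]

_GEOM_KEYS = {
    "n_cells": int,
    "cell_width": float,
    "cell_height": float,
    "outer_wall_thickness": float,
    "anticlinal_wall_thickness": float,
    "inner_wall_thickness": float,
}


def parse_config(path) -> dict:
    """Parse ``key = value`` lines into a dict of str/float/int values."""
    out: dict = {}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value', got {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        try:
            out[key] = int(val)
        except ValueError:
            try:
                out[key] = float(val)
            except ValueError:
                out[key] = val
    return out


def spec_from_config(cfg: dict) -> CellRowSpec:
    kwargs = {k: t(cfg[k]) for k, t in _GEOM_KEYS.items() if k in cfg}
    return CellRowSpec(**kwargs)


def material_from_config(cfg: dict) -> WallMaterial:
    return WallMaterial(
        elastic_modulus=float(cfg.get("elastic_modulus_pa", 5e8)),
        poisson_ratio=float(cfg.get("poisson_ratio", 0.45)),
    )


def pressure_from_config(cfg: dict) -> float:
    """Turgor pressure in Pa; bar keys are converted (1 bar = 1e5 Pa)."""
    if "turgor_pressure_pa" in cfg:
        return float(cfg["turgor_pressure_pa"])
    return float(cfg.get("turgor_pressure_bar", 5.0)) * BAR_TO_PA


def softening_from_config(cfg: dict) -> SofteningSpec:
    return SofteningSpec(
        factor=float(cfg.get("soften_factor", 1.0)),
        radius=float(cfg.get("soften_radius", 0.5)),
        sides=str(cfg.get("soften_sides", "outer")),
    )
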