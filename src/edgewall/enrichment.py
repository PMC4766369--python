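"""Shell-based edge-enrichment quantification and its ANOVA stage.

Implements the membrane-proximity enrichment readout used for
edge-clustered vesicle populations: each cell is cut into consecutive
2-μm sections parallel to its outer surface; within a section the voxels
are partitioned by 3D Euclidean distance to the plasma membrane into an
outer border (0-1 μm), inner border (1-2 μm), and interior; compartment
mean intensities are normalized by the section's total mean intensity to
give relative enrichments (voxel-weighted mean exactly 1 by construction).
Cell-level enrichments feed a two-way fixed-effects ANOVA (compartment x
treatment) with a Tukey HSD post hoc.

A companion statistic measures per-punctum distance to the cell periphery
and compares two markers by rank-sum test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = [
    "cell_distance_to_pm",
    "cut_sections",
    "shell_compartments",
    "relative_enrichment",
    "enrichment_table",
    "enrichment_anova",
    "puncta_periphery_distance",
    "compare_periphery_distributions",
    "detect_puncta",
]

COMPARTMENTS = ("outer_border", "inner_border", "interior")


def _cell_crop(labels: np.ndarray, cell_id: int):
    """(mask, slices) bounding-box crop of one cell, 1-voxel padded."""
    mask = labels == cell_id
    if not mask.any():
        raise ValueError(f"cell {cell_id} not present in label volume")
    objs = ndimage.find_objects(mask.astype(np.uint8))[0]
    slices = tuple(
        slice(max(s.start - 1, 0), min(s.stop + 1, n))
        for s, n in zip(objs, labels.shape)
    )
    return mask[slices], slices


def cell_distance_to_pm(
    labels: np.ndarray, voxel_size, cell_id: int
):
    """3D Euclidean distance of every cell voxel to the plasma membrane.

    Distance is computed from the cell's full 3D boundary (anything
    outside the cell counts as membrane-adjacent), with anisotropic voxel
    sampling.  Returns ``(dist, slices)`` on the cell's padded bounding
    box; voxels outside the cell hold 0.
    """
    dx, dy, dz = voxel_size
    mask, slices = _cell_crop(labels, cell_id)
    dist = ndimage.distance_transform_edt(mask, sampling=(dz, dy, dx))
    return dist, slices


def cut_sections(
    labels: np.ndarray,
    voxel_size,
    cell_id: int,
    n_sections: int = 3,
    thickness: float = 2.0,
) -> list[np.ndarray]:
    """Consecutive slab masks measured inward from the cell's outer surface.

    The outer surface is the cell face nearest the top of the volume
    (maximum z); section ``s`` collects cell voxels whose centers lie at
    depth [s*thickness, (s+1)*thickness) along -z.  Rejects cells
    shallower than ``n_sections * thickness``.
    """
    dx, dy, dz = voxel_size
    mask = labels == cell_id
    if not mask.any():
        raise ValueError(f"cell {cell_id} not present in label volume")
    zidx = np.flatnonzero(mask.any(axis=(1, 2)))
    z_top = (zidx.max() + 1) * dz  # upper face of the top voxel layer
    depth_extent = (zidx.max() - zidx.min() + 1) * dz
    required = n_sections * thickness
    if depth_extent + 1e-9 < required:
        raise ValueError(
            f"cell {cell_id} is {depth_extent:.2f} μm deep; "
            f"{required:.2f} μm required for {n_sections} sections"
        )
    zc = (np.arange(labels.shape[0]) + 0.5) * dz
    depth = z_top - zc  # depth of each z-layer's voxel centers
    sections = []
    for s in range(n_sections):
        in_band = (depth >= s * thickness) & (depth < (s + 1) * thickness)
        sec = mask & in_band[:, None, None]
        sections.append(sec)
    return sections


def shell_compartments(
    section_mask: np.ndarray,
    dist: np.ndarray,
    slices,
    bands: tuple[float, float] = (1.0, 2.0),
) -> dict[str, np.ndarray]:
    """Partition a section's cell voxels into PM-distance bands.

    ``dist``/``slices`` come from :func:`cell_distance_to_pm`.  Bands are
    outer border (0, b1], inner border (b1, b2], interior (b2, inf).
    """
    b1, b2 = bands
    d = np.zeros(section_mask.shape)
    d[slices] = dist
    sec = section_mask
    return {
        "outer_border": sec & (d > 0) & (d <= b1),
        "inner_border": sec & (d > b1) & (d <= b2),
        "interior": sec & (d > b2),
    }


def relative_enrichment(
    intensity: np.ndarray,
    section_mask: np.ndarray,
    compartments: dict[str, np.ndarray],
) -> list[dict]:
    """Per-compartment mean intensity normalized by the section mean.

    Rows for empty compartments carry NaN rather than a silent zero; the
    voxel-count-weighted mean of the reported enrichments equals 1 for any
    image.
    """
    sec_vals = intensity[section_mask]
    total_mean = float(sec_vals.mean()) if sec_vals.size else np.nan
    rows = []
    for name, m in compartments.items():
        n = int(m.sum())
        if n == 0 or total_mean == 0 or not np.isfinite(total_mean):
            mean_i, enr = np.nan, np.nan
        else:
            mean_i = float(intensity[m].mean())
            enr = mean_i / total_mean
        rows.append(
            {
                "compartment": name,
                "n_voxels": n,
                "mean_intensity": mean_i,
                "relative_enrichment": enr,
            }
        )
    return rows


def enrichment_table(
    intensity: np.ndarray,
    labels: np.ndarray,
    voxel_size,
    cell_ids=None,
    n_sections: int = 3,
    thickness: float = 2.0,
    bands: tuple[float, float] = (1.0, 2.0),
    treatment: str | None = None,
) -> pd.DataFrame:
    """Full enrichment table over cells and sections."""
    if cell_ids is None:
        cell_ids = np.unique(labels)
        cell_ids = cell_ids[cell_ids > 0]
    rows = []
    for cid in cell_ids:
        dist, slices = cell_distance_to_pm(labels, voxel_size, int(cid))
        sections = cut_sections(labels, voxel_size, int(cid), n_sections, thickness)
        for s, sec in enumerate(sections, start=1):
            comps = shell_compartments(sec, dist, slices, bands)
            for row in relative_enrichment(intensity, sec, comps):
                rows.append({"cell_id": int(cid), "section": s, **row})
    df = pd.DataFrame(rows)
    if treatment is not None:
        df["treatment"] = treatment
    return df


def enrichment_anova(table: pd.DataFrame, value_col: str = "relative_enrichment"):
    """Two-way fixed-effects ANOVA (compartment x treatment) + Tukey HSD.

    Cells are the replicate unit: section values are averaged per
    (treatment, cell, compartment) before the fit.  Raises on designs with
    empty factor combinations, listing the missing ones.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    if "treatment" not in table.columns:
        raise ValueError("table needs a 'treatment' column (>= 2 levels)")
    cells = (
        table.dropna(subset=[value_col])
        .groupby(["treatment", "cell_id", "compartment"], as_index=False)[value_col]
        .mean()
    )
    treatments = cells["treatment"].unique()
    comps = cells["compartment"].unique()
    if len(treatments) < 2 or len(comps) < 2:
        raise ValueError("need >= 2 treatments and >= 2 compartments")
    missing = [
        (t, c)
        for t in treatments
        for c in comps
        if not ((cells["treatment"] == t) & (cells["compartment"] == c)).any()
    ]
    if missing:
        raise ValueError(f"empty factor combinations: {missing}")

    model = smf.ols(
        f"{value_col} ~ C(compartment) * C(treatment)", data=cells
    ).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    group = cells["treatment"] + ":" + cells["compartment"]
    tukey = pairwise_tukeyhsd(cells[value_col].to_numpy(), group.to_numpy())
    tukey_df = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    )
    return {"anova": anova, "tukey": tukey_df, "cell_means": cells}


def puncta_periphery_distance(
    labels: np.ndarray,
    voxel_size,
    centers: np.ndarray,
    cell_ids: np.ndarray,
) -> np.ndarray:
    """Distance (μm) of each punctum center to the nearest PM voxel center.

    PM voxels are cell voxels adjacent to non-cell voxels (6-neighborhood)
    of the punctum's own cell.
    """
    dx, dy, dz = voxel_size
    centers = np.atleast_2d(centers)
    out = np.full(len(centers), np.nan)
    for cid in np.unique(cell_ids):
        mask, slices = _cell_crop(labels, int(cid))
        interior = ndimage.binary_erosion(mask)
        pm = mask & ~interior
        zz, yy, xx = np.nonzero(pm)
        pm_xyz = np.column_stack(
            [
                (xx + slices[2].start + 0.5) * dx,
                (yy + slices[1].start + 0.5) * dy,
                (zz + slices[0].start + 0.5) * dz,
            ]
        )
        tree = cKDTree(pm_xyz)
        sel = cell_ids == cid
        d, _ = tree.query(centers[sel])
        out[sel] = d
    return out


def compare_periphery_distributions(d1: np.ndarray, d2: np.ndarray) -> dict:
    """Summary quantiles and rank-sum comparison of two distance samples."""
    d1 = np.asarray(d1)[np.isfinite(np.asarray(d1, dtype=float))]
    d2 = np.asarray(d2)[np.isfinite(np.asarray(d2, dtype=float))]
    if len(d1) == 0 or len(d2) == 0:
        return {"n1": len(d1), "n2": len(d2), "p_value": np.nan,
                "median1": np.nan, "median2": np.nan}
    stat, p = stats.mannwhitneyu(d1, d2, alternative="two-sided")
    q = (0.25, 0.5, 0.75)
    return {
        "n1": len(d1),
        "n2": len(d2),
        "median1": float(np.median(d1)),
        "median2": float(np.median(d2)),
        "quantiles1": tuple(float(v) for v in np.quantile(d1, q)),
        "quantiles2": tuple(float(v) for v in np.quantile(d2, q)),
        "statistic": float(stat),
        "p_value": float(p),
    }


def detect_puncta(
    intensity: np.ndarray,
    background_mask: np.ndarray,
    voxel_size,
    k: float = 2.0,
    min_distance: int = 2,
) -> np.ndarray:
    """Local-maximum punctum detection above mean background + k*SD.

    Returns detected centers in (x, y, z) μm.
    """
    from skimage.feature import peak_local_max

    bg = intensity[background_mask]
    thresh = float(bg.mean() + k * bg.std())
    peaks = peak_local_max(
        intensity, min_distance=min_distance, threshold_abs=thresh
    )
    dx, dy, dz = voxel_size
    return np.column_stack(
        [
            (peaks[:, 2] + 0.5) * dx,
            (peaks[:, 1] + 0.5) * dy,
            (peaks[:, 0] + 0.5) * dz,
        ]
    )
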