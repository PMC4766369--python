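"""Reciprocal thresholded colocalization and the 2x2 specificity test.

Colocalization follows the SD-thresholded, Manders-style voxel-overlap
procedure: a channel's signal mask is everything brighter than the mean
background plus k standard deviations (k = 1 or 2), and per cell the
fraction of channel-A signal voxels overlapping channel-B's mask is
reported together with its reciprocal.  An object-based mode (fraction of
discrete puncta whose footprint touches the other mask) is provided as an
alternative readout.

The specificity of a phenotype across transgenic lines is tested with
Fisher's exact test computed by full hypergeometric enumeration over all
2x2 tables with the observed margins; the two-sided p-value sums the
probabilities of tables no more probable than the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "ColocResult",
    "FisherResult",
    "threshold_mask",
    "reciprocal_coloc",
    "object_coloc",
    "fisher_exact",
]


def threshold_mask(
    intensity: np.ndarray, background_mask: np.ndarray, k: float
) -> np.ndarray:
    """Signal mask: voxels brighter than mean(background) + k * SD(background)."""
    bg = intensity[background_mask]
    if bg.size == 0:
        raise ValueError("background region is empty")
    sd = float(bg.std())
    if sd == 0:
        warnings.warn("zero-variance background; thresholding at the mean only")
    return intensity > float(bg.mean()) + k * sd


@dataclass
class ColocResult:
    """Per-cell reciprocal overlap fractions plus group summary."""

    threshold_k: float
    per_cell: pd.DataFrame  # cell_id, frac_a_in_b, frac_b_in_a, n_a, n_b
    mean_a_in_b: float
    sd_a_in_b: float
    mean_b_in_a: float
    sd_b_in_a: float


def reciprocal_coloc(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    labels: np.ndarray,
    threshold_k: float = np.nan,
) -> ColocResult:
    """Voxel-overlap colocalization per cell: |A∩B|/|A| and |A∩B|/|B|.

    Cells where a channel has no signal voxels report NaN for the
    undefined fraction rather than zero.
    """
    if mask_a.shape != mask_b.shape or mask_a.shape != labels.shape:
        raise ValueError("channel masks and labels must share a shape")
    rows = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        cell = labels == cid
        na = int((mask_a & cell).sum())
        nb = int((mask_b & cell).sum())
        nab = int((mask_a & mask_b & cell).sum())
        rows.append(
            {
                "cell_id": int(cid),
                "n_a": na,
                "n_b": nb,
                "n_overlap": nab,
                "frac_a_in_b": nab / na if na else np.nan,
                "frac_b_in_a": nab / nb if nb else np.nan,
            }
        )
    df = pd.DataFrame(rows)
    return ColocResult(
        threshold_k=threshold_k,
        per_cell=df,
        mean_a_in_b=float(df["frac_a_in_b"].mean()),
        sd_a_in_b=float(df["frac_a_in_b"].std(ddof=1)),
        mean_b_in_a=float(df["frac_b_in_a"].mean()),
        sd_b_in_a=float(df["frac_b_in_a"].std(ddof=1)),
    )


def object_coloc(
    mask_a: np.ndarray, mask_b: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Object-based alternative: fraction of discrete channel-A objects per
    cell whose footprint overlaps the channel-B mask, and the reciprocal."""
    if mask_a.shape != mask_b.shape or mask_a.shape != labels.shape:
        raise ValueError("channel masks and labels must share a shape")
    rows = []
    for cid in np.unique(labels):
        if cid == 0:
            continue
        cell = labels == cid

        def frac(src, other):
            lab, n = ndimage.label(src & cell)
            if n == 0:
                return np.nan, 0
            hits = np.unique(lab[(lab > 0) & other])
            return len(hits) / n, n

        fa, na = frac(mask_a, mask_b)
        fb, nb = frac(mask_b, mask_a)
        rows.append(
            {
                "cell_id": int(cid),
                "n_objects_a": na,
                "n_objects_b": nb,
                "frac_objects_a_in_b": fa,
                "frac_objects_b_in_a": fb,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class FisherResult:
    """Exact-test output for a 2x2 table (rows: groups, cols: phenotype)."""

    p_one_sided_greater: float  # association at least as strong toward cell a
    p_one_sided_less: float
    p_two_sided: float
    odds_ratio: float


def fisher_exact(a: int, b: int, c: int, d: int) -> FisherResult:
    """Fisher's exact test by hypergeometric enumeration with fixed margins.

    Enumerates every admissible table with the observed row/column sums;
    the two-sided p sums probabilities of tables no more probable than the
    observed one (minimum-likelihood rule).  Degenerate margins give p = 1
    with a warning.
    """
    table = np.array([a, b, c, d])
    if np.any(table < 0) or np.any(table != np.floor(table)):
        raise ValueError("counts must be non-negative integers")
    a, b, c, d = (int(v) for v in table)
    N = a + b + c + d
    row1, col1 = a + b, a + c
    if N == 0 or row1 in (0, N) or col1 in (0, N):
        warnings.warn("degenerate margin: test is uninformative, p = 1")
        return FisherResult(1.0, 1.0, 1.0, np.nan)

    lo = max(0, col1 - (c + d))
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, N, row1, col1)
    p_obs = pmf[support == a][0]
    p_greater = float(pmf[support >= a].sum())
    p_less = float(pmf[support <= a].sum())
    p_two = float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())
    odds = (a * d) / (b * c) if b * c > 0 else np.inf
    return FisherResult(
        p_one_sided_greater=min(p_greater, 1.0),
        p_one_sided_less=min(p_less, 1.0),
        p_two_sided=min(p_two, 1.0),
        odds_ratio=float(odds),
    )
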