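"""Segmentation evaluation: Dice, HD95 on true-positive components, and
paired Wilcoxon signed-rank testing with Bonferroni correction.

HD95 convention (frozen for reproducibility): a mask's surface is the set
of mask voxels removed by a 6-connectivity erosion (voxels on the array
edge count as surface); distances are Euclidean distances between surface
voxel *centers* in mm, via the per-axis spacing; the statistic is the 95th
percentile (linear interpolation) of the pooled set of nearest-surface
distances taken in both directions.

Because a segmentation of many small targets is dominated by distant false
positives, HD95 is additionally offered restricted to *true-positive
components*: predicted 26-connected components that overlap the ground
truth by at least one voxel.  If no component overlaps, the distance is
undefined (NaN) rather than infinite, and aggregation reports how many
cases were undefined.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .geometry import ContractError
from .pipeline import DataError

__all__ = [
    "SegScore",
    "dice",
    "hd95",
    "hd95_tp_components",
    "wilcoxon_signed_rank",
    "bonferroni",
    "summarize_scores",
]


@dataclass
class SegScore:
    """Per-case evaluation record; ``hd95`` is NaN when undefined."""

    case_id: str
    dice: float
    hd95: float

    @property
    def hd95_defined(self) -> bool:
        return not math.isnan(self.hd95)


def _check_masks(pred, gt) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred).astype(bool)
    gt = np.asarray(gt).astype(bool)
    if pred.shape != gt.shape:
        raise ContractError(f"mask shapes differ: pred {pred.shape} vs gt {gt.shape}")
    return pred, gt


def dice(pred, gt) -> float:
    """Dice overlap 2|P∩G| / (|P|+|G|); 1.0 when both masks are empty."""
    pred, gt = _check_masks(pred, gt)
    total = int(pred.sum()) + int(gt.sum())
    if total == 0:
        return 1.0
    return 2.0 * int(np.logical_and(pred, gt).sum()) / total


def _surface_coords(mask: np.ndarray, spacing: np.ndarray) -> np.ndarray:
    """mm coordinates of border voxels (mask minus 6-connectivity erosion)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    border = mask & ~interior
    return np.argwhere(border) * spacing


def hd95(pred, gt, spacing) -> float:
    """95th-percentile symmetric surface distance in mm; NaN if a mask is empty."""
    pred, gt = _check_masks(pred, gt)
    spacing = np.asarray(spacing, dtype=float).reshape(pred.ndim)
    if not pred.any() or not gt.any():
        warnings.warn("hd95 undefined: empty mask", UserWarning, stacklevel=2)
        return math.nan
    a = _surface_coords(pred, spacing)
    b = _surface_coords(gt, spacing)
    d_ab = cKDTree(b).query(a, k=1)[0]
    d_ba = cKDTree(a).query(b, k=1)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def hd95_tp_components(pred, gt, spacing) -> float:
    """HD95 between ground truth and the union of true-positive components.

    Predicted 26-connected components with at least one overlapping voxel
    are kept; the rest (pure false positives) are discarded before the
    distance is computed.  Returns NaN when nothing overlaps.
    """
    pred, gt = _check_masks(pred, gt)
    if not gt.any():
        raise DataError("hd95_tp_components requires a non-empty ground truth")
    structure = np.ones((3,) * pred.ndim, dtype=bool)  # 26-connectivity in 3D
    labels, n_comp = ndimage.label(pred, structure=structure)
    if n_comp == 0:
        warnings.warn("hd95 undefined: empty prediction", UserWarning, stacklevel=2)
        return math.nan
    overlapping = np.unique(labels[gt & (labels > 0)])
    if overlapping.size == 0:
        warnings.warn(
            "hd95 undefined: no predicted component overlaps ground truth",
            UserWarning,
            stacklevel=2,
        )
        return math.nan
    tp_union = np.isin(labels, overlapping)
    return hd95(tp_union, gt, spacing)


# ---------------------------------------------------------------------------
# paired significance testing
# ---------------------------------------------------------------------------

_EXACT_MAX_N = 15


def _exact_two_sided_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided p by enumerating all 2^n sign assignments of the ranks."""
    n = ranks.size
    signs = (np.arange(2**n)[:, None] >> np.arange(n)[None, :]) & 1
    w_dist = signs @ ranks
    p_le = np.count_nonzero(w_dist <= w_plus + 1e-12) / 2**n
    p_ge = np.count_nonzero(w_dist >= w_plus - 1e-12) / 2**n
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(paired_a: Sequence[float], paired_b: Sequence[float]) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value for a vs b.

    Zero differences are dropped.  With n <= 15 remaining pairs the null
    distribution is enumerated exactly over all sign assignments (average
    ranks, so ties are handled); larger n uses the tie-corrected normal
    approximation.  All differences zero degenerates to p = 1 with a
    warning.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError(f"paired samples must be equal-length 1D, got {a.shape} vs {b.shape}")
    diff = a - b
    diff = diff[diff != 0]
    n = diff.size
    if n == 0:
        warnings.warn("all paired differences are zero; p = 1", UserWarning, stacklevel=2)
        return 1.0
    if n < 5:
        raise DataError(f"need >= 5 non-zero paired differences, got {n}")
    if n <= _EXACT_MAX_N:
        ranks = stats.rankdata(np.abs(diff))
        w_plus = float(ranks[diff > 0].sum())
        return _exact_two_sided_p(ranks, w_plus)
    res = stats.wilcoxon(diff, zero_method="wilcox", alternative="two-sided", mode="approx")
    return float(res.pvalue)


def bonferroni(p_values: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Multiply each p-value by the number of comparisons ``m``, cap at 1."""
    p = list(p_values)
    if m is None:
        m = len(p)
    if m < len(p):
        raise DataError(f"m = {m} is smaller than the number of p-values ({len(p)})")
    for v in p:
        if not 0.0 <= v <= 1.0:
            raise DataError(f"p-value {v} outside [0, 1]")
    return [min(1.0, v * m) for v in p]


def summarize_scores(scores: Sequence[SegScore]) -> dict:
    """Mean Dice and mean HD95 over the cases where HD95 is defined."""
    dices = [s.dice for s in scores]
    hds = [s.hd95 for s in scores if s.hd95_defined]
    return {
        "n": len(dices),
        "mean_dice": float(np.mean(dices)) if dices else math.nan,
        "mean_hd95": float(np.mean(hds)) if hds else math.nan,
        "n_hd95_defined": len(hds),
    }
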