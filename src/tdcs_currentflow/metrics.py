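"""Scalar summaries and map-level comparisons of current-density volumes.

Region medians (rather than means) summarize the skewed |J| distributions;
paired percent differences quantify the artificial-vs-real discrepancy per
subject; SSIM/Dice compare whole volumes; and a voxelwise paired t-map
localizes where the two electrode pipelines disagree across a cohort.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sp_stats
from skimage.metrics import structural_similarity

from .errors import ValidationError


@dataclass
class MedianSummary:
    region: str
    median_j: float  # A/m^2
    voxel_count: int
    model: str = ""


@dataclass
class PairedMapComparison:
    t_grid: np.ndarray
    significance_mask: np.ndarray
    difference_grid: np.ndarray  # mean(real - artificial) within the mask, A/m^2
    alpha: float
    n_excluded_zero_variance: int


def median_current_density(
    jmag: np.ndarray, mask: np.ndarray, region: str = "", model: str = ""
) -> MedianSummary:
    """Sample median of |J| over the masked voxels.

    For even counts this is the mean of the two central order statistics.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != np.asarray(jmag).shape:
        raise ValidationError("mask and volume shapes differ")
    vals = np.asarray(jmag, dtype=float)[mask]
    if vals.size == 0:
        raise ValidationError(f"empty mask for region {region!r}")
    if not np.all(np.isfinite(vals)):
        raise ValidationError(f"non-finite |J| inside mask {region!r}")
    return MedianSummary(region, float(np.median(vals)), int(vals.size), model)


def percent_difference(artificial_value: float, real_value: float) -> float:
    """100 * |artificial - real| / real."""
    if real_value == 0:
        raise ZeroDivisionError("percent difference undefined for real value 0")
    return 100.0 * abs(artificial_value - real_value) / real_value


def volume_similarity(
    vol_a: np.ndarray,
    vol_b: np.ndarray,
    mask: np.ndarray,
    dice_percentile: float = 99.0,
    win_size: int = 11,
) -> tuple[float, float]:
    """(SSIM, Dice) between two |J| volumes on a common grid.

    SSIM uses the standard constants (K1=0.01, K2=0.03) with the dynamic
    range set to the maximum over both masked volumes; values outside the
    mask are zeroed.  Dice binarizes each volume at its own
    ``dice_percentile`` of masked values (suprathreshold overlap).
    """
    a = np.asarray(vol_a, dtype=float)
    b = np.asarray(vol_b, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValidationError("volumes and mask must share one grid")
    if not mask.any():
        raise ValidationError("empty mask")

    am = np.where(mask, np.nan_to_num(a), 0.0)
    bm = np.where(mask, np.nan_to_num(b), 0.0)
    data_range = float(max(am[mask].max(), bm[mask].max()))
    if data_range <= 0:
        raise ValidationError("both volumes are zero inside the mask; SSIM/Dice undefined")
    win = min(win_size, *(s if s % 2 else s - 1 for s in a.shape))
    ssim = float(
        structural_similarity(am, bm, data_range=data_range, win_size=win, K1=0.01, K2=0.03)
    )

    ta = np.percentile(am[mask], dice_percentile)
    tb = np.percentile(bm[mask], dice_percentile)
    sa = mask & (am > ta)
    sb = mask & (bm > tb)
    denom = sa.sum() + sb.sum()
    if denom == 0:
        raise ValidationError("no suprathreshold voxels; Dice undefined")
    dice = 2.0 * np.count_nonzero(sa & sb) / denom
    return ssim, float(dice)


def voxelwise_paired_tmap(
    stack_artificial: np.ndarray,
    stack_real: np.ndarray,
    alpha: float = 0.001,
    mask: np.ndarray | None = None,
) -> PairedMapComparison:
    """Per-voxel paired t-test over subjects for the real-vs-artificial contrast.

    Stacks are (n_subjects, nx, ny, nz) |J| grids on a shared grid.  Voxels
    with zero difference variance are excluded and counted.  The difference
    grid holds mean(real - artificial) inside the significance mask.
    """
    art = np.asarray(stack_artificial, dtype=float)
    real = np.asarray(stack_real, dtype=float)
    if art.shape != real.shape:
        raise ValidationError("stacks must share one grid")
    n = art.shape[0]
    if n < 3:
        raise ValidationError("need at least 3 paired subjects")

    d = real - art
    valid = np.isfinite(d).all(axis=0)
    if mask is not None:
        valid &= np.asarray(mask, dtype=bool)
    mean_d = np.where(valid, np.nanmean(d, axis=0), np.nan)
    sd_d = np.where(valid, np.nanstd(d, axis=0, ddof=1), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        nonzero = valid & (sd_d > 0)
        t = np.full(valid.shape, np.nan)
        t[nonzero] = mean_d[nonzero] / (sd_d[nonzero] / np.sqrt(n))
        p = np.full(valid.shape, np.nan)
        p[nonzero] = 2.0 * sp_stats.t.sf(np.abs(t[nonzero]), df=n - 1)

    sig = nonzero & (p < alpha)
    diff = np.where(sig, mean_d, np.nan)
    return PairedMapComparison(
        t_grid=t,
        significance_mask=sig,
        difference_grid=diff,
        alpha=alpha,
        n_excluded_zero_variance=int(np.count_nonzero(valid & ~nonzero)),
    )
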