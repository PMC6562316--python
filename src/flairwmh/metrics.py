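"""Agreement and association statistics for segmentation validation.

Implements the evaluation toolbox used throughout the pipeline: Dice overlap,
Pearson correlation, intraclass correlation (two-way mixed, absolute
agreement, single measure — ICC(A,1)), the zero-intercept log-log fit between
manual and automatic volumes with its MSE, the lesion-wise outline/detection
error rates (OER/DER), robust outlier removal on volume differences, and the
age association of log WMH volume with a 10-fold leave-one-fold-out slope
uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .core import BinaryMask

__all__ = [
    "dice",
    "icc",
    "loglog_fit",
    "oer_der",
    "remove_volume_outliers",
    "wmhv_age_regression",
    "SlopeEstimate",
    "AgreementReport",
    "agreement_report",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def _as_bool(a) -> np.ndarray:
    if isinstance(a, BinaryMask):
        return a.data
    return np.asarray(a).astype(bool)


def dice(a, b) -> float:
    """2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = _as_bool(a), _as_bool(b)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def icc(manual, automatic) -> float:
    """ICC(A,1): two-way mixed effects, absolute agreement, single measure.

    Computed from the two-way ANOVA mean squares (McGraw & Wong A-1 form)
    for k = 2 raters.
    """
    x = np.asarray(manual, dtype=float)
    y = np.asarray(automatic, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("paired 1-D volume lists required")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    data = np.stack([x, y], axis=1)  # n subjects x k raters
    k = 2
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(data.var(), 0):
        raise ValueError("zero variance in both raters")
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((data - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse)))


def loglog_fit(manual, automatic) -> tuple[float, float]:
    """Zero-intercept least squares of ln(automatic) on ln(manual).

    Returns (slope, mse) where mse is the mean squared residual of the fit.
    """
    m = np.asarray(manual, dtype=float)
    a = np.asarray(automatic, dtype=float)
    if np.any(m <= 0) or np.any(a <= 0):
        raise ValueError("volumes must be strictly positive for the log-log fit")
    lx, ly = np.log(m), np.log(a)
    sxx = (lx * lx).sum()
    if sxx == 0:
        raise ValueError("degenerate manual volumes (all 1.0 cc)")
    slope = float((lx * ly).sum() / sxx)
    resid = ly - slope * lx
    return slope, float(np.mean(resid**2))


def oer_der(manual, automatic) -> tuple[float, float]:
    """Outline and detection error rates over 26-connected union components.

    Components of the union containing voxels from both masks contribute
    their symmetric difference to the outline error (boundary disagreement);
    single-source components contribute their whole volume to the detection
    error (missed or spurious lesions).  Both are normalized by the mean of
    the two mask volumes.  (0, 0) when both masks are empty.
    """
    a, b = _as_bool(manual), _as_bool(automatic)
    if a.shape != b.shape:
        raise ValueError(f"mask grids differ: {a.shape} vs {b.shape}")
    union = a | b
    if not union.any():
        return (0.0, 0.0)
    labels, n = ndimage.label(union, structure=_STRUCT26 if a.ndim == 3 else None)
    oe = de = 0
    for comp in range(1, n + 1):
        sel = labels == comp
        na, nb = int((a & sel).sum()), int((b & sel).sum())
        if na > 0 and nb > 0:
            oe += int((a ^ b)[sel].sum())
        else:
            de += na + nb
    mean_vol = 0.5 * (a.sum() + b.sum())
    return float(oe / mean_vol), float(de / mean_vol)


def remove_volume_outliers(manual, automatic, threshold: float = 3.5) -> np.ndarray:
    """Indices kept after modified-z screening of the volume differences."""
    from .qc import modified_zscore

    m = np.asarray(manual, dtype=float)
    a = np.asarray(automatic, dtype=float)
    if m.shape != a.shape:
        raise ValueError("paired lists required")
    z = modified_zscore(a - m)
    return np.flatnonzero(np.abs(z) <= threshold)


@dataclass
class SlopeEstimate:
    slope: float  # ln(cc)/year
    intercept: float
    fold_sd: float  # leave-one-fold-out (grouped jackknife) SE of the slope
    n: int
    fold_slopes: np.ndarray | None = None


def wmhv_age_regression(ages, wmhv, folds: int = 10, seed: int = 0) -> SlopeEstimate:
    """OLS of ln(WMHv) on age, with fold-based slope uncertainty.

    Subjects are shuffled (seeded) into ``folds`` contiguous folds; the model
    is refit leaving each fold out.  The reported uncertainty is the grouped
    (delete-a-fold) jackknife standard error of the slope,
    ``sqrt((k-1)/k * sum_i (s_i - s_mean)^2)`` — the raw spread of the fold
    slopes understates the sampling SD because any two refits share ~80% of
    the data.
    """
    ages = np.asarray(ages, dtype=float)
    wmhv = np.asarray(wmhv, dtype=float)
    if np.any(wmhv <= 0):
        raise ValueError("WMH volumes must be positive")
    n = ages.size
    if n < folds:
        raise ValueError(f"need at least {folds} subjects for {folds}-fold uncertainty")
    y = np.log(wmhv)
    slope, intercept = np.polyfit(ages, y, 1)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_ids = np.array_split(order, folds)
    fold_slopes = []
    for held in fold_ids:
        keep = np.setdiff1d(order, held)
        s, _ = np.polyfit(ages[keep], y[keep], 1)
        fold_slopes.append(s)
    fold_slopes = np.asarray(fold_slopes)
    k = len(fold_slopes)
    jack_se = np.sqrt((k - 1) / k * ((fold_slopes - fold_slopes.mean()) ** 2).sum())
    return SlopeEstimate(
        slope=float(slope),
        intercept=float(intercept),
        fold_sd=float(jack_se),
        n=int(n),
        fold_slopes=fold_slopes,
    )


@dataclass
class AgreementReport:
    """Summary of manual-vs-automatic segmentation agreement."""

    pearson_r: float
    pearson_p: float
    icc: float
    slope: float  # zero-intercept, ln scale
    mse: float
    n_pairs: int
    n_outliers_removed: int
    dice_median: float = np.nan
    oer_median: float = np.nan
    oer_iqr: tuple[float, float] = (np.nan, np.nan)
    der_median: float = np.nan
    der_iqr: tuple[float, float] = (np.nan, np.nan)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "icc": self.icc,
            "slope": self.slope,
            "mse": self.mse,
            "n_pairs": self.n_pairs,
            "n_outliers_removed": self.n_outliers_removed,
            "dice_median": self.dice_median,
            "oer_median": self.oer_median,
            "oer_iqr": list(self.oer_iqr),
            "der_median": self.der_median,
            "der_iqr": list(self.der_iqr),
        }


def agreement_report(
    manual_volumes,
    automatic_volumes,
    mask_pairs: list[tuple[BinaryMask, BinaryMask]] | None = None,
    remove_outliers: bool = True,
) -> AgreementReport:
    """Volume agreement on the natural-log scale, optionally with mask-wise
    Dice and OER/DER summaries; volume-difference outliers are screened with
    the modified z-score (threshold 3.5) before correlating."""
    m = np.asarray(manual_volumes, dtype=float)
    a = np.asarray(automatic_volumes, dtype=float)
    kept = remove_volume_outliers(m, a) if remove_outliers else np.arange(m.size)
    mk, ak = m[kept], a[kept]
    r, p = stats.pearsonr(np.log(mk), np.log(ak))
    slope, mse = loglog_fit(mk, ak)
    rep = AgreementReport(
        pearson_r=float(r),
        pearson_p=float(p),
        icc=icc(np.log(mk), np.log(ak)),  # natural log throughout
        slope=slope,
        mse=mse,
        n_pairs=int(kept.size),
        n_outliers_removed=int(m.size - kept.size),
    )
    if mask_pairs:
        dices = [dice(x, y) for x, y in mask_pairs]
        pairs = [oer_der(x, y) for x, y in mask_pairs]
        oers = np.array([p_[0] for p_ in pairs])
        ders = np.array([p_[1] for p_ in pairs])
        rep.dice_median = float(np.median(dices))
        rep.oer_median = float(np.median(oers))
        rep.oer_iqr = tuple(np.percentile(oers, [25, 75]))
        rep.der_median = float(np.median(ders))
        rep.der_iqr = tuple(np.percentile(ders, [25, 75]))
    return rep
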