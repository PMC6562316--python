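"""Cohort quality control: geometry screening and brain-volume outlier flags.

Two tiers, run at different points of the pipeline:

1. Before processing, acquisition geometry is screened — modified z-scores
   (threshold 3.5) of the in-plane and through-plane resolutions across the
   cohort, plus a hard flag for scans with at most 3 slices.
2. After brain extraction, total brain volume (grey matter + white matter +
   ventricles) is screened two ways: a site-stratified modified z-score
   (threshold 3.5), and residuals from the cohort-wide linear model of brain
   volume on age, ``y = m*age + b``, flagging volumes more than two residual
   standard deviations from the model estimate.

Flags carry a disposition (pending / excluded / kept): outlier detection
proposes, a human review — modeled here as an editable disposition — decides.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AgeVolumeModel",
    "QCFlag",
    "modified_zscore",
    "screen_geometry",
    "fit_age_volume",
    "flag_age_outliers",
    "flag_site_volume_outliers",
    "qc_summary",
]

Z_THRESHOLD = 3.5
MIN_SLICES = 4  # scans with <= 3 slices are flagged
AGE_SD_MULTIPLE = 2.0


@dataclass
class AgeVolumeModel:
    """Linear model of total brain volume (cc) on age (years)."""

    m: float  # cc/year
    b: float  # cc
    residual_sd: float  # cc
    n: int

    def predict(self, age) -> np.ndarray:
        return self.m * np.asarray(age, dtype=float) + self.b


@dataclass
class QCFlag:
    subject_id: str
    reason: str  # resolution_inplane | resolution_throughplane | low_slices |
    #              site_volume | age_volume | registration | motion
    score: float  # modified z, or deviation in SD multiples
    disposition: str = "pending"  # pending | excluded | kept


def modified_zscore(values) -> np.ndarray:
    """0.6745 * (x - median) / MAD.

    With MAD = 0 (degenerate cohorts with identical metadata) the score is 0
    where the deviation is 0 and an infinite sentinel elsewhere, so such
    cohorts flag genuine deviants without dividing by zero.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    med = np.median(x)
    dev = x - med
    mad = np.median(np.abs(dev))
    if mad == 0:
        out = np.zeros_like(dev)
        nz = dev != 0
        out[nz] = np.inf * np.sign(dev[nz])
        return out
    return 0.6745 * dev / mad


def screen_geometry(records) -> list[QCFlag]:
    """Flag resolution outliers (|modified z| > 3.5 on either axis) and scans
    with low slice counts (<= 3)."""
    records = list(records)
    if not records:
        return []
    flags: list[QCFlag] = []
    z_in = modified_zscore([r.inplane_mm for r in records])
    z_th = modified_zscore([r.throughplane_mm for r in records])
    for r, zi, zt in zip(records, z_in, z_th):
        if np.abs(zi) > Z_THRESHOLD:
            flags.append(QCFlag(r.subject_id, "resolution_inplane", float(zi)))
        if np.abs(zt) > Z_THRESHOLD:
            flags.append(QCFlag(r.subject_id, "resolution_throughplane", float(zt)))
        if r.slices < MIN_SLICES:
            flags.append(QCFlag(r.subject_id, "low_slices", float(r.slices)))
    return flags


def fit_age_volume(ages, volumes) -> AgeVolumeModel:
    """Ordinary least squares of brain volume on age."""
    ages = np.asarray(ages, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if ages.size != volumes.size:
        raise ValueError("ages and volumes must be paired")
    if ages.size < 3:
        raise ValueError("need at least 3 subjects to fit the age model")
    if np.allclose(ages, ages[0]):
        raise ValueError("constant ages: singular design")
    m, b = np.polyfit(ages, volumes, 1)
    resid = volumes - (m * ages + b)
    return AgeVolumeModel(m=float(m), b=float(b), residual_sd=float(resid.std()), n=int(ages.size))


def flag_age_outliers(model: AgeVolumeModel, records, volumes=None) -> list[QCFlag]:
    """Flag brain volumes more than 2 residual SDs from the model estimate.

    ``volumes`` overrides the per-record volume (e.g. pipeline-measured
    brain volumes rather than generator truth).
    """
    records = list(records)
    if volumes is None:
        volumes = [r.true_brain_cc for r in records]
    flags = []
    for r, v in zip(records, volumes):
        if model.residual_sd == 0:
            dev_sd = 0.0 if v == model.predict(r.age) else np.inf
        else:
            dev_sd = float((v - model.predict(r.age)) / model.residual_sd)
        if np.abs(dev_sd) > AGE_SD_MULTIPLE:
            flags.append(QCFlag(r.subject_id, "age_volume", dev_sd))
    return flags


def flag_site_volume_outliers(records, volumes=None) -> list[QCFlag]:
    """Modified z-score of brain volume within each site, threshold 3.5.

    Sites with a single subject are skipped with a warning.
    """
    records = list(records)
    if volumes is None:
        volumes = [r.true_brain_cc for r in records]
    flags: list[QCFlag] = []
    sites = sorted({r.site for r in records})
    for site in sites:
        group = [(r, v) for r, v in zip(records, volumes) if r.site == site]
        if len(group) < 2:
            warnings.warn(f"site {site} has a single subject; skipping site-volume QC")
            continue
        z = modified_zscore([v for _, v in group])
        for (g, _), zg in zip(group, z):
            if np.abs(zg) > Z_THRESHOLD:
                flags.append(QCFlag(g.subject_id, "site_volume", float(zg)))
    return flags


@dataclass
class QCSummary:
    n_total: int
    n_flagged: int
    n_excluded: int
    n_kept_after_review: int
    n_pending: int
    counts_by_reason: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_flagged": self.n_flagged,
            "n_excluded": self.n_excluded,
            "n_kept_after_review": self.n_kept_after_review,
            "n_pending": self.n_pending,
            "counts_by_reason": self.counts_by_reason,
        }


def qc_summary(records, flags: list[QCFlag]) -> QCSummary:
    """Account for every subject exactly once: unflagged + excluded + kept +
    pending partitions the cohort."""
    by_subject: dict[str, list[QCFlag]] = {}
    for f in flags:
        by_subject.setdefault(f.subject_id, []).append(f)
    n_excluded = n_kept = n_pending = 0
    for _, fs in by_subject.items():
        if any(f.disposition == "excluded" for f in fs):
            n_excluded += 1
        elif all(f.disposition == "kept" for f in fs):
            n_kept += 1
        else:
            n_pending += 1
    counts: dict[str, int] = {}
    for f in flags:
        counts[f.reason] = counts.get(f.reason, 0) + 1
    return QCSummary(
        n_total=len(list(records)),
        n_flagged=len(by_subject),
        n_excluded=n_excluded,
        n_kept_after_review=n_kept,
        n_pending=n_pending,
        counts_by_reason=counts,
    )
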