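"""Cohort orchestration: per-subject processing, QC, and WMHv analysis.

The per-subject flow is fixed: brain extraction -> intensity normalization ->
spatial normalization (isotropic upsampling + affine registration to the
template) -> WMH segmentation.  A failed stage marks all downstream stages
skipped; the cohort run continues with the next subject.  Subjects are
independent, so cohort processing is an embarrassingly parallel map; serial
and parallel execution produce identical outputs.

A cohort run follows the screening order of large clinical studies:
acquisition-geometry outliers are excluded before any image processing, the
remaining subjects are processed, extracted brain volumes feed site-level and
age-model QC, and the WMHv-age analysis runs on the surviving subjects only.
"""

from __future__ import annotations

import hashlib
import json
from concurrent.futures import ProcessPoolExecutor
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .augment import AugmentConfig
from .brainx import BrainXModel, UNetConfig, extract_brain, train_brainx
from .core import BinaryMask, VoxelVolume
from .intnorm import normalize_volume
from .metrics import SlopeEstimate, wmhv_age_regression
from .phantom import PhantomTruth, SubjectRecord
from .qc import (
    QCFlag,
    fit_age_volume,
    flag_age_outliers,
    flag_site_volume_outliers,
    qc_summary,
    screen_geometry,
)
from .spatialnorm import (
    Template,
    build_template,
    register_affine,
    registration_mask_dice,
    resample_to_template,
    upsample_iso,
    upsample_mask_iso,
)
from .wmhseg import InferenceModel, PriorModel, segment_wmh, train_inference, train_prior

__all__ = [
    "PipelineConfig",
    "ModelBundle",
    "SubjectResult",
    "train_pipeline_models",
    "run_subject",
    "run_cohort",
    "CohortResult",
]

_STAGES = ("brain_extraction", "intensity_normalization", "spatial_normalization", "wmh_segmentation")


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, serializable for provenance."""

    # Batch-level corruption (the augment module) is off by default: the
    # phantom cohorts already carry site-gain and noise variability, and the
    # short CPU training schedules converge much further without it.  Enable
    # it for longer schedules or externally heterogeneous data.
    unet: UNetConfig = field(default_factory=lambda: UNetConfig(features=16, epochs=5))
    augment: AugmentConfig | None = None
    prior_features: int = 8
    prior_code: int = 32
    prior_epochs: int = 4
    inference_epochs: int = 4
    slice_stride: int = 2
    bandwidth: float | None = None  # mean-shift bandwidth; None = adaptive
    reg_levels: tuple[int, ...] = (4, 2)
    reg_maxfev: tuple[int, ...] = (200, 80)
    template_n: int = 10
    workers: int = 1
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["augment"] = asdict(self.augment) if self.augment else None
        d["unet"] = asdict(self.unet)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class ModelBundle:
    """Everything a cohort run needs: trained networks plus the template."""

    brainx: BrainXModel
    prior: PriorModel
    inference: InferenceModel
    template: Template

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.brainx.save(d / "brainx")
        self.prior.save(d / "prior")
        self.inference.save(d / "inference")
        self.template.volume.save(d / "template_flair.nii.gz")
        self.template.brain_mask.save(d / "template_brain.nii.gz")
        np.save(d / "template_prior.npy", self.template.wmh_prior)

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        from .core import load_mask, load_volume

        d = Path(directory)
        prior = PriorModel.load(d / "prior")
        tpl = Template(
            volume=load_volume(d / "template_flair.nii.gz"),
            brain_mask=load_mask(d / "template_brain.nii.gz"),
            wmh_prior=np.load(d / "template_prior.npy"),
        )
        return cls(
            brainx=BrainXModel.load(d / "brainx"),
            prior=prior,
            inference=InferenceModel.load(d / "inference", prior),
            template=tpl,
        )


@dataclass
class SubjectResult:
    subject_id: str
    stages: dict = field(default_factory=lambda: {s: "pending" for s in _STAGES})
    error: str | None = None
    brain_cc: float = np.nan
    wm_mode: float = np.nan
    fwhm: tuple[float, float] | None = None
    registration_dice: float = np.nan
    wmhv_cc: float = np.nan
    ln_wmhv: float = np.nan
    left_cc: float = np.nan
    right_cc: float = np.nan
    flags: list = field(default_factory=list)

    def row(self) -> dict:
        return {
            "id": self.subject_id,
            "status": "ok" if self.error is None else "failed",
            "brain_cc": self.brain_cc,
            "wm_mode": self.wm_mode,
            "registration_dice": self.registration_dice,
            "wmhv_cc": self.wmhv_cc,
            "ln_wmhv": self.ln_wmhv,
            "left_cc": self.left_cc,
            "right_cc": self.right_cc,
        }


def train_pipeline_models(
    training: list[PhantomTruth],
    config: PipelineConfig | None = None,
    template_phantoms: list[PhantomTruth] | None = None,
) -> ModelBundle:
    """Train all pipeline models from phantoms with ground-truth masks.

    The brain-extraction network trains on (FLAIR, brain mask) pairs; the
    template is the mean of normalized, isotropically resampled phantoms;
    the spatial prior trains on atlas-space WMH masks and the inference
    encoder on (atlas FLAIR, WMH mask) pairs.  Training phantoms share the
    template geometry by construction, so their masks reach atlas space by
    direct upsampling without per-subject registration.
    """
    config = config or PipelineConfig()
    if len(training) < 10:
        raise ValueError("need at least 10 training phantoms")
    bx = train_brainx(
        [(p.flair, p.brain_mask) for p in training], config.unet, augment=config.augment
    )
    norms = [normalize_volume(p.flair, p.brain_mask, bandwidth=config.bandwidth) for p in training]
    tpl_src = template_phantoms or training[: config.template_n]
    tpl_norms = (
        [normalize_volume(p.flair, p.brain_mask, bandwidth=config.bandwidth) for p in tpl_src]
        if template_phantoms
        else norms[: config.template_n]
    )
    template = build_template(
        [n.volume for n in tpl_norms],
        [p.brain_mask for p in tpl_src],
        [p.wmh_mask for p in tpl_src],
    )
    atlas_masks = [upsample_mask_iso(p.wmh_mask) for p in training]
    atlas_flairs = [upsample_iso(n.volume) for n in norms]
    prior = train_prior(
        atlas_masks,
        features=config.prior_features,
        code=config.prior_code,
        epochs=config.prior_epochs,
        slice_stride=config.slice_stride,
        seed=config.seed,
    )
    inference = train_inference(
        list(zip(atlas_flairs, atlas_masks)),
        prior,
        epochs=config.inference_epochs,
        slice_stride=config.slice_stride,
        seed=config.seed,
    )
    return ModelBundle(brainx=bx, prior=prior, inference=inference, template=template)


def run_subject(
    bundle: ModelBundle,
    scan: VoxelVolume,
    subject_id: str,
    config: PipelineConfig | None = None,
    lesion_mask: BinaryMask | None = None,
    out_dir=None,
) -> SubjectResult:
    """Run the four-stage flow on one scan; errors are recorded, not raised."""
    config = config or PipelineConfig()
    res = SubjectResult(subject_id=subject_id)

    def fail(stage, exc):
        res.stages[stage] = "failed"
        res.error = f"{stage}: {exc}"
        later = _STAGES[_STAGES.index(stage) + 1 :]
        for s in later:
            res.stages[s] = "skipped"
        return res

    try:
        ext = extract_brain(bundle.brainx, scan)
        res.brain_cc = ext.volume_cc
        if ext.flagged:
            raise RuntimeError("empty brain prediction")
        res.stages["brain_extraction"] = "ok"
    except Exception as e:  # noqa: BLE001 - stage errors feed QC
        return fail("brain_extraction", e)

    try:
        norm = normalize_volume(scan, ext.mask, bandwidth=config.bandwidth)
        res.wm_mode = norm.wm_mode
        res.fwhm = norm.fwhm
        res.stages["intensity_normalization"] = "ok"
    except Exception as e:  # noqa: BLE001
        return fail("intensity_normalization", e)

    try:
        up = upsample_iso(norm.volume)
        transform = register_affine(
            up, bundle.template, levels=config.reg_levels, maxfev=config.reg_maxfev
        )
        res.registration_dice = registration_mask_dice(
            upsample_mask_iso(ext.mask), transform, bundle.template
        )
        atlas = resample_to_template(up, transform, bundle.template)
        res.stages["spatial_normalization"] = "ok"
    except Exception as e:  # noqa: BLE001
        return fail("spatial_normalization", e)

    try:
        atlas_lesion = None
        if lesion_mask is not None:
            atlas_lesion = resample_to_template(
                upsample_mask_iso(lesion_mask), transform, bundle.template
            )
        seg = segment_wmh(
            bundle.inference, atlas, bundle.template, fwhm=norm.fwhm, lesion_mask=atlas_lesion
        )
        res.wmhv_cc = seg.wmhv_cc
        res.ln_wmhv = seg.ln_wmhv
        res.left_cc = seg.left_cc
        res.right_cc = seg.right_cc
        res.stages["wmh_segmentation"] = "ok"
        if out_dir is not None:
            d = Path(out_dir)
            d.mkdir(parents=True, exist_ok=True)
            ext.mask.save(d / f"{subject_id}_brain.nii.gz")
            norm.volume.save(d / f"{subject_id}_norm.nii.gz")
            atlas.save(d / f"{subject_id}_atlas.nii.gz")
            seg.mask.save(d / f"{subject_id}_wmh.nii.gz")
            seg.probability.save(d / f"{subject_id}_wmh_prob.nii.gz")
    except Exception as e:  # noqa: BLE001
        return fail("wmh_segmentation", e)
    return res


@dataclass
class CohortResult:
    table: pd.DataFrame  # one row per input subject
    flags: list[QCFlag]
    age_model: "object | None"  # AgeVolumeModel, None if too few subjects
    analysis: SlopeEstimate | None
    summary: dict

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(d / "wmhv_table.tsv", sep="\t", index=False)
        rows = [
            {"id": f.subject_id, "reason": f.reason, "score": f.score, "disposition": f.disposition}
            for f in self.flags
        ]
        pd.DataFrame(rows, columns=["id", "reason", "score", "disposition"]).to_csv(
            d / "qc_flags.tsv", sep="\t", index=False
        )
        (d / "summary.json").write_text(json.dumps(self.summary, indent=2, default=float))


def _run_one(args):
    bundle, scan, sid, config = args
    return run_subject(bundle, scan, sid, config)


def run_cohort(
    bundle: ModelBundle,
    subjects: list[tuple[SubjectRecord, VoxelVolume]],
    config: PipelineConfig | None = None,
    out_dir=None,
) -> CohortResult:
    """Process a cohort: geometry screen, per-subject runs, volume QC, analysis.

    Geometry-flagged subjects are excluded before processing.  Brain-volume
    QC (site-stratified modified z and the age model) runs on the measured
    volumes of processed subjects; flagged subjects are excluded from the
    WMHv-age analysis.  Deterministic given the config seeds.
    """
    config = config or PipelineConfig()
    records = [r for r, _ in subjects]

    geo_flags = screen_geometry(records)
    for f in geo_flags:
        f.disposition = "excluded"
    excluded_geo = {f.subject_id for f in geo_flags}

    todo = [(r, s) for r, s in subjects if r.subject_id not in excluded_geo]
    jobs = [(bundle, scan, rec.subject_id, config) for rec, scan in todo]
    if config.workers > 1:
        with ProcessPoolExecutor(max_workers=config.workers) as pool:
            results = list(pool.map(_run_one, jobs))
    else:
        results = [_run_one(j) for j in jobs]
    by_id = {res.subject_id: res for res in results}

    processed = [(r, by_id[r.subject_id]) for r, _ in todo if by_id[r.subject_id].error is None]
    vol_flags: list[QCFlag] = []
    age_model = None
    if len(processed) >= 3:
        recs = [r for r, _ in processed]
        vols = [res.brain_cc for _, res in processed]
        vol_flags += flag_site_volume_outliers(recs, vols)
        ages = [r.age for r in recs]
        age_model = fit_age_volume(ages, vols)
        vol_flags += flag_age_outliers(age_model, recs, vols)
    for f in vol_flags:
        f.disposition = "excluded"
    excluded_vol = {f.subject_id for f in vol_flags}

    proc_fail_flags = [
        QCFlag(res.subject_id, "motion", np.nan, "excluded")
        for res in results
        if res.error is not None
    ]
    all_flags = geo_flags + vol_flags + proc_fail_flags

    survivors = [
        (r, by_id[r.subject_id])
        for r, _ in todo
        if by_id[r.subject_id].error is None and r.subject_id not in excluded_vol
    ]
    analysis = None
    analysis_note = None
    positive = [(r, res) for r, res in survivors if res.wmhv_cc > 0]
    if len(positive) >= 10:
        analysis = wmhv_age_regression(
            [r.age for r, _ in positive], [res.wmhv_cc for _, res in positive], seed=config.seed
        )
    else:
        analysis_note = f"analysis skipped: only {len(positive)} surviving subjects with WMHv > 0"

    rows = []
    for rec, _ in subjects:
        res = by_id.get(rec.subject_id)
        row = {
            "id": rec.subject_id,
            "age": rec.age,
            "sex": rec.sex,
            "site": rec.site,
        }
        if rec.subject_id in excluded_geo:
            row.update({"status": "excluded_geometry"})
        elif res is not None:
            row.update(res.row())
            row["id"] = rec.subject_id
            if rec.subject_id in excluded_vol:
                row["status"] = "excluded_volume_qc"
        rows.append(row)
    table = pd.DataFrame(rows)

    summary = {
        "n_input": len(subjects),
        "n_excluded_geometry": len(excluded_geo),
        "n_processing_failed": len(proc_fail_flags),
        "n_excluded_volume_qc": len(excluded_vol - excluded_geo),
        "n_analyzed": len(positive) if analysis is not None else 0,
        "n_kept": len(survivors),
        "qc": qc_summary(records, all_flags).to_dict(),
        "age_model": None
        if age_model is None
        else {"m_cc_per_year": age_model.m, "b_cc": age_model.b, "residual_sd_cc": age_model.residual_sd},
        "analysis": None
        if analysis is None
        else {
            "ln_wmhv_age_slope": analysis.slope,
            "intercept": analysis.intercept,
            "fold_sd": analysis.fold_sd,
            "n": analysis.n,
        },
        "analysis_note": analysis_note,
        "provenance": {
            "version": __version__,
            "config_hash": config.config_hash(),
            "seed": config.seed,
        },
    }
    result = CohortResult(table=table, flags=all_flags, age_model=age_model, analysis=analysis, summary=summary)
    if out_dir is not None:
        result.save(out_dir)
    return result
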