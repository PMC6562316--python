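# flairwmh

Automated quantification of white matter hyperintensity (WMH) burden on
clinical-grade T2-FLAIR MRI.

WMH — the bright lesion class on FLAIR linked to cerebrovascular disease —
is usually delineated by hand, which does not scale to the thousands of
scans that hospital-based stroke cohorts produce. Clinical FLAIR is also
hostile to standard neuroimaging tooling: voxels are highly anisotropic
(~0.7 mm in-plane, ~6 mm between slices), intensities are in arbitrary
scanner units that differ across sites, and acute stroke lesions share the
hyperintense appearance of WMH. `flairwmh` implements a fully automated
pipeline for this setting:

1. **Brain extraction** — a 2-D U-Net over axial slice triplets (5
   pool/upsample levels, 2 convolutions per level, Adadelta, mini-batches
   of 16), with 97th-percentile intensity scaling, padding to multiples of
   16, hole closing, and largest-connected-component selection.
2. **Intensity normalization** — mean-shift estimation of the white-matter
   intensity mode inside the brain mask, rescaled so the mode maps to
   0.75; the FWHM of the mode's density peak marks probable WM for QC.
3. **Spatial normalization** — cubic upsampling to a 1 mm grid and a
   12-parameter affine registration (multi-resolution Powell search on
   normalized cross-correlation) to a population template.
4. **WMH segmentation** — a convolutional auto-encoder learns the spatial
   distribution of lesions from label maps; an inference encoder maps the
   FLAIR image to the frozen decoder's latent code, and the decoded
   probability map is intersected with a hyperintensity gate. WMHv is
   reported in cc, with left/right hemispheric volumes.
5. **Cohort QC and analysis** — geometry screening (modified z-score
   `0.6745·(x−median)/MAD`, threshold 3.5; ≤3 slices), site-stratified and
   age-model brain-volume outlier flags (`y = m·age + b`, 2 residual SDs),
   and the WMHv–age association `ln(WMHv) = s·age + c` with a 10-fold
   leave-one-fold-out slope uncertainty.

Real clinical cohorts cannot be redistributed, so the package includes a
first-class phantom module: synthetic anisotropic FLAIR heads with
ground-truth brain/WM/ventricle/WMH/stroke masks, multi-site intensity
gains, motion/ghosting corruption operators, and cohort generators that
embed the statistical models above. All networks run on a small NumPy
layer library with explicit backprop — no GPU or deep-learning framework
required. See `docs/methods.md` for the full model description.

## Worked example

Train every model on 20 synthetic subjects and process a small cohort:

```python
import dataclasses
import numpy as np

from flairwmh.phantom import TEST_SCALE_SPEC, SubjectRecord, generate_phantom
from flairwmh.brainx import UNetConfig
from flairwmh.pipeline import PipelineConfig, run_cohort, train_pipeline_models

rng = np.random.default_rng(7)
phantoms = [
    generate_phantom(dataclasses.replace(
        TEST_SCALE_SPEC,
        seed=100 + i,
        target_wmh_cc=float(np.exp(rng.uniform(np.log(0.5), np.log(30)))),
        site_gain=float(np.exp(rng.uniform(np.log(0.5), np.log(2)))),
    ))
    for i in range(22)
]

config = PipelineConfig(unet=UNetConfig(features=16, epochs=5),
                        prior_features=8, prior_code=32)
bundle = train_pipeline_models(phantoms[:20], config)

subjects = [
    (SubjectRecord(f"sub-{i}", age=60.0 + i, sex="F", site=0,
                   inplane_mm=2.0, throughplane_mm=6.0, slices=12),
     p.flair)
    for i, p in enumerate(phantoms[20:])
]
result = run_cohort(bundle, subjects, config)
print(result.table[["id", "brain_cc", "wm_mode", "registration_dice", "wmhv_cc"]])
```

which prints:

```
      id  brain_cc     wm_mode  registration_dice  wmhv_cc
0  sub-0   269.184  170.829130           0.980342    2.751
1  sub-1   268.440  163.185507           0.980105    5.086
```

`brain_cc` is the extracted total brain volume (both heads are ~269 cc at
this miniature grid scale); `wm_mode` is the estimated white-matter
intensity in native scanner units, which depends on each site's gain —
after normalization both modes map to 0.75; `registration_dice` is the
overlap between the registered brain mask and the template mask, stored
per subject as a QC input; `wmhv_cc` is the segmented WMH volume (ground
truth for these two subjects: 1.85 and 3.89 cc — small lesion loads carry
a modest positive bias from partial-volume boundaries). On
30-phantom evaluation cohorts the pipeline's WMHv agrees with ground truth
at Pearson r ≈ 0.99 and ICC ≈ 0.99 with a log-log slope ≈ 0.97, and the
cohort analysis recovers the generating WMHv–age slope of
0.051 ln(cc)/year (all recomputed by `scripts/acceptance.py`).

A command-line interface mirrors the library:

```bash
flairwmh phantom --n 20 --out data/ --seed 7        # synthetic cohort
flairwmh brainx train --data data/ --out model      # brain extraction
flairwmh brainx apply --model model --in scan.nii.gz --out mask.nii.gz
flairwmh qc --cohort cohort.tsv --out qc/           # geometry + volume QC
flairwmh run --models models/ --scans data/ --cohort cohort.tsv --out out/
```

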