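# Methods

`flairwmh` quantifies white matter hyperintensity (WMH) burden on
clinical-grade T2-FLAIR MRI: brain extraction, intensity normalization,
atlas-space spatial normalization, spatial-prior lesion segmentation,
cohort quality control, and the WMHv–age association. Real emergency-room
FLAIR of stroke patients cannot be redistributed, so the package ships a
synthetic head-phantom generator that reproduces the geometry and contrast
structure of such data; every stage is trained and validated against
phantom ground truth.

## Head phantoms

A head is built from nested ellipsoids (scalp, skull, a CSF gap, a grey
matter ribbon of 3 mm, white matter interior) with paired medial
ventricular ellipsoids. Lesions follow the spatial structure that the
segmentation prior later exploits: 70% of the target WMH volume is placed
as spheres (radius 2.5–5 mm) in a periventricular shell 2–10 mm from the
ventricular surface, 30% as deep white-matter spheres beyond 10 mm. An
optional stroke lesion (a larger deep sphere) is kept disjoint from WMH
and ventricles. FLAIR contrast: ventricular CSF suppressed (25), white
matter 100, grey matter 115, WMH 170, stroke 160, all in arbitrary
scanner units, multiplied by a per-site gain (default range 0.5–2.0) with
additive Gaussian acquisition noise (SD 5 units).

Tissue occupancy is simulated on a ~1 mm grid and block-averaged onto the
anisotropic acquisition grid, reproducing thick-slice partial voluming;
masks are binarized at occupancy 0.5, and reported "true" volumes are
voxel counts times voxel volume on that grid. Lesion placement tops up
against the partial-volumed measurement so the achieved WMH volume lands
within 15% of the target (for targets ≥ 0.5 cc). The default acquisition
geometry is clinical (256×256×28 voxels at 0.7×0.7×6.3 mm); the test
scale used throughout the suite is 64×64×12 at 2×2×6 mm, which preserves
the in-plane/through-plane anisotropy style while rendering in under a
second.

The cohort generator layers the two statistical models the analysis
stages assume: total brain volume `y = m·age + b + N(0, σ)` (defaults
m = −2.4 cc/yr, b = 1630.8 cc, σ = 167.5 cc) and
`ln WMHv = s·age + c + N(0, σ_w)` (defaults s = 0.051 ln(cc)/yr,
c = −1.57, σ_w = 0.5), with ages uniform on [30, 90] and an exponential
WMHv option. With the residual SDs at zero both models are recovered
exactly by least squares — the identity the recovery tests rely on.
Voxel phantoms are rendered per subject only on request; statistical
cohorts at epidemiological n need only the records. Rendered test-scale
cohorts use a grid-appropriate brain model (≈300 cc heads), since a
1500 cc head cannot fit the miniature grid.

What the phantoms do **not** emulate: gyral and deep grey anatomy, bias
fields, multi-peak tissue histograms, pathology heterogeneity
(confluent vs punctate lesions), or k-space-accurate motion. Passing
phantom tests therefore demonstrates the pipeline's mechanics and
calibration under known truth, not clinical accuracy.

## Training-time corruption model

Mini-batch samples can be corrupted with (in fixed order) multiplicative
contrast scaling in [0.7, 1.3], up to 3 ghost copies shifted along one
axis with geometrically decaying weight (default 0.3, offsets 4–16
voxels), additive Gaussian noise (SD 0.4), and Perlin gradient noise
(SD 0.5, lattice period 32, cosine-smoothstep interpolation, rescaled
post hoc to the target SD). The operators do not commute; the order is
pinned by tests. With the short 5-epoch schedules used at test scale the
pipeline trains without corruption by default — the phantom cohorts
already vary site gain and noise, and the corruption budget otherwise
dominates the optimization — but the model remains one switch away for
longer schedules or heterogeneous external data.

## Brain extraction

A 2-D U-Net over axial slice triplets (each slice with its two
neighbours as channels; edge slices replicate the missing neighbour).
Five 2×2 max-pool levels down and five nearest-neighbour upsample levels
up, two 3×3 convolutions per level with a constant feature width
(default 128; 16 at test scale so CPU training finishes in minutes),
skip connections on the up path, 1×1 sigmoid output. Inputs are scaled
so the volume's 97th intensity percentile maps to 1 and padded in-plane
to multiples of 16; the padding is inverted on output. This scaling
makes extraction exactly invariant to global intensity rescaling of the
input.

The networks are implemented in a small NumPy layer library with
explicit backward passes (im2col GEMM convolutions, argmax-tracked
pooling) and the Adadelta optimizer (ρ = 0.95, lr = 1). Adadelta's eps
is 1e-4 rather than the textbook 1e-6: the first update magnitudes scale
with √eps, and at 1e-6 a 75-step schedule never leaves the warm-up
regime (1e-2 diverges). Loss is per-pixel binary cross-entropy
(threshold 0.5; both choices are conventions, not claims). Predictions
are post-processed by per-slice and 3-D hole filling, retention of the
largest 26-connected component, and a final hole fill, so the output
mask is guaranteed single-component and hole-free; an empty prediction
is returned as a flagged zero-volume result that feeds QC rather than
raising.

## Intensity normalization

Inside the brain mask, the white-matter intensity mode is the fixed
point of a Gaussian-kernel mean-shift iteration (bandwidth 5% of the
1st–99th percentile range; convergence at 1e-6 of the range or 500
iterations; deterministic order-statistic thinning above 200k voxels).
Initialization is the argmax of a 256-bin histogram restricted to the
upper 60% of the in-brain range — on FLAIR the suppressed CSF occupies
the dark end, so this steers the iteration to the WM peak. Intensities
are rescaled so the mode maps to 0.75 (a fixed constant of the method).
The FWHM of a 512-point Gaussian KDE around the mode marks probable
white matter for QC; bounds that never cross half-maximum clamp to the
range edge with a warning. Normalization is idempotent (second scale
factor ≈ 1) and the mode estimate is scale-equivariant.

## Spatial normalization

Volumes are resampled to 1 mm isotropic grids with cubic interpolation
(output shape = floor of the physical extent) and registered to a
template by a 12-parameter affine (translation, rotation, log-scale,
shear, parameterized about the template centre) maximizing normalized
cross-correlation over template-mask voxels. The built-in optimizer is a
multi-resolution Powell search over scaled parameters (strides 4×/2×/1×,
capped function evaluations; cohort processing uses the cheaper 4×/2×
schedule, whose mask overlap matches the full schedule). Any engine
producing a world-to-world 4×4 affine satisfies the backend contract.
A failure to improve on the identity returns the identity with a warning
so QC sees it. Masks resample by nearest neighbour; per-subject
registration quality (Dice of the warped brain mask against the
template mask) is stored in the results table as a QC input. The
template is the voxelwise mean of normalized, isotropically resampled
phantoms, its brain mask the majority vote, and its WMH prior the
smoothed (σ = 2 mm) lesion frequency, rescaled to [0, 1]. Deformable
registration is deliberately out of scope.

## WMH segmentation

The spatial prior is a convolutional auto-encoder over atlas-space WMH
label maps: four conv(3×3)+ReLU+max-pool stages, a dense bottleneck
producing a fixed-length code (default 64; 32 at test scale), and four
conv+upsample stages with a sigmoid output. Label maps are split
train/validation/test preserving 699:91:90 proportions. The inference
network re-uses the frozen decoder: an encoder of identical topology but
independent parameters maps the registered, normalized FLAIR image to
the prior's code; training updates only the encoder, and the decoder is
verified bitwise unchanged afterwards. Both trainings weight the
positive class by the background/lesion voxel ratio (capped at 40);
unweighted cross-entropy on ~1% foregrounds is minimized by predicting
background everywhere.

The final mask is (decoded probability ≥ 0.5) AND (intensity above a
hyperintensity gate), restricted to the template brain mask and the
support of the template WMH prior (> 0.05) — cortical grey matter on
FLAIR can be as bright as mildly hyperintense lesions, and the prior
support is what excludes it. The gate treats lesion intensities as a
second class above normal white matter: a floor at 0.75 plus the FWHM
half-width marks where hyperintensity begins, and Otsu's criterion over
in-region voxels brighter than the WM mode places the threshold between
the WM noise tail / partial-volume ramp and the lesion plateau (falling
back to the floor when fewer than 200 candidates exist). Thresholding at
the floor alone dilates every blurred lesion boundary on thick-slice
data — on gate-only phantom volumes the adaptive rule moves the ICC
against truth from 0.34 to ~0.97. A fixed gate value can be passed
explicitly. Voxels inside an optional subject-level acute stroke mask
are removed; otherwise stroke/WMH disambiguation relies on the spatial
prior (phantom stroke lesions sit outside the periventricular shell).
WMHv is the mask voxel count × 0.001 cc on the 1 mm grid; hemispheric
volumes split at the template midsagittal plane and sum exactly to the
total.

## Quality control

Geometry screening flags in-plane or through-plane resolutions with
|modified z| > 3.5 (z = 0.6745·(x − median)/MAD; a zero MAD yields a
0/±∞ sentinel so degenerate cohorts with identical metadata flag only
true deviants) and scans with ≤ 3 slices; these are excluded before any
processing. After brain extraction, measured brain volumes are screened
by a site-stratified modified z (threshold 3.5; single-subject sites
skipped with a warning) and by residuals from the cohort-wide OLS fit of
volume on age, flagging |residual| > 2 residual SDs. Thresholds are
strict ("more than"). The age model is fit on all processed subjects in
a single pass, then flags are applied. Flags carry a disposition; the
automated cohort run treats volume-QC flags as exclusions, while the
disposition field supports a human kept/pending review in interactive
use. The cohort summary accounts for every input subject exactly once.

## Agreement and association statistics

Dice (1.0 for two empty masks); Pearson correlation; ICC as ICC(A,1) —
two-way, absolute agreement, single measure, computed from the ANOVA
mean squares (configurable; cross-checked against pingouin in tests);
zero-intercept least squares of ln(automatic) on ln(manual) volumes with
its mean squared residual; natural logs throughout. OER/DER decompose
disagreement over 26-connected components of the mask union: components
containing voxels of both masks contribute their symmetric difference to
the outline error, single-source components their full volume to the
detection error, both normalized by the mean mask volume — one fixed,
documented convention among the several in circulation. Volume-difference
outliers are removed by modified z at 3.5 before correlating.

The WMHv–age association is OLS of ln(WMHv) on age. Its uncertainty uses
a seeded shuffle into 10 contiguous folds and leave-one-fold-out refits;
the reported value is the delete-a-fold (grouped jackknife) standard
error, √((k−1)/k · Σ(sᵢ − s̄)²). The raw SD of the fold slopes would
understate the sampling SD roughly three-fold at k = 10, because any two
refits share ~80% of the data; the jackknife form matches the
closed-form OLS slope SE on simulated cohorts.

## Problem sizes and orchestration

The suite and the acceptance script run at test scale: 20 training
phantoms (64×64×12), a 16-feature U-Net trained 5 epochs in mini-batches
of 16, a spatial prior with 8 features and a 32-length code trained 4
epochs on every second atlas slice, and evaluation cohorts of ~30
subjects — sizes chosen so a single-CPU run of the whole pipeline
finishes in minutes while every contract stays at full strength.
Subjects are processed independently (serial and process-parallel
execution produce identical outputs); a failed stage marks downstream
stages skipped and the cohort run continues. Outputs carry provenance
(package version, config hash, seeds), and repeated runs with the same
seeds are bit-identical.

## Known limitations

Ellipsoid phantoms make brain extraction and registration easier than
real anatomy; reported Dice values at test scale are upper bounds on
clinical behaviour. The decoder bottleneck yields deliberately coarse
lesion probability maps — per-lesion boundaries come from the intensity
gate, so lesion-wise Dice (~0.6 on phantoms) is modest even when volume
agreement is high. The registration optimizer assumes a roughly
centred, brain-extracted head and a monomodal similarity; it is not a
general-purpose registration tool. The stroke/WMH separation is only as
good as the spatial prior unless an acute lesion mask is supplied.
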