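"""Synthetic anisotropic FLAIR head phantoms with ground-truth tissue masks.

Clinical-grade FLAIR of acute stroke patients cannot be redistributed, so the
package ships a phantom generator that emulates the geometry and contrast of
such scans: a head built from nested ellipsoids (scalp, skull, brain), a
CSF-suppressed ventricular system, bright periventricular and deep white
matter hyperintensities (WMH), an optional stroke lesion, multi-site
intensity gain and additive noise — on the highly anisotropic voxel grids
typical of emergency-room FLAIR (~0.7 mm in-plane, ~6.3 mm through-plane).

Tissue occupancy is simulated on a fine (~1 mm) grid and block-averaged down
to the anisotropic acquisition grid, which reproduces thick-slice partial
voluming.  Ground truth (brain / WM / ventricle / WMH / stroke masks and the
true volumes in cc) is reported on the acquisition grid so that every
downstream stage can be scored against it.

A cohort generator layers demographic structure on top: age-linear total
brain volume and age-linear log WMH volume, the two statistical models the
quality-control and analysis stages assume.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import BinaryMask, VoxelVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "SubjectRecord",
    "generate_phantom",
    "generate_cohort",
    "TEST_SCALE_SPEC",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head.

    Intensities are in arbitrary scanner units and obey FLAIR contrast:
    WMH brighter than white matter, ventricular CSF suppressed (dark).
    """

    shape: tuple[int, int, int] = (256, 256, 28)
    spacing: tuple[float, float, float] = (0.7, 0.7, 6.3)
    intensities: dict = field(
        default_factory=lambda: {
            "background": 3.0,
            "scalp": 130.0,
            "skull": 20.0,
            "csf": 25.0,
            "gm": 115.0,
            "wm": 100.0,
            "ventricle": 25.0,
            "wmh": 170.0,
            "stroke": 160.0,
        }
    )
    target_wmh_cc: float = 5.0
    target_brain_cc: float | None = None  # None: use the grid's natural head size
    stroke: bool = False
    site_gain: float = 1.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")
        ints = self.intensities
        if not (ints["wmh"] > ints["wm"] > ints["ventricle"]):
            raise ValueError(
                "FLAIR contrast violated: need WMH > WM > ventricle intensity, got "
                f"{ints['wmh']}, {ints['wm']}, {ints['ventricle']}"
            )
        if self.target_wmh_cc < 0:
            raise ValueError("target WMH volume must be non-negative")
        if self.site_gain <= 0:
            raise ValueError("site gain must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def physical_extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]


@dataclass
class PhantomTruth:
    """A rendered phantom plus its ground truth on the acquisition grid."""

    flair: VoxelVolume
    brain_mask: BinaryMask
    wm_mask: BinaryMask
    ventricle_mask: BinaryMask
    wmh_mask: BinaryMask
    stroke_mask: BinaryMask
    true_brain_cc: float
    true_wmh_cc: float

    def save(self, directory, prefix: str = "phantom") -> None:
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.flair.save(d / f"{prefix}_flair.nii.gz")
        for name in ("brain", "wm", "ventricle", "wmh", "stroke"):
            getattr(self, f"{name}_mask").save(d / f"{prefix}_{name}.nii.gz")


@dataclass
class SubjectRecord:
    """Per-subject demographics and acquisition geometry for a cohort."""

    subject_id: str
    age: float
    sex: str
    site: int
    inplane_mm: float
    throughplane_mm: float
    slices: int
    true_brain_cc: float = np.nan
    true_wmh_cc: float = np.nan


# Geometry fractions (of the grid's physical half-extent / of brain semi-axes).
_SCALP_FRAC = 0.92
_SCALP_THICK = 3.0  # mm
_SKULL_THICK = 3.0  # mm
_CSF_GAP = 2.0  # mm
_GM_THICK = 3.0  # mm
_VENT_SEMI = (0.10, 0.35, 0.30)  # of brain semi-axes
_VENT_OFFSET_X = 0.15  # of brain x semi-axis
_PV_SHELL = (2.0, 10.0)  # periventricular distance band, mm
_PV_FRACTION = 0.7  # fraction of lesion volume in the periventricular shell


def _sim_factors(spacing: tuple[float, float, float]) -> tuple[int, int, int]:
    """Integer subdivision per axis so the simulation grid is ~1 mm."""
    return tuple(max(1, int(round(s / 1.0))) for s in spacing)  # type: ignore[return-value]


def _block_mean(a: np.ndarray, f: tuple[int, int, int]) -> np.ndarray:
    x, y, z = a.shape
    fx, fy, fz = f
    return (
        a.reshape(x // fx, fx, y // fy, fy, z // fz, fz)
        .mean(axis=(1, 3, 5))
    )


def _ellipsoid(coords, center, semi) -> np.ndarray:
    x, y, z = coords
    return (
        ((x - center[0]) / semi[0]) ** 2
        + ((y - center[1]) / semi[1]) ** 2
        + ((z - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _add_sphere(mask_out, allowed, coords_1d, center, radius, spacing):
    """Rasterize sphere ∩ allowed into mask_out using a local bounding box."""
    xs, ys, zs = coords_1d
    lo, hi = [], []
    for ax, c in zip((xs, ys, zs), center):
        i0 = int(np.searchsorted(ax, c - radius))
        i1 = int(np.searchsorted(ax, c + radius)) + 1
        lo.append(max(0, i0))
        hi.append(min(len(ax), i1))
    sl = tuple(slice(l, h) for l, h in zip(lo, hi))
    gx, gy, gz = np.meshgrid(xs[sl[0]], ys[sl[1]], zs[sl[2]], indexing="ij")
    sphere = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2 <= radius**2
    added = sphere & allowed[sl] & ~mask_out[sl]
    mask_out[sl] |= added
    return int(added.sum())


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Render one phantom head deterministically from its spec and seed."""
    rng = np.random.default_rng(spec.seed)
    f = _sim_factors(spec.spacing)
    sim_shape = tuple(n * k for n, k in zip(spec.shape, f))
    sim_spacing = tuple(s / k for s, k in zip(spec.spacing, f))
    sim_voxvol_cc = float(np.prod(sim_spacing)) / 1000.0

    extent = np.array(spec.physical_extent_mm)
    center = extent / 2.0
    coords_1d = tuple(
        (np.arange(n) + 0.5) * s for n, s in zip(sim_shape, sim_spacing)
    )
    coords = np.meshgrid(*coords_1d, indexing="ij", sparse=True)

    scalp_semi = _SCALP_FRAC * extent / 2.0
    skull_outer = scalp_semi - _SCALP_THICK
    skull_inner = skull_outer - _SKULL_THICK
    brain_semi = skull_inner - _CSF_GAP
    if np.any(brain_semi <= _GM_THICK):
        raise ValueError(f"grid extent {tuple(extent)} mm is too small to hold a head")

    if spec.target_brain_cc is not None:
        natural_cc = 4.0 / 3.0 * np.pi * np.prod(brain_semi) / 1000.0
        s = (spec.target_brain_cc / natural_cc) ** (1.0 / 3.0)
        s_max = float(np.min(skull_inner / brain_semi))  # keep brain inside the skull
        if s > s_max:
            warnings.warn(
                f"target brain volume {spec.target_brain_cc:.0f} cc does not fit the "
                f"grid; clamping scale {s:.3f} -> {s_max:.3f}"
            )
            s = s_max
        brain_semi = brain_semi * s

    scalp_m = _ellipsoid(coords, center, scalp_semi)
    skull_outer_m = _ellipsoid(coords, center, skull_outer)
    skull_inner_m = _ellipsoid(coords, center, skull_inner)
    brain_m = _ellipsoid(coords, center, brain_semi)
    inner_m = _ellipsoid(coords, center, brain_semi - _GM_THICK)

    vent_semi = np.array(_VENT_SEMI) * brain_semi
    off = _VENT_OFFSET_X * brain_semi[0]
    vent_m = _ellipsoid(coords, center + np.array([off, 0, 0]), vent_semi) | _ellipsoid(
        coords, center - np.array([off, 0, 0]), vent_semi
    )
    vent_m &= inner_m

    gm_m = brain_m & ~inner_m
    wm_avail = inner_m & ~vent_m

    # Distance (mm) from the ventricular surface, for lesion placement.
    dist = ndimage.distance_transform_edt(~vent_m, sampling=sim_spacing)
    shell_m = wm_avail & (dist >= _PV_SHELL[0]) & (dist <= _PV_SHELL[1])
    deep_m = wm_avail & (dist > _PV_SHELL[1])

    stroke_m = np.zeros(sim_shape, dtype=bool)
    stroke_center_idx = None
    if spec.stroke:
        stroke_allowed = deep_m & (dist > _PV_SHELL[1] + 2.0)
        if not stroke_allowed.any():  # small heads: fall back to any deep WM
            stroke_allowed = deep_m
        idx = np.flatnonzero(stroke_allowed)
        if idx.size:
            c_flat = idx[rng.integers(idx.size)]
            c = np.unravel_index(c_flat, sim_shape)
            c_mm = tuple(coords_1d[a][c[a]] for a in range(3))
            r = max(min(8.0, 0.3 * float(np.min(brain_semi))), 0.75 * max(spec.spacing))
            _add_sphere(stroke_m, stroke_allowed, coords_1d, c_mm, r, sim_spacing)
            stroke_center_idx = tuple(int(c[a] // f[a]) for a in range(3))

    wmh_allowed = (shell_m | deep_m) & ~stroke_m
    avail_cc = float(wmh_allowed.sum()) * sim_voxvol_cc
    if spec.target_wmh_cc > 0.9 * avail_cc:
        raise ValueError(
            f"target WMH volume {spec.target_wmh_cc:.1f} cc exceeds 90% of the "
            f"available white matter ({avail_cc:.1f} cc)"
        )

    wmh_m = np.zeros(sim_shape, dtype=bool)
    coarse_wmh_cc = 0.0
    voxvol_cc = float(np.prod(spec.spacing)) / 1000.0

    def _place(region, budget_vox):
        placed = 0
        idx = np.flatnonzero(region & wmh_allowed & ~wmh_m)
        attempts = 0
        while placed < budget_vox and idx.size and attempts < 200:
            c_flat = idx[rng.integers(idx.size)]
            c = np.unravel_index(c_flat, sim_shape)
            c_mm = tuple(coords_1d[a][c[a]] for a in range(3))
            r = rng.uniform(2.5, 5.0)
            placed += _add_sphere(wmh_m, wmh_allowed, coords_1d, c_mm, r, sim_spacing)
            attempts += 1
        return placed

    if spec.target_wmh_cc > 0:
        n_target = spec.target_wmh_cc / sim_voxvol_cc
        _place(shell_m, _PV_FRACTION * n_target)
        _place(deep_m, (1.0 - _PV_FRACTION) * n_target - 0)
        # Top up against the acquisition-grid (partial-volumed) measurement.
        for _ in range(30):
            coarse_wmh_cc = float((_block_mean(wmh_m, f) > 0.5).sum()) * voxvol_cc
            if coarse_wmh_cc >= 0.92 * spec.target_wmh_cc:
                break
            if _place(shell_m if rng.random() < _PV_FRACTION else deep_m, 1) == 0:
                break

    wm_m = wm_avail & ~wmh_m & ~stroke_m

    # Piecewise-constant tissue image on the simulation grid.
    ints = spec.intensities
    img = np.full(sim_shape, ints["background"], dtype=np.float64)
    img[scalp_m] = ints["scalp"]
    img[skull_outer_m] = ints["skull"]
    img[skull_inner_m] = ints["csf"]
    img[gm_m] = ints["gm"]
    img[wm_m] = ints["wm"]
    img[vent_m] = ints["ventricle"]
    img[wmh_m] = ints["wmh"]
    img[stroke_m] = ints["stroke"]

    # Block-average to the anisotropic acquisition grid (thick-slice blur),
    # apply the site gain, then add acquisition noise.
    flair = _block_mean(img, f) * spec.site_gain
    if spec.noise_sd > 0:
        flair = flair + rng.normal(0.0, spec.noise_sd * spec.site_gain, size=flair.shape)

    def _coarse(m: np.ndarray) -> np.ndarray:
        return _block_mean(m, f) > 0.5

    brain_c = _coarse(brain_m)
    vent_c = _coarse(vent_m) & brain_c
    wmh_c = _coarse(wmh_m) & brain_c
    stroke_c = _coarse(stroke_m) & brain_c & ~vent_c
    if stroke_m.any() and not stroke_c.any() and stroke_center_idx is not None:
        # partial voluming erased a small lesion: keep at least its centre voxel
        stroke_c[stroke_center_idx] = brain_c[stroke_center_idx] and not vent_c[stroke_center_idx]
    wm_c = _coarse(wm_m) & brain_c & ~wmh_c & ~stroke_c & ~vent_c

    sp = spec.spacing
    truth = PhantomTruth(
        flair=VoxelVolume(flair, sp),
        brain_mask=BinaryMask(brain_c, sp),
        wm_mask=BinaryMask(wm_c, sp),
        ventricle_mask=BinaryMask(vent_c, sp),
        wmh_mask=BinaryMask(wmh_c, sp),
        stroke_mask=BinaryMask(stroke_c, sp),
        true_brain_cc=float(brain_c.sum()) * voxvol_cc,
        true_wmh_cc=float(wmh_c.sum()) * voxvol_cc,
    )
    return truth


# A small grid used throughout the test suite and worked examples: same
# clinical anisotropy ratio, but a grid a laptop CPU renders in milliseconds.
TEST_SCALE_SPEC = PhantomSpec(
    shape=(64, 64, 12),
    spacing=(2.0, 2.0, 6.0),
    target_wmh_cc=5.0,
    noise_sd=5.0,
)

# Brain-volume model at adult-head scale (cc vs years) and on the test grid, where
# a ~300 cc head is the largest that fits the 128x128x72 mm extent.
BRAIN_MODEL_DEFAULT = (-2.4, 1630.8, 167.5)
BRAIN_MODEL_TEST_SCALE = (-0.5, 320.0, 10.0)
WMH_MODEL_DEFAULT = (0.051, -1.57, 0.5)  # ln(cc) per year, intercept, residual SD


def generate_cohort(
    n: int,
    *,
    brain_model: tuple[float, float, float] = BRAIN_MODEL_DEFAULT,
    wmh_model: tuple[float, float, float] = WMH_MODEL_DEFAULT,
    sites: int = 12,
    age_range: tuple[float, float] = (30.0, 90.0),
    wmh_dist: str = "lognormal",
    wmh_floor_cc: float = 0.05,
    site_gain_range: tuple[float, float] = (0.5, 2.0),
    seed: int = 0,
    render: bool = False,
    base_spec: PhantomSpec | None = None,
) -> list[tuple[SubjectRecord, PhantomTruth | None]]:
    """Generate a cohort of subject records (and optionally rendered phantoms).

    Total brain volume follows ``m*age + b + N(0, sd)`` and WMH volume follows
    ``ln(WMHv) = slope*age + intercept + N(0, sd)`` (or an exponential with the
    same age-dependent scale when ``wmh_dist='exponential'``), floored at
    ``wmh_floor_cc``.  With both residual SDs at zero the generating models are
    recovered exactly by least squares — the property the analysis stages are
    tested against.

    Rendering every subject as a voxel phantom is opt-in (``render=True``):
    statistical cohorts at epidemiological sample sizes need only the records.
    """
    if n < 1:
        raise ValueError("cohort size must be >= 1")
    if sites < 1:
        raise ValueError("site count must be positive")
    m_b, b_b, sd_b = brain_model
    m_w, b_w, sd_w = wmh_model
    if sd_b < 0 or sd_w < 0:
        raise ValueError("residual SDs must be non-negative")

    rng = np.random.default_rng(seed)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]
    site_gains = np.exp(
        rng.uniform(np.log(site_gain_range[0]), np.log(site_gain_range[1]), size=sites)
    )

    base = base_spec if base_spec is not None else PhantomSpec()
    out: list[tuple[SubjectRecord, PhantomTruth | None]] = []
    for i in range(n):
        age = float(rng.uniform(*age_range))
        sex = "F" if rng.random() < 0.5 else "M"
        site = i % sites
        brain_cc = m_b * age + b_b + (rng.normal(0.0, sd_b) if sd_b > 0 else 0.0)
        ln_mu = m_w * age + b_w
        if wmh_dist == "lognormal":
            wmh_cc = float(np.exp(ln_mu + (rng.normal(0.0, sd_w) if sd_w > 0 else 0.0)))
        elif wmh_dist == "exponential":
            wmh_cc = float(rng.exponential(np.exp(ln_mu)))
        else:
            raise ValueError(f"unknown wmh_dist {wmh_dist!r}")
        wmh_cc = max(wmh_cc, wmh_floor_cc)
        rec = SubjectRecord(
            subject_id=f"sub-{i:04d}",
            age=age,
            sex=sex,
            site=site,
            inplane_mm=base.spacing[0],
            throughplane_mm=base.spacing[2],
            slices=base.shape[2],
            true_brain_cc=float(brain_cc),
            true_wmh_cc=wmh_cc,
        )
        truth = None
        if render:
            sub_spec = replace(
                base,
                seed=child_seeds[i],
                target_wmh_cc=wmh_cc,
                target_brain_cc=float(brain_cc),
                site_gain=float(site_gains[site]),
            )
            truth = generate_phantom(sub_spec)
            rec.true_brain_cc = truth.true_brain_cc
            rec.true_wmh_cc = truth.true_wmh_cc
        out.append((rec, truth))
    return out


def cohort_table(cohort) -> "pandas.DataFrame":  # noqa: F821
    """Tabulate a generated cohort as a DataFrame (id, age, sex, site, ...)."""
    import pandas as pd

    rows = []
    for rec, _ in cohort:
        rows.append(
            {
                "id": rec.subject_id,
                "age": rec.age,
                "sex": rec.sex,
                "site": rec.site,
                "inplane_mm": rec.inplane_mm,
                "throughplane_mm": rec.throughplane_mm,
                "slices": rec.slices,
                "true_brain_cc": rec.true_brain_cc,
                "true_wmh_cc": rec.true_wmh_cc,
            }
        )
    return pd.DataFrame(rows)
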