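"""Spatial normalization: isotropic upsampling and affine registration to a template.

Clinical FLAIR grids are highly anisotropic, so atlas-space processing first
resamples each volume to a 1 mm isotropic grid with cubic interpolation and
then aligns it to a template with a 12-parameter affine (translation,
rotation, log-scale, shear) that maximizes normalized cross-correlation
(NCC) over a multi-resolution schedule.  The registration backend is a
contract: any engine producing a world-to-world 4x4 affine can be plugged
in; the built-in optimizer (Powell search over scaled parameters) means no
external registration binary is required.

World coordinates are defined by each volume's affine (default: index times
spacing, RAS).  Transforms map moving world coordinates to fixed (template)
world coordinates and are stored as plain-text 4x4 matrices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .core import BinaryMask, VoxelVolume

__all__ = [
    "AffineTransform",
    "Template",
    "upsample_iso",
    "build_template",
    "register_affine",
    "resample_to_template",
    "resample_to_grid",
    "registration_mask_dice",
]


@dataclass
class AffineTransform:
    """4x4 homogeneous map from moving world to fixed world coordinates."""

    matrix: np.ndarray
    score: float = np.nan  # similarity at the optimum (NCC)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if abs(np.linalg.det(self.matrix[:3, :3])) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def identity(cls, score: float = np.nan) -> "AffineTransform":
        return cls(np.eye(4), score)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.score)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self after other: (self @ other)(x) = self(other(x))."""
        return AffineTransform(self.matrix @ other.matrix)

    def save(self, path) -> None:
        np.savetxt(str(path), self.matrix, header="moving-world -> fixed-world (RAS, row-major)")

    @classmethod
    def load(cls, path) -> "AffineTransform":
        return cls(np.loadtxt(str(path)))


@dataclass
class Template:
    """Atlas volume on a 1 mm isotropic grid, with brain mask and WMH prior."""

    volume: VoxelVolume
    brain_mask: BinaryMask
    wmh_prior: np.ndarray  # per-voxel probability in [0, 1]

    def __post_init__(self) -> None:
        if not np.allclose(self.volume.spacing, 1.0):
            raise ValueError("template grid must be 1 mm isotropic")
        if self.wmh_prior.min() < 0 or self.wmh_prior.max() > 1:
            raise ValueError("WMH prior must lie in [0, 1]")


def upsample_iso(volume: VoxelVolume, target: float = 1.0, order: int = 3) -> VoxelVolume:
    """Cubic resampling onto an isotropic grid covering the same extent.

    Output shape is floor(extent / target) per axis.
    """
    if any(s <= 0 for s in volume.spacing):
        raise ValueError("voxel spacing must be positive")
    out_shape = tuple(int(np.floor(e / target)) for e in volume.physical_extent_mm)
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(out_shape, volume.spacing)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(volume.data, coords, order=order, mode="nearest")
    return VoxelVolume(data, (target,) * 3)


def upsample_mask_iso(mask: BinaryMask, target: float = 1.0) -> BinaryMask:
    out_shape = tuple(int(np.floor(e / target)) for e in (n * s for n, s in zip(mask.shape, mask.spacing)))
    coords = np.meshgrid(
        *[np.arange(n) * target / s for n, s in zip(out_shape, mask.spacing)],
        indexing="ij",
    )
    data = ndimage.map_coordinates(mask.data.astype(np.float32), coords, order=0)
    return BinaryMask(data > 0.5, (target,) * 3)


def build_template(
    volumes: list[VoxelVolume],
    brain_masks: list[BinaryMask],
    wmh_masks: list[BinaryMask] | None = None,
    prior_smooth_mm: float = 2.0,
) -> Template:
    """Population template: voxelwise mean of isotropically resampled volumes.

    Inputs are expected to be intensity-normalized and to share acquisition
    geometry (the phantom generator guarantees this); the brain mask is the
    majority vote and the WMH prior the smoothed lesion frequency.
    """
    ups = [upsample_iso(v) for v in volumes]
    shape = ups[0].shape
    if any(u.shape != shape for u in ups):
        raise ValueError("template inputs do not share a common grid after upsampling")
    vol = VoxelVolume(np.mean([u.data for u in ups], axis=0), (1.0, 1.0, 1.0))
    masks = [upsample_mask_iso(m).data for m in brain_masks]
    brain = BinaryMask(np.mean(masks, axis=0) > 0.5, (1.0, 1.0, 1.0))
    if wmh_masks:
        freq = np.mean([upsample_mask_iso(m).data for m in wmh_masks], axis=0)
        prior = ndimage.gaussian_filter(freq, prior_smooth_mm)
        prior = np.clip(prior / max(prior.max(), 1e-12), 0.0, 1.0)
    else:
        prior = np.zeros(shape)
    return Template(volume=vol, brain_mask=brain, wmh_prior=prior)


def _params_to_matrix(p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """12 parameters -> 4x4 affine about ``center``: t, r, log-scale, shear."""
    t, r, ls, sh = p[:3], p[3:6], p[6:9], p[9:12]
    cx, cy, cz = np.cos(r)
    sx, sy, sz = np.sin(r)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    K = np.array([[1, sh[0], sh[1]], [0, 1, sh[2]], [0, 0, 1]])
    A = Rz @ Ry @ Rx @ K @ np.diag(np.exp(ls))
    M = np.eye(4)
    M[:3, :3] = A
    M[:3, 3] = center + t - A @ center
    return M


_PARAM_SCALE = np.array([10.0, 10.0, 10.0, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.05, 0.05, 0.05])


def _ncc(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    return float((a * b).sum() / denom) if denom > 0 else 0.0


def register_affine(
    moving: VoxelVolume,
    fixed: Template,
    levels: tuple[int, ...] = (4, 2, 1),
    maxfev: tuple[int, ...] | None = None,
    seed: int = 0,
) -> AffineTransform:
    """12-parameter affine maximizing NCC with multi-resolution Powell search.

    Deterministic given its inputs; if the optimum fails to improve on the
    identity transform, the identity is returned with a warning so that
    downstream QC sees the failure.
    """
    fvol = fixed.volume
    center = np.array(fvol.physical_extent_mm) / 2.0
    A_m_inv = np.linalg.inv(moving.affine)
    mdata = np.ascontiguousarray(moving.data, dtype=np.float64)
    if maxfev is None:
        maxfev = tuple(400 if l > 1 else 200 for l in levels)

    # Sample points: fixed-grid voxels inside the dilated template brain mask.
    dil = ndimage.binary_dilation(fixed.brain_mask.data, iterations=3)

    def level_samples(stride: int):
        sub = dil[::stride, ::stride, ::stride]
        idx = np.argwhere(sub) * stride
        world = (fvol.affine[:3, :3] @ idx.T + fvol.affine[:3, 3:4]).T
        vals = fvol.data[idx[:, 0], idx[:, 1], idx[:, 2]]
        return world, vals

    def objective_factory(world, fvals):
        def obj(z):
            M = _params_to_matrix(z * _PARAM_SCALE, center)
            Minv = np.linalg.inv(M)
            wm = (Minv[:3, :3] @ world.T + Minv[:3, 3:4])
            im = A_m_inv[:3, :3] @ wm + A_m_inv[:3, 3:4]
            mvals = ndimage.map_coordinates(mdata, im, order=1, mode="constant", cval=0.0)
            return -_ncc(mvals, fvals)

        return obj

    z = np.zeros(12)
    obj_final = None
    for stride, fev in zip(levels, maxfev):
        world, fvals = level_samples(stride)
        obj = objective_factory(world, fvals)
        res = optimize.minimize(
            obj, z, method="Powell", options={"maxfev": int(fev), "xtol": 1e-4, "ftol": 1e-6}
        )
        z = res.x
        obj_final = obj

    ncc_opt = -obj_final(z)
    ncc_id = -obj_final(np.zeros(12))
    if ncc_opt <= ncc_id - 1e-9:
        warnings.warn(
            f"registration failed to improve on identity (NCC {ncc_opt:.4f} <= {ncc_id:.4f}); "
            "returning identity"
        )
        return AffineTransform.identity(score=ncc_id)
    return AffineTransform(_params_to_matrix(z * _PARAM_SCALE, center), score=ncc_opt)


def resample_to_grid(
    obj: VoxelVolume | BinaryMask,
    transform: AffineTransform,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    affine: np.ndarray,
    order: int | None = None,
):
    """Resample onto an arbitrary target grid through ``transform``.

    Cubic interpolation for intensity volumes, nearest neighbour for masks
    (labels stay binary).
    """
    is_mask = isinstance(obj, BinaryMask)
    if order is None:
        order = 0 if is_mask else 3
    Minv = np.linalg.inv(transform.matrix)
    A_m_inv = np.linalg.inv(obj.affine)
    idx = np.indices(shape).reshape(3, -1)
    world_f = np.asarray(affine)[:3, :3] @ idx + np.asarray(affine)[:3, 3:4]
    world_m = Minv[:3, :3] @ world_f + Minv[:3, 3:4]
    im = A_m_inv[:3, :3] @ world_m + A_m_inv[:3, 3:4]
    src = obj.data.astype(np.float32) if is_mask else obj.data
    vals = ndimage.map_coordinates(src, im, order=order, mode="constant", cval=0.0)
    vals = vals.reshape(shape)
    if is_mask:
        return BinaryMask(vals > 0.5, spacing, affine)
    return VoxelVolume(vals, spacing, affine)


def resample_to_template(
    obj: VoxelVolume | BinaryMask,
    transform: AffineTransform,
    fixed: Template,
    order: int | None = None,
):
    t = fixed.volume
    return resample_to_grid(obj, transform, t.shape, t.spacing, t.affine, order=order)


def registration_mask_dice(
    subject_brain_mask: BinaryMask, transform: AffineTransform, fixed: Template
) -> float:
    """Dice between the registered subject brain mask and the template mask —
    the per-subject registration quality metric stored for QC."""
    from .metrics import dice

    warped = resample_to_template(subject_brain_mask, transform, fixed)
    return dice(warped, fixed.brain_mask)
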