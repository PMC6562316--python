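"""Core geometric containers: intensity volumes and binary masks with voxel spacing.

Every pipeline stage consumes and produces :class:`VoxelVolume` /
:class:`BinaryMask` objects.  Arrays are indexed ``(x, y, z)`` where ``z`` is
the through-plane (slice) axis; clinical FLAIR is highly anisotropic, with
fine in-plane and coarse through-plane spacing, so the spacing metadata is
load-bearing everywhere (volumes in cc, upsampling, registration).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

__all__ = ["VoxelVolume", "BinaryMask", "load_volume", "load_mask"]


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """RAS affine with the grid origin at voxel (0, 0, 0)."""
    aff = np.diag([spacing[0], spacing[1], spacing[2], 1.0])
    return aff


@dataclass
class VoxelVolume:
    """A 3-D scalar intensity grid with physical voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive mm values, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cubic centimetres (1 cc = 1000 mm^3)."""
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def physical_extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * s for n, s in zip(self.shape, self.spacing))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "VoxelVolume":
        return replace(self, data=np.asarray(data))

    def same_grid(self, other: "VoxelVolume | BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def save(self, path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


@dataclass
class BinaryMask:
    """A boolean grid geometrically aligned with a :class:`VoxelVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_cc(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def count(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cc: voxel count times voxel volume."""
        return self.count * self.voxel_volume_cc

    def same_grid(self, other: "VoxelVolume | BinaryMask") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)

    def save(self, path) -> None:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.affine)
        img.header.set_zooms(self.spacing)
        nib.save(img, str(path))


def _load(path):
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, spacing, np.asarray(img.affine)


def load_volume(path) -> VoxelVolume:
    data, spacing, affine = _load(path)
    return VoxelVolume(np.asarray(data, dtype=np.float64), spacing, affine)


def load_mask(path) -> BinaryMask:
    data, spacing, affine = _load(path)
    return BinaryMask(data > 0, spacing, affine)
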