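"""Training-time corruption model for clinical FLAIR slices.

Emulates the degradations seen in emergency-room FLAIR: scanner-to-scanner
contrast differences (multiplicative intensity scaling in [0.7, 1.3]),
motion ghosting (up to 3 displaced faint copies of the anatomy along one
axis, the phase-encode analogue), and additive Gaussian plus Perlin noise
(SDs 0.4 and 0.5 on intensity-normalized slices).  Applied per mini-batch
sample during network training, in the fixed order
contrast -> ghosts -> Gaussian -> Perlin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AugmentConfig",
    "scale_contrast",
    "add_ghosts",
    "add_gaussian_noise",
    "add_perlin_noise",
    "perlin_field",
    "augment_slice",
]


@dataclass
class AugmentConfig:
    contrast: tuple[float, float] = (0.7, 1.3)
    max_ghosts: int = 3
    ghost_offset: tuple[int, int] = (4, 16)  # sampled shift magnitude, voxels
    ghost_weight: float = 0.3
    gaussian_sd: float = 0.4
    perlin_sd: float = 0.5
    perlin_period: int = 32

    def __post_init__(self) -> None:
        lo, hi = self.contrast
        if not (0 < lo <= hi):
            raise ValueError(f"contrast range must satisfy 0 < low <= high, got {self.contrast}")
        if self.max_ghosts < 0:
            raise ValueError("max_ghosts must be >= 0")
        if self.gaussian_sd < 0 or self.perlin_sd < 0:
            raise ValueError("noise SDs must be >= 0")


def scale_contrast(slice_: np.ndarray, factor: float) -> np.ndarray:
    if factor <= 0:
        raise ValueError(f"contrast factor must be positive, got {factor}")
    return slice_ * factor


def _shift2d(a: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer shift with zero fill at the borders."""
    out = np.zeros_like(a)
    sx, sy = int(shift[0]), int(shift[1])
    h, w = a.shape
    src_x = slice(max(0, -sx), min(h, h - sx))
    src_y = slice(max(0, -sy), min(w, w - sy))
    dst_x = slice(max(0, sx), min(h, h + sx))
    dst_y = slice(max(0, sy), min(w, w + sy))
    out[dst_x, dst_y] = a[src_x, src_y]
    return out


def add_ghosts(
    slice_: np.ndarray,
    n: int,
    offset: tuple[int, int],
    weight: float = 0.3,
    max_ghosts: int = 3,
) -> np.ndarray:
    """Add ``n`` displaced copies with geometrically decaying weight.

    Copy ``k`` is shifted by ``k * offset`` and scaled by ``weight ** k``.
    """
    if not (0 <= n <= max_ghosts):
        raise ValueError(f"ghost count {n} outside [0, {max_ghosts}]")
    out = slice_.astype(np.float64, copy=True)
    for k in range(1, n + 1):
        out += weight**k * _shift2d(slice_, (k * offset[0], k * offset[1]))
    return out


def add_gaussian_noise(slice_: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return slice_.copy()
    return slice_ + rng.normal(0.0, sd, size=slice_.shape)


def perlin_field(
    shape: tuple[int, int], period: int, rng: np.random.Generator
) -> np.ndarray:
    """2-D gradient (Perlin-style) noise with cosine-smoothstep interpolation.

    Random unit gradients sit on a lattice with the given voxel period; each
    pixel interpolates the corner dot products.  The returned field has zero
    mean and unit sample SD.
    """
    if period < 2:
        raise ValueError("period must be >= 2")
    h, w = shape
    gh, gw = h // period + 2, w // period + 2
    theta = rng.uniform(0, 2 * np.pi, size=(gh, gw))
    gx, gy = np.cos(theta), np.sin(theta)

    ys, xs = np.meshgrid(np.arange(w) / period, np.arange(h) / period)
    xi, yi = xs.astype(int), ys.astype(int)
    xf, yf = xs - xi, ys - yi

    def dot(ix, iy, dx, dy):
        return gx[ix, iy] * dx + gy[ix, iy] * dy

    n00 = dot(xi, yi, xf, yf)
    n10 = dot(xi + 1, yi, xf - 1, yf)
    n01 = dot(xi, yi + 1, xf, yf - 1)
    n11 = dot(xi + 1, yi + 1, xf - 1, yf - 1)

    u = 0.5 * (1 - np.cos(np.pi * xf))  # cosine smoothstep
    v = 0.5 * (1 - np.cos(np.pi * yf))
    field = (n00 * (1 - u) + n10 * u) * (1 - v) + (n01 * (1 - u) + n11 * u) * v
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def add_perlin_noise(
    slice_: np.ndarray, sd: float, period: int, rng: np.random.Generator
) -> np.ndarray:
    """Add smooth gradient noise rescaled post hoc to sample SD ``sd``."""
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if sd == 0:
        return slice_.copy()
    return slice_ + sd * perlin_field(slice_.shape, period, rng)


def augment_slice(
    slice_: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> np.ndarray:
    """Sample one corruption and apply it (contrast -> ghosts -> noise).

    The order is fixed: the operators do not commute, so training and tests
    pin it.  For multi-channel inputs (slice triplets) the same corruption is
    applied to every channel.
    """
    factor = rng.uniform(*cfg.contrast)
    n_ghosts = int(rng.integers(0, cfg.max_ghosts + 1))
    mag = int(rng.integers(cfg.ghost_offset[0], cfg.ghost_offset[1] + 1))
    axis = int(rng.integers(2))
    offset = (mag, 0) if axis == 0 else (0, mag)

    channels = slice_[None] if slice_.ndim == 2 else slice_
    noise_g = rng.normal(0.0, cfg.gaussian_sd, size=channels.shape[-2:]) if cfg.gaussian_sd > 0 else 0.0
    noise_p = (
        cfg.perlin_sd * perlin_field(channels.shape[-2:], cfg.perlin_period, rng)
        if cfg.perlin_sd > 0
        else 0.0
    )
    out = np.empty_like(channels, dtype=np.float64)
    for c in range(channels.shape[0]):
        s = scale_contrast(channels[c], factor)
        s = add_ghosts(s, n_ghosts, offset, cfg.ghost_weight, cfg.max_ghosts)
        out[c] = s + noise_g + noise_p
    return out[0] if slice_.ndim == 2 else out
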