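"""Brain extraction for clinical FLAIR via a 2-D U-Net over axial slice triplets.

The extractor mirrors clinical-FLAIR skull stripping practice: each axial
slice plus its two neighbours form a 3-channel input to a U-Net with five
pool/upsample levels and two convolutions per level; intensities are roughly
normalized by scaling the volume's 97th percentile to 1, and slices are
zero-padded so in-plane dimensions are multiples of 16.  Predicted
probability maps are thresholded at 0.5, holes are closed, and the largest
26-connected 3-D component is kept as the brain mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .augment import AugmentConfig, augment_slice
from .core import BinaryMask, VoxelVolume
from .nn import UNet2D, train_model
from .nn.layers import sigmoid
from .nn.models import load_state, state_arrays

__all__ = [
    "UNetConfig",
    "BrainExtractionResult",
    "BrainXModel",
    "preprocess_volume",
    "make_slice_triplets",
    "train_brainx",
    "extract_brain",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class UNetConfig:
    """Architecture and optimization settings for the brain-extraction net.

    Defaults follow the full-size network (five levels, 128 features,
    Adadelta mini-batches of 16); ``features`` is configurable down so that
    CPU-only training finishes in minutes.
    """

    levels: int = 5
    features: int = 128
    in_channels: int = 3
    batch_size: int = 16
    optimizer: str = "adadelta"
    epochs: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 1 or self.features < 1:
            raise ValueError("levels and features must be >= 1")
        if self.in_channels % 2 != 1:
            raise ValueError("in_channels must be odd")


@dataclass
class Preprocessed:
    """A scaled, padded volume plus the padding needed to invert it."""

    volume: VoxelVolume
    pad_before: tuple[int, int]
    pad_after: tuple[int, int]
    scale: float

    def unpad(self, data: np.ndarray) -> np.ndarray:
        (bx, by), (ax, ay) = self.pad_before, self.pad_after
        nx, ny = data.shape[0] - bx - ax, data.shape[1] - by - ay
        return data[bx : bx + nx, by : by + ny, :]


@dataclass
class BrainExtractionResult:
    mask: BinaryMask
    volume_cc: float
    probabilities: np.ndarray  # per-voxel probability, original grid
    flagged: bool = False  # empty prediction: feeds QC rather than raising


def preprocess_volume(volume: VoxelVolume) -> Preprocessed:
    """Scale the 97th intensity percentile to 1 and pad in-plane to x16."""
    p97 = float(np.percentile(volume.data, 97))
    if p97 <= 0:
        raise ValueError("97th percentile of intensities is not positive; empty volume?")
    data = volume.data / p97
    nx, ny, _ = data.shape
    tx, ty = (-nx) % 16, (-ny) % 16
    before = (tx // 2, ty // 2)
    after = (tx - tx // 2, ty - ty // 2)
    if tx or ty:
        data = np.pad(data, ((before[0], after[0]), (before[1], after[1]), (0, 0)))
    return Preprocessed(
        volume=VoxelVolume(data, volume.spacing, volume.affine),
        pad_before=before,
        pad_after=after,
        scale=1.0 / p97,
    )


def make_slice_triplets(volume: VoxelVolume) -> np.ndarray:
    """(n_slices, 3, H, W): each axial slice with its two neighbours.

    Boundary slices replicate the edge slice as the missing neighbour.
    """
    data = volume.data
    nz = data.shape[2]
    if nz < 1:
        raise ValueError("volume has no axial slices")
    idx = np.arange(nz)
    nbr = np.stack([np.clip(idx - 1, 0, nz - 1), idx, np.clip(idx + 1, 0, nz - 1)])
    # data is (X, Y, Z); slices become (H, W) = (X, Y)
    return data[:, :, nbr].transpose(3, 2, 0, 1).astype(np.float32)


@dataclass
class BrainXModel:
    """Trained U-Net plus its configuration; serializable to npz + JSON."""

    net: UNet2D
    config: UNetConfig
    history: dict = field(default_factory=dict)

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *state_arrays(self.net))
        sidecar = {"config": asdict(self.config), "net": self.net.config()}
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "BrainXModel":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = UNetConfig(**sidecar["config"])
        net = UNet2D(cfg.in_channels, cfg.features, cfg.levels, seed=cfg.seed)
        with np.load(path.with_suffix(".npz")) as z:
            load_state(net, [z[k] for k in z.files])
        return cls(net=net, config=cfg)


def _training_arrays(pairs: list[tuple[VoxelVolume, BinaryMask]]):
    xs, ys = [], []
    for vol, mask in pairs:
        if vol.shape != mask.shape:
            raise ValueError(f"volume {vol.shape} and mask {mask.shape} are misaligned")
        pre = preprocess_volume(vol)
        xs.append(make_slice_triplets(pre.volume))
        m = mask.data.astype(np.float32)
        (bx, by), (ax, ay) = pre.pad_before, pre.pad_after
        m = np.pad(m, ((bx, ax), (by, ay), (0, 0)))
        ys.append(m.transpose(2, 0, 1)[:, None, :, :])
    return np.concatenate(xs), np.concatenate(ys)


def train_brainx(
    pairs: list[tuple[VoxelVolume, BinaryMask]],
    config: UNetConfig | None = None,
    augment: AugmentConfig | None = None,
    val_pairs: list[tuple[VoxelVolume, BinaryMask]] | None = None,
) -> BrainXModel:
    """Train the brain-extraction U-Net on (volume, brain-mask) pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 training volumes")
    config = config or UNetConfig()
    X, Y = _training_arrays(pairs)
    val = None
    if val_pairs:
        val = _training_arrays(val_pairs)

    augment_fn = None
    if augment is not None:
        def augment_fn(batch, rng):
            out = np.empty_like(batch)
            for i in range(batch.shape[0]):
                out[i] = augment_slice(batch[i], augment, rng)
            return out

    net = UNet2D(config.in_channels, config.features, config.levels, seed=config.seed)
    history = train_model(
        net,
        X,
        Y,
        epochs=config.epochs,
        batch_size=config.batch_size,
        seed=config.seed,
        augment_fn=augment_fn,
        val=val,
    )
    return BrainXModel(net=net, config=config, history=history)


def _postprocess(binary: np.ndarray) -> np.ndarray:
    """Close holes (per-slice then 3-D) and keep the largest 26-connected
    component, then re-fill so the result is guaranteed hole-free."""
    if not binary.any():
        return binary
    filled = np.stack(
        [ndimage.binary_fill_holes(binary[:, :, k]) for k in range(binary.shape[2])], axis=2
    )
    filled = ndimage.binary_fill_holes(filled)
    labels, n = ndimage.label(filled, structure=_STRUCT26)
    if n > 1:
        counts = np.bincount(labels.ravel())
        counts[0] = 0
        filled = labels == int(np.argmax(counts))
    return ndimage.binary_fill_holes(filled)


def extract_brain(model: BrainXModel, volume: VoxelVolume) -> BrainExtractionResult:
    """Apply the network slice-wise, threshold at 0.5, and post-process."""
    pre = preprocess_volume(volume)
    trip = make_slice_triplets(pre.volume)
    bs = model.config.batch_size
    probs = []
    for start in range(0, trip.shape[0], bs):
        logits = model.net.forward(trip[start : start + bs])
        probs.append(sigmoid(logits)[:, 0])
    prob = np.concatenate(probs).transpose(1, 2, 0)  # back to (X, Y, Z)
    prob = pre.unpad(prob)
    mask = _postprocess(prob >= 0.5)
    bm = BinaryMask(mask, volume.spacing, volume.affine)
    return BrainExtractionResult(
        mask=bm,
        volume_cc=bm.volume_cc,
        probabilities=prob,
        flagged=not mask.any(),
    )
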