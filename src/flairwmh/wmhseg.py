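"""Atlas-space WMH segmentation with a learned spatial prior.

The segmentation model has two halves.  A convolutional auto-encoder is
trained on WMH label maps in template space; its dense bottleneck captures
the spatial covariance of lesion patterns (periventricular caps and deep
white-matter blobs), and its decoder becomes a fixed spatial prior.  An
inference encoder with the same topology but independent parameters then
maps an intensity-normalized, registered FLAIR image to the prior's latent
code; decoding that code yields a lesion probability map.  The final mask
additionally requires hyperintensity consistency — voxels must be brighter
than an intensity gate placed above the normalized white-matter mode —
which separates WMH from normal tissue that the coarse prior may cover.

Voxels inside an optional subject-level acute stroke lesion mask are removed
from the WMH mask; without one, the spatial prior alone is relied on to
avoid stroke hyperintensity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import BinaryMask, VoxelVolume
from .intnorm import WM_TARGET, estimate_wm_mode
from .metrics import agreement_report
from .nn import ConvAutoEncoder, ImageEncoder, train_model
from .nn.layers import sigmoid
from .nn.models import load_state, state_arrays
from .nn.train import evaluate_loss
from .spatialnorm import Template

__all__ = [
    "PriorModel",
    "InferenceModel",
    "WMHResult",
    "train_prior",
    "train_inference",
    "segment_wmh",
    "evaluate_validation",
    "default_gate",
]

# Train/val/test fractions keep the 699:91:90 outline-split proportions.
SPLIT_FRACTIONS = (699 / 880, 91 / 880, 90 / 880)
PROB_THRESHOLD = 0.5


@dataclass
class PriorModel:
    """Spatial-prior auto-encoder plus training metadata."""

    net: ConvAutoEncoder
    n_train: int
    n_val: int
    n_test: int
    seed: int
    history: dict | None = None

    @property
    def decoder(self):
        return self.net.decoder

    def decoder_state(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.net.decoder.params]

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *state_arrays(self.net))
        meta = {
            "net": self.net.config(),
            "n_train": self.n_train,
            "n_val": self.n_val,
            "n_test": self.n_test,
            "seed": self.seed,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path) -> "PriorModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = meta["net"]
        net = ConvAutoEncoder(tuple(cfg["hw"]), cfg["features"], cfg["code"], seed=meta["seed"])
        with np.load(path.with_suffix(".npz")) as z:
            load_state(net, [z[k] for k in z.files])
        return cls(net=net, n_train=meta["n_train"], n_val=meta["n_val"],
                   n_test=meta["n_test"], seed=meta["seed"])


class InferenceModel:
    """Image encoder feeding the frozen prior decoder."""

    def __init__(self, encoder: ImageEncoder, prior: PriorModel):
        self.encoder = encoder
        self.prior = prior
        self._frozen = prior.decoder_state()

    @property
    def params(self):
        # All parameters whose gradients must be cleared each step; only the
        # encoder's are ever updated.
        return self.encoder.params + self.prior.decoder.params

    @property
    def trainable(self):
        return self.encoder.params

    def forward(self, x):
        return self.prior.decoder.forward(self.encoder.forward(x))

    def backward(self, dlogits):
        self.encoder.backward(self.prior.decoder.backward(dlogits))

    def check_frozen(self) -> None:
        """Bitwise freeze contract: the prior decoder must be unchanged."""
        for ref, p in zip(self._frozen, self.prior.decoder.params):
            if not np.array_equal(ref, p.value):
                raise RuntimeError("prior decoder was modified during inference training")

    def predict_prob(self, slices: np.ndarray, batch_size: int = 16) -> np.ndarray:
        out = []
        for s in range(0, slices.shape[0], batch_size):
            out.append(sigmoid(self.forward(slices[s : s + batch_size]))[:, 0])
        return np.concatenate(out)

    def save(self, path) -> None:
        path = Path(path)
        np.savez(path.with_suffix(".npz"), *state_arrays(self.encoder))
        path.with_suffix(".json").write_text(json.dumps({"net": self.encoder.config()}, indent=2))

    @classmethod
    def load(cls, path, prior: PriorModel) -> "InferenceModel":
        path = Path(path)
        cfg = json.loads(path.with_suffix(".json").read_text())["net"]
        enc = ImageEncoder(tuple(cfg["hw"]), cfg["features"], cfg["code"])
        with np.load(path.with_suffix(".npz")) as z:
            load_state(enc, [z[k] for k in z.files])
        return cls(enc, prior)


@dataclass
class WMHResult:
    probability: VoxelVolume  # atlas-space lesion probability
    mask: BinaryMask  # final WMH mask (probability AND intensity gate)
    wmhv_cc: float
    ln_wmhv: float
    left_cc: float
    right_cc: float


def _mask_slices(masks: list[BinaryMask], stride: int = 1) -> np.ndarray:
    grid = masks[0].shape
    for m in masks:
        if m.shape != grid:
            raise ValueError("label maps are not on a common grid")
    arrs = [m.data.transpose(2, 0, 1)[::stride, None].astype(np.float32) for m in masks]
    return np.concatenate(arrs)


def _auto_pos_weight(y: np.ndarray, cap: float = 40.0) -> float:
    """Balance the sparse lesion class: negative/positive ratio, capped."""
    pos = float(y.sum())
    if pos == 0:
        return 1.0
    return float(np.clip((y.size - pos) / pos, 1.0, cap))


def _volume_slices(vols: list[VoxelVolume], stride: int = 1) -> np.ndarray:
    arrs = [v.data.transpose(2, 0, 1)[::stride, None].astype(np.float32) for v in vols]
    return np.concatenate(arrs)


def train_prior(
    label_maps: list[BinaryMask],
    features: int = 16,
    code: int = 64,
    epochs: int = 5,
    slice_stride: int = 1,
    pos_weight: float | None = None,
    seed: int = 0,
) -> PriorModel:
    """Train the spatial-prior auto-encoder on atlas-space WMH label maps.

    Maps are shuffled into train/validation/test subsets with the same
    proportions as the 699/91/90 outline split; the validation subset tracks
    reconstruction loss during training.
    """
    if len(label_maps) < 10:
        raise ValueError("need at least 10 label maps to train the prior")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(label_maps))
    n = len(label_maps)
    n_train = max(1, int(round(SPLIT_FRACTIONS[0] * n)))
    n_val = max(1, int(round(SPLIT_FRACTIONS[1] * n)))
    train_maps = [label_maps[i] for i in order[:n_train]]
    val_maps = [label_maps[i] for i in order[n_train : n_train + n_val]]

    hw = train_maps[0].shape[:2]
    net = ConvAutoEncoder(hw, features=features, code=code, seed=seed)
    X = _mask_slices(train_maps, slice_stride)
    Xv = _mask_slices(val_maps, slice_stride)
    if pos_weight is None:
        pos_weight = _auto_pos_weight(X)
    untrained_val = evaluate_loss(net, Xv, Xv, pos_weight=pos_weight)
    history = train_model(
        net, X, X, epochs=epochs, seed=seed, val=(Xv, Xv), pos_weight=pos_weight
    )
    history["untrained_val_loss"] = untrained_val
    return PriorModel(
        net=net,
        n_train=n_train,
        n_val=n_val,
        n_test=n - n_train - n_val,
        seed=seed,
        history=history,
    )


def train_inference(
    pairs: list[tuple[VoxelVolume, BinaryMask]],
    prior: PriorModel,
    epochs: int = 5,
    slice_stride: int = 1,
    pos_weight: float | None = None,
    seed: int = 0,
) -> InferenceModel:
    """Train the image encoder against the frozen prior decoder.

    Only encoder parameters are updated; the decoder is verified bitwise
    unchanged afterwards (freeze contract).
    """
    vols = [p[0] for p in pairs]
    masks = [p[1] for p in pairs]
    X = _volume_slices(vols, slice_stride)
    Y = _mask_slices(masks, slice_stride)
    enc = ImageEncoder(prior.net.hw, features=prior.net.features, code=prior.net.code, seed=seed + 1)
    model = InferenceModel(enc, prior)
    if pos_weight is None:
        pos_weight = _auto_pos_weight(Y)
    history = train_model(
        model, X, Y, epochs=epochs, seed=seed, trainable=model.trainable, pos_weight=pos_weight
    )
    model.check_frozen()
    model.history = history
    return model


def default_gate(fwhm: tuple[float, float] | None) -> float:
    """Hyperintensity floor: the WM mode plus the FWHM half-width."""
    if fwhm is None:
        return WM_TARGET + 0.10
    return WM_TARGET + 0.5 * (fwhm[1] - fwhm[0])


def adaptive_gate(
    atlas_data: np.ndarray,
    region: np.ndarray,
    fwhm: tuple[float, float] | None,
    min_candidates: int = 200,
) -> float:
    """Two-class intensity gate between normal WM and the lesion class.

    The FWHM-based floor marks where hyperintensity begins, but on
    thick-slice scans the WM-to-lesion intensity ramp spans several mm once
    upsampled, so thresholding at the floor dilates every lesion boundary.
    Following the generative two-class view of lesion intensities, the gate
    is instead placed by Otsu's criterion over in-region voxels brighter
    than the WM mode — separating the WM noise tail / partial-volume ramp
    from the lesion plateau — and never below the floor.
    """
    floor = default_gate(fwhm)
    above = atlas_data[region & (atlas_data > WM_TARGET)]
    if above.size < min_candidates:
        return floor
    from skimage.filters import threshold_otsu

    return max(float(threshold_otsu(above)), floor)


def segment_wmh(
    model: InferenceModel,
    atlas_flair: VoxelVolume,
    template: Template,
    fwhm: tuple[float, float] | None = None,
    gate: float | None = None,
    lesion_mask: BinaryMask | None = None,
    prior_floor: float = 0.05,
) -> WMHResult:
    """Segment WMH on an intensity-normalized, registered FLAIR volume.

    The final mask is (decoded probability >= 0.5) AND (intensity above the
    gate), restricted to the template brain mask and to the support of the
    template's spatial WMH prior (``prior_floor``), which excludes cortical
    grey matter that can be as hyperintense as the gate; WMHv is reported in
    cc (1 mm^3 voxels) with left/right hemispheric volumes split at the
    template midsagittal plane.
    """
    brain = template.brain_mask.data
    if not np.any(atlas_flair.data):
        # no signal at all: nothing can pass the hyperintensity gate
        zero = np.zeros(atlas_flair.shape, dtype=bool)
        return WMHResult(
            probability=VoxelVolume(np.zeros(atlas_flair.shape), atlas_flair.spacing, atlas_flair.affine),
            mask=BinaryMask(zero, atlas_flair.spacing, atlas_flair.affine),
            wmhv_cc=0.0,
            ln_wmhv=-np.inf,
            left_cc=0.0,
            right_cc=0.0,
        )
    in_brain = atlas_flair.data[brain]
    mode = estimate_wm_mode(in_brain)
    if not (0.6 <= mode <= 0.9):
        raise ValueError(
            f"input does not look intensity-normalized: in-brain mode {mode:.3f} "
            "outside [0.6, 0.9] (expected WM mode at 0.75)"
        )
    region = brain.copy()
    if template.wmh_prior.any():
        region &= template.wmh_prior > prior_floor
    if gate is None:
        gate = adaptive_gate(atlas_flair.data, region, fwhm)

    slices = _volume_slices([atlas_flair])
    prob = model.predict_prob(slices).transpose(1, 2, 0)  # (X, Y, Z)
    mask = (prob >= PROB_THRESHOLD) & (atlas_flair.data > gate) & region
    if lesion_mask is not None:
        mask &= ~lesion_mask.data

    voxvol_cc = atlas_flair.voxel_volume_cc
    nx = mask.shape[0]
    left = mask[: nx // 2].sum() * voxvol_cc
    right = mask[nx // 2 :].sum() * voxvol_cc
    wmhv = float(mask.sum()) * voxvol_cc
    return WMHResult(
        probability=VoxelVolume(prob, atlas_flair.spacing, atlas_flair.affine),
        mask=BinaryMask(mask, atlas_flair.spacing, atlas_flair.affine),
        wmhv_cc=wmhv,
        ln_wmhv=float(np.log(wmhv)) if wmhv > 0 else -np.inf,
        left_cc=float(left),
        right_cc=float(right),
    )


def evaluate_validation(manual_wmhv, automatic_wmhv):
    """Agreement between manual and automatic WMHv on the natural-log scale:
    Pearson r, zero-intercept log-log slope with MSE, and ICC."""
    m = np.asarray(manual_wmhv, dtype=float)
    a = np.asarray(automatic_wmhv, dtype=float)
    if np.any(m <= 0) or np.any(a <= 0):
        raise ValueError("volumes must be positive before log transformation")
    return agreement_report(m, a, remove_outliers=False)
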