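"""Network architectures: 2-D U-Net and the spatial-prior auto-encoder."""

from __future__ import annotations

import numpy as np

from .layers import F32, Conv2D, Dense, MaxPool2, ReLU, Upsample2

__all__ = ["UNet2D", "ConvAutoEncoder", "ImageEncoder", "state_arrays", "load_state"]


class _ConvBlock:
    """conv3x3 -> ReLU -> conv3x3 -> ReLU."""

    def __init__(self, cin, cout, rng):
        self.c1, self.r1 = Conv2D(cin, cout, 3, rng), ReLU()
        self.c2, self.r2 = Conv2D(cout, cout, 3, rng), ReLU()

    @property
    def params(self):
        return self.c1.params + self.c2.params

    def forward(self, x):
        return self.r2.forward(self.c2.forward(self.r1.forward(self.c1.forward(x))))

    def backward(self, dy):
        return self.c1.backward(self.r1.backward(self.c2.backward(self.r2.backward(dy))))


class UNet2D:
    """U-Net with ``levels`` pool/upsample stages and a constant feature width.

    Two 3x3 convolutions per level, 2x2 max-pool down / nearest upsample up,
    skip connections concatenated on the up path, 1x1 output convolution
    producing per-pixel logits.  Inputs of arbitrary in-plane size are
    zero-padded to a multiple of 2**levels and the output cropped back.
    """

    def __init__(self, in_channels: int = 3, features: int = 128, levels: int = 5, seed: int = 0):
        if levels < 1 or features < 1:
            raise ValueError("levels and features must be >= 1")
        if in_channels % 2 != 1:
            raise ValueError("input channel count must be odd (centre slice + neighbours)")
        rng = np.random.default_rng(seed)
        self.in_channels, self.features, self.levels = in_channels, features, levels
        F = features
        self.down = []
        cin = in_channels
        for _ in range(levels):
            self.down.append((_ConvBlock(cin, F, rng), MaxPool2()))
            cin = F
        self.bottom = _ConvBlock(F, F, rng)
        self.up = []
        for _ in range(levels):
            self.up.append((Upsample2(), _ConvBlock(2 * F, F, rng)))
        self.out = Conv2D(F, 1, 1, rng)

    @property
    def params(self):
        ps = []
        for blk, _ in self.down:
            ps += blk.params
        ps += self.bottom.params
        for _, blk in self.up:
            ps += blk.params
        ps += self.out.params
        return ps

    def _pad(self, x):
        m = 2**self.levels
        _, _, h, w = x.shape
        ph, pw = (-h) % m, (-w) % m
        self._padhw = (ph, pw, h, w)
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        return x

    def forward(self, x: np.ndarray) -> np.ndarray:
        x = self._pad(np.asarray(x, dtype=F32))
        skips = []
        for blk, pool in self.down:
            x = blk.forward(x)
            skips.append(x)
            x = pool.forward(x)
        x = self.bottom.forward(x)
        self._split = []
        for (ups, blk), skip in zip(self.up, reversed(skips)):
            x = ups.forward(x)
            x = np.concatenate([skip, x], axis=1)
            x = blk.forward(x)
        logits = self.out.forward(x)
        ph, pw, h, w = self._padhw
        return logits[:, :, :h, :w]

    def backward(self, dlogits: np.ndarray) -> None:
        ph, pw, h, w = self._padhw
        if ph or pw:
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), (0, ph), (0, pw)))
        d = self.out.backward(np.asarray(dlogits, dtype=F32))
        dskips = []
        for ups, blk in reversed(self.up):
            d = blk.backward(d)
            dskip, d = np.split(d, 2, axis=1)
            dskips.append(dskip)
            d = ups.backward(d)
        d = self.bottom.backward(d)
        for (blk, pool), dskip in zip(reversed(self.down), reversed(dskips)):
            d = pool.backward(d)
            d = blk.backward(d + dskip)

    def config(self) -> dict:
        return {
            "kind": "unet2d",
            "in_channels": self.in_channels,
            "features": self.features,
            "levels": self.levels,
        }


def _pad16(hw: tuple[int, int]) -> tuple[int, int]:
    return (hw[0] + (-hw[0]) % 16, hw[1] + (-hw[1]) % 16)


class _Encoder:
    """Four conv3x3+ReLU+maxpool stages, then a dense layer to a fixed code.

    Inputs are zero-padded to a multiple of 16 (four 2x2 pools) internally.
    """

    def __init__(self, in_channels, features, code, hw, rng):
        self.hw_in = tuple(hw)
        hw = _pad16(hw)
        h, w = hw
        self.hw = hw
        F = features
        self.stages = []
        cin = in_channels
        for _ in range(4):
            self.stages.append((Conv2D(cin, F, 3, rng), ReLU(), MaxPool2()))
            cin = F
        self._flat = F * (h // 16) * (w // 16)
        self.dense = Dense(self._flat, code, rng)

    @property
    def params(self):
        ps = []
        for c, _, _ in self.stages:
            ps += c.params
        return ps + self.dense.params

    def forward(self, x):
        ph, pw = self.hw[0] - x.shape[2], self.hw[1] - x.shape[3]
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
        for c, r, p in self.stages:
            x = p.forward(r.forward(c.forward(x)))
        self._shape = x.shape
        return self.dense.forward(x.reshape(x.shape[0], -1))

    def backward(self, dcode):
        d = self.dense.backward(dcode).reshape(self._shape)
        for c, r, p in reversed(self.stages):
            d = c.backward(r.backward(p.backward(d)))
        ph, pw = self.hw[0] - self.hw_in[0], self.hw[1] - self.hw_in[1]
        if ph or pw:
            d = d[:, :, : self.hw_in[0], : self.hw_in[1]]
        return d


class _Decoder:
    """Dense from the code, then four conv3x3+ReLU+upsample stages, 1x1 out."""

    def __init__(self, features, code, hw, rng):
        self.hw_in = tuple(hw)
        hw = _pad16(hw)
        h, w = hw
        self.hw = hw
        F = features
        self._shape0 = (F, h // 16, w // 16)
        self.dense = Dense(code, int(np.prod(self._shape0)), rng)
        self.relu0 = ReLU()
        self.stages = []
        for _ in range(4):
            self.stages.append((Upsample2(), Conv2D(F, F, 3, rng), ReLU()))
        self.out = Conv2D(F, 1, 1, rng)

    @property
    def params(self):
        ps = self.dense.params.copy()
        for _, c, _ in self.stages:
            ps += c.params
        return ps + self.out.params

    def forward(self, code):
        n = code.shape[0]
        x = self.relu0.forward(self.dense.forward(code)).reshape((n,) + self._shape0)
        for u, c, r in self.stages:
            x = r.forward(c.forward(u.forward(x)))
        logits = self.out.forward(x)
        return logits[:, :, : self.hw_in[0], : self.hw_in[1]]

    def backward(self, dlogits):
        ph, pw = self.hw[0] - self.hw_in[0], self.hw[1] - self.hw_in[1]
        if ph or pw:
            dlogits = np.pad(dlogits, ((0, 0), (0, 0), (0, ph), (0, pw)))
        d = self.out.backward(dlogits)
        for u, c, r in reversed(self.stages):
            d = u.backward(c.backward(r.backward(d)))
        n = d.shape[0]
        return self.dense.backward(self.relu0.backward(d.reshape(n, -1)))


class ConvAutoEncoder:
    """Spatial-prior auto-encoder over lesion label maps.

    Encoder: four conv+max-pool stages and a dense bottleneck producing a
    fixed-length code (the spatial-covariance summary); decoder mirrors it
    with conv+upsample stages and a sigmoid output.  ReLU on all convolutions.
    """

    def __init__(self, hw: tuple[int, int], features: int = 16, code: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hw, self.features, self.code = tuple(hw), features, code
        self.encoder = _Encoder(1, features, code, hw, rng)
        self.decoder = _Decoder(features, code, hw, rng)

    @property
    def params(self):
        return self.encoder.params + self.decoder.params

    def forward(self, x):
        return self.decoder.forward(self.encoder.forward(x))

    def backward(self, dlogits):
        self.encoder.backward(self.decoder.backward(dlogits))

    def config(self) -> dict:
        return {
            "kind": "conv_autoencoder",
            "hw": list(self.hw),
            "features": self.features,
            "code": self.code,
        }


class ImageEncoder:
    """Inference-side encoder: same topology as the prior encoder, independent
    parameters, mapping an intensity image to the prior's latent code."""

    def __init__(self, hw: tuple[int, int], features: int = 16, code: int = 64, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.hw, self.features, self.code = tuple(hw), features, code
        self.encoder = _Encoder(1, features, code, hw, rng)

    @property
    def params(self):
        return self.encoder.params

    def forward(self, x):
        return self.encoder.forward(x)

    def backward(self, dcode):
        return self.encoder.backward(dcode)

    def config(self) -> dict:
        return {
            "kind": "image_encoder",
            "hw": list(self.hw),
            "features": self.features,
            "code": self.code,
        }


def state_arrays(model) -> list[np.ndarray]:
    return [p.value for p in model.params]


def load_state(model, arrays) -> None:
    params = model.params
    if len(params) != len(arrays):
        raise ValueError(f"state has {len(arrays)} arrays, model expects {len(params)}")
    for p, a in zip(params, arrays):
        if p.value.shape != a.shape:
            raise ValueError(f"shape mismatch {p.value.shape} vs {a.shape}")
        p.value[...] = a
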