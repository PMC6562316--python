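"""Layer primitives with explicit backward passes (float32, deterministic)."""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Conv2D",
    "Dense",
    "ReLU",
    "MaxPool2",
    "Upsample2",
    "Adadelta",
    "sigmoid",
    "sigmoid_bce",
]

F32 = np.float32


class Param:
    """A trainable array with an accumulated gradient."""

    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=F32)
        self.grad = np.zeros_like(self.value)


def _im2col(x: np.ndarray, k: int) -> np.ndarray:
    """(N, C, H, W) -> (N, H*W, C*k*k) patch matrix for same-size conv."""
    n, c, h, w = x.shape
    p = k // 2
    xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (N, C, H, W, k, k)
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h * w, c * k * k)


class Conv2D:
    """Same-padded k x k convolution (k odd), He-initialized."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (cin * k * k))
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = Param(rng.normal(0.0, scale, size=(cout, cin * k * k)))
        self.b = Param(np.zeros(cout))
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        self._shape = x.shape
        cols = _im2col(x, self.k).reshape(n * h * w, -1)  # (N*HW, C*k*k)
        self._cols = cols
        y = cols @ self.W.value.T + self.b.value  # (N*HW, cout)
        return y.reshape(n, h * w, self.cout).transpose(0, 2, 1).reshape(n, self.cout, h, w)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        k, p = self.k, self.k // 2
        dyf = dy.reshape(n, self.cout, h * w).transpose(0, 2, 1).reshape(n * h * w, self.cout)
        cols = self._cols
        self._cols = None
        self.W.grad += dyf.T @ cols
        self.b.grad += dyf.sum(axis=0)
        dcols = dyf @ self.W.value  # (N*HW, C*k*k)
        dc6 = dcols.reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
        dxp = np.zeros((n, c, h + 2 * p, w + 2 * p), dtype=F32)
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dc6[:, :, :, :, i, j]
        return dxp[:, :, p : p + h, p : p + w]


class Dense:
    def __init__(self, din: int, dout: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / din), size=(din, dout)))
        self.b = Param(np.zeros(dout))
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.W.grad += self._x.T @ dy
        self.b.grad += dy.sum(axis=0)
        return dy @ self.W.value.T


class ReLU:
    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2:
    """2x2 max pooling; ties resolve to the first maximum (deterministic)."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        flat = xr.reshape(n, c, h // 2, w // 2, 4)
        self._argmax = flat.argmax(axis=-1)
        self._shape = x.shape
        return flat.max(axis=-1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        one_hot = np.eye(4, dtype=F32)[self._argmax]  # (n, c, h2, w2, 4)
        d = one_hot * dy[..., None]
        d = d.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return d.reshape(n, c, h, w)


class Upsample2:
    """Nearest-neighbour 2x upsampling; backward sums each 2x2 block."""

    params: list = []

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c, h, w = dy.shape
        return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def sigmoid_bce(logits: np.ndarray, targets: np.ndarray, pos_weight: float = 1.0):
    """Mean binary cross-entropy from logits; returns (loss, dlogits).

    ``pos_weight`` > 1 up-weights the positive class — the usual remedy for
    sparse foregrounds such as lesion masks, where unweighted cross-entropy
    is minimized by predicting background everywhere.
    """
    z = logits.astype(np.float64)
    y = targets.astype(np.float64)
    elem = np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))
    w = 1.0 + (pos_weight - 1.0) * y
    loss = np.mean(w * elem)
    dz = w * (sigmoid(z) - y) / z.size
    return float(loss), dz.astype(F32)


class Adadelta:
    """Adadelta (Zeiler): per-parameter adaptive step without a learning rate.

    rho follows the original formulation; eps defaults to 1e-4, which sets
    the scale of the first updates (sqrt(eps)) high enough that short
    training schedules leave the warm-up phase quickly.  lr is a global
    multiplier kept at 1.0.
    """

    def __init__(self, params, rho: float = 0.95, eps: float = 1e-4, lr: float = 1.0):
        self.params = list(params)
        self.rho, self.eps, self.lr = rho, eps, lr
        self._eg = [np.zeros_like(p.value) for p in self.params]
        self._ed = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self._eg, self._ed):
            g = p.grad
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            dx = -np.sqrt((ed + self.eps) / (eg + self.eps)) * g
            ed *= self.rho
            ed += (1 - self.rho) * dx * dx
            p.value += self.lr * dx
            p.grad[...] = 0.0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0
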