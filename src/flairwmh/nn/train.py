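"""Mini-batch training loop shared by the two networks."""

from __future__ import annotations

import numpy as np

from .layers import Adadelta, sigmoid_bce

__all__ = ["train_model"]


def train_model(
    model,
    X: np.ndarray,
    Y: np.ndarray,
    *,
    epochs: int,
    batch_size: int = 16,
    seed: int = 0,
    trainable=None,
    augment_fn=None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
    lr: float = 1.0,
    pos_weight: float = 1.0,
) -> dict:
    """Train with Adadelta on per-pixel sigmoid cross-entropy.

    ``trainable`` restricts the optimizer to a subset of parameters (used to
    keep the prior decoder frozen during inference-network training);
    gradients accumulated on frozen parameters are discarded each step.
    ``augment_fn(batch, rng) -> batch`` corrupts samples per mini-batch.
    Returns epoch-mean training losses (and validation losses if ``val``).
    """
    n = X.shape[0]
    if n == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(seed)
    params = list(model.params) if trainable is None else list(trainable)
    opt = Adadelta(params, lr=lr)
    all_params = list(model.params)
    history: dict = {"loss": [], "val_loss": []}
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            xb, yb = X[idx], Y[idx]
            if augment_fn is not None:
                xb = augment_fn(xb, rng)
            logits = model.forward(xb)
            loss, dlogits = sigmoid_bce(logits, yb, pos_weight=pos_weight)
            model.backward(dlogits)
            opt.step()
            for p in all_params:  # drop gradients on frozen parameters
                p.grad[...] = 0.0
            losses.append(loss)
        history["loss"].append(float(np.mean(losses)))
        if val is not None:
            history["val_loss"].append(evaluate_loss(model, *val, batch_size=batch_size, pos_weight=pos_weight))
    if val is None:
        history.pop("val_loss")
    return history


def evaluate_loss(model, X, Y, batch_size: int = 16, pos_weight: float = 1.0) -> float:
    total, count = 0.0, 0
    for start in range(0, X.shape[0], batch_size):
        xb, yb = X[start : start + batch_size], Y[start : start + batch_size]
        loss, _ = sigmoid_bce(model.forward(xb), yb, pos_weight=pos_weight)
        total += loss * xb.shape[0]
        count += xb.shape[0]
    return total / max(count, 1)
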