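"""Losses, the Adam optimizer, and the mini-batch training loop."""

from __future__ import annotations

import hashlib
from typing import Callable, Optional

import numpy as np

from .layers import Param, Sequential

_EPS = 1e-7


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns NaN/inf during training."""


def bce_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy over all elements, and its gradient.

    ``pred`` must already be probabilities (sigmoid output layer).
    """
    p = np.clip(pred, _EPS, 1.0 - _EPS)
    loss = -np.mean(target * np.log(p) + (1.0 - target) * np.log(1.0 - p))
    grad = (p - target) / (p * (1.0 - p)) / p.size
    return float(loss), grad


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error over all elements, and its gradient."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    return loss, 2.0 * diff / diff.size


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ) -> None:
        self.params = [p for p in params if p.trainable]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * p.grad
            v *= self.beta2
            v += (1.0 - self.beta2) * p.grad * p.grad
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0


LossFn = Callable[[np.ndarray, np.ndarray], tuple[float, np.ndarray]]


def fit(
    model: Sequential,
    x: np.ndarray,
    y: np.ndarray,
    loss_fn: LossFn,
    epochs: int = 40,
    batch_size: int = 256,
    val_fraction: float = 0.1,
    lr: float = 1e-3,
    seed: int = 0,
    callback: Optional[Callable[[int, float, Optional[float]], None]] = None,
) -> dict:
    """Train ``model`` in place; returns a per-epoch loss history.

    The training array is split 90/10 into train/validation (seeded); each
    epoch reshuffles the training part, iterates full batches plus a final
    partial one, and records mean train loss and validation loss.  A
    non-finite loss aborts with :class:`TrainingDivergedError`.
    """
    n = len(x)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = int(round(n * val_fraction))
    val_idx, train_idx = order[:n_val], order[n_val:]
    x_val, y_val = x[val_idx], y[val_idx]
    x_train, y_train = x[train_idx], y[train_idx]

    optimizer = Adam(model.params(), lr=lr)
    history: dict = {"train_loss": [], "val_loss": []}
    for epoch in range(epochs):
        perm = rng.permutation(len(x_train))
        batch_losses = []
        for start in range(0, len(x_train), batch_size):
            idx = perm[start : start + batch_size]
            pred = model.forward(x_train[idx], training=True)
            loss, grad = loss_fn(pred, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite loss {loss} at epoch {epoch + 1}"
                )
            optimizer.zero_grad()
            model.backward(grad)
            optimizer.step()
            batch_losses.append(loss)
        train_loss = float(np.mean(batch_losses))
        val_loss = None
        if len(x_val):
            val_pred = predict(model, x_val, batch_size)
            val_loss, _ = loss_fn(val_pred, y_val)
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        if callback is not None:
            callback(epoch, train_loss, val_loss)
    return history


def predict(model: Sequential, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Batched forward pass without training-mode side effects."""
    chunks = [
        model.forward(x[start : start + batch_size])
        for start in range(0, len(x), batch_size)
    ]
    return np.concatenate(chunks, axis=0)


def weight_hash(model: Sequential) -> str:
    """SHA-256 of all weights; detects any in-place modification."""
    digest = hashlib.sha256()
    for p in model.params():
        digest.update(np.ascontiguousarray(p.value).tobytes())
    return digest.hexdigest()
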