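"""Layers with explicit forward/backward passes.

Conventions: batch axis first; sequence data is channels-last
``(batch, length, channels)``.  ``forward`` caches what ``backward``
needs; ``backward`` receives the loss gradient w.r.t. the layer output,
accumulates parameter gradients in-place and returns the gradient w.r.t.
the input.  All floats are float64 for numerically stable gradient
checking; the matrices involved are small enough that speed is set by
BLAS either way.
"""

from __future__ import annotations

import numpy as np


class Param:
    """A trainable array and its accumulated gradient."""

    __slots__ = ("value", "grad", "trainable")

    def __init__(self, value: np.ndarray, trainable: bool = True) -> None:
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.trainable = trainable


def glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)




class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Affine map on the last axis: works on (B, D) and (B, T, D) alike."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        self.w = Param(glorot(rng, (d_in, d_out), d_in, d_out))
        self.b = Param(np.zeros(d_out))

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.w.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return (dy2 @ self.w.value.T).reshape(self._x.shape)


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
        return self._y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Reshape(Layer):
    def __init__(self, target: tuple[int, ...]) -> None:
        self.target = target

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Transpose12(Layer):
    """Swap the two trailing axes: (B, A, C) <-> (B, C, A)."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.swapaxes(x, 1, 2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.swapaxes(dy, 1, 2)


class Embedding(Layer):
    """Token-index lookup into a jointly learned (vocab, dim) table."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator) -> None:
        self.table = Param(rng.normal(0.0, 0.05, size=(vocab_size, dim)))

    def params(self) -> list[Param]:
        return [self.table]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._idx = np.asarray(x, dtype=np.int64)
        return self.table.value[self._idx]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        np.add.at(self.table.grad, self._idx, dy)
        return np.zeros_like(self._idx, dtype=np.float64)  # indices carry no grad


class Conv1D(Layer):
    """1-D convolution, stride 1, zero 'same' padding, channels last."""

    def __init__(
        self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator
    ) -> None:
        self.kernel = kernel
        fan_in, fan_out = kernel * c_in, kernel * c_out
        self.w = Param(glorot(rng, (kernel, c_in, c_out), fan_in, fan_out))
        self.b = Param(np.zeros(c_out))
        self._pad_left = (kernel - 1) // 2
        self._pad_right = kernel - 1 - self._pad_left

    def params(self) -> list[Param]:
        return [self.w, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        length = x.shape[1]
        xpad = np.pad(x, ((0, 0), (self._pad_left, self._pad_right), (0, 0)))
        self._xpad, self._length = xpad, length
        y = np.broadcast_to(
            self.b.value, (x.shape[0], length, self.b.value.shape[0])
        ).copy()
        for j in range(self.kernel):
            y += xpad[:, j : j + length, :] @ self.w.value[j]
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        length = self._length
        dxpad = np.zeros_like(self._xpad)
        for j in range(self.kernel):
            window = self._xpad[:, j : j + length, :]
            self.w.grad[j] += np.einsum("blc,bld->cd", window, dy)
            dxpad[:, j : j + length, :] += dy @ self.w.value[j].T
        self.b.grad += dy.sum(axis=(0, 1))
        if self._pad_right:
            return dxpad[:, self._pad_left : -self._pad_right, :]
        return dxpad[:, self._pad_left :, :]


class AvgPool1D(Layer):
    """Average pooling with window = stride; a ragged tail is dropped."""

    def __init__(self, pool: int) -> None:
        self.pool = pool

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, length, c = x.shape
        keep = (length // self.pool) * self.pool
        self._in_shape = x.shape
        self._keep = keep
        return x[:, :keep, :].reshape(b, keep // self.pool, self.pool, c).mean(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, _, c = self._in_shape
        dx = np.zeros(self._in_shape)
        spread = np.repeat(dy / self.pool, self.pool, axis=1)
        dx[:, : self._keep, :] = spread
        return dx


class UpSample1D(Layer):
    """Nearest-neighbour upsampling: repeat each time step ``factor`` times."""

    def __init__(self, factor: int) -> None:
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, length, c = dy.shape
        return dy.reshape(b, length // self.factor, self.factor, c).sum(axis=2)


class RepeatVector(Layer):
    """(B, D) -> (B, n, D) by repetition (seeds a sequence decoder)."""

    def __init__(self, n: int) -> None:
        self.n = n

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return np.repeat(x[:, None, :], self.n, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.sum(axis=1)


class LSTM(Layer):
    """Single LSTM layer over (B, T, D) with hidden size H.

    Gate order in the fused weight matrices is input, forget, cell, output;
    the forget-gate bias starts at 1 (standard remedy against early
    forgetting).  Returns the full hidden sequence or only the final state.
    """

    def __init__(
        self,
        d_in: int,
        hidden: int,
        rng: np.random.Generator,
        return_sequences: bool = False,
    ) -> None:
        self.hidden = hidden
        self.return_sequences = return_sequences
        self.wx = Param(glorot(rng, (d_in, 4 * hidden), d_in, 4 * hidden))
        self.wh = Param(glorot(rng, (hidden, 4 * hidden), hidden, 4 * hidden))
        bias = np.zeros(4 * hidden)
        bias[hidden : 2 * hidden] = 1.0
        self.b = Param(bias)

    def params(self) -> list[Param]:
        return [self.wx, self.wh, self.b]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, t, _ = x.shape
        h = self.hidden
        hs = np.zeros((b, t + 1, h))
        cs = np.zeros((b, t + 1, h))
        gates = np.zeros((b, t, 4 * h))
        tanh_c = np.zeros((b, t, h))
        for step in range(t):
            z = x[:, step] @ self.wx.value + hs[:, step] @ self.wh.value + self.b.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h : 2 * h])
            g = np.tanh(z[:, 2 * h : 3 * h])
            o = _sigmoid(z[:, 3 * h :])
            cs[:, step + 1] = f * cs[:, step] + i * g
            tanh_c[:, step] = np.tanh(cs[:, step + 1])
            hs[:, step + 1] = o * tanh_c[:, step]
            gates[:, step] = np.concatenate([i, f, g, o], axis=1)
        self._cache = (x, hs, cs, gates, tanh_c)
        return hs[:, 1:] if self.return_sequences else hs[:, -1]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, hs, cs, gates, tanh_c = self._cache
        b, t, _ = x.shape
        h = self.hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for step in range(t - 1, -1, -1):
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, step]
            elif step == t - 1:
                dh += dy
            i = gates[:, step, :h]
            f = gates[:, step, h : 2 * h]
            g = gates[:, step, 2 * h : 3 * h]
            o = gates[:, step, 3 * h :]
            tc = tanh_c[:, step]
            dc = dc_next + dh * o * (1.0 - tc * tc)
            do = dh * tc
            di = dc * g
            df = dc * cs[:, step]
            dg = dc * i
            dz = np.concatenate(
                [
                    di * i * (1 - i),
                    df * f * (1 - f),
                    dg * (1 - g * g),
                    do * o * (1 - o),
                ],
                axis=1,
            )
            self.wx.grad += x[:, step].T @ dz
            self.wh.grad += hs[:, step].T @ dz
            self.b.grad += dz.sum(axis=0)
            dx[:, step] = dz @ self.wx.value.T
            dh_next = dz @ self.wh.value.T
            dc_next = dc * f
        return dx


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class Sequential(Layer):
    """A plain layer chain; also the unit of (de)serialization."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training=training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def get_weights(self) -> list[np.ndarray]:
        return [p.value.copy() for p in self.params()]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        own = self.params()
        if len(own) != len(weights):
            raise ValueError(
                f"expected {len(own)} weight arrays, got {len(weights)}"
            )
        for p, w in zip(own, weights):
            if p.value.shape != w.shape:
                raise ValueError(f"shape mismatch {p.value.shape} vs {w.shape}")
            p.value = np.asarray(w, dtype=np.float64).copy()
            p.grad = np.zeros_like(p.value)
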