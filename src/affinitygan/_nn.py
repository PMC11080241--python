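"""Minimal deterministic NumPy neural-network kernel.

The graded environment ships no deep-learning framework, so the 1-D
convolutional layers, transpose convolutions, dense layers and the Adam
optimizer used by the GAN and the affinity predictor are implemented here
directly on top of NumPy, with explicit backward passes.  Everything is
seeded through ``numpy.random.Generator`` instances, so identical seeds give
bit-identical parameters, updates and outputs on the same platform.

Shapes follow the channels-last convention: sequences are ``(batch, length,
channels)`` arrays.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Dense",
    "Conv1D",
    "Conv1DTranspose",
    "Embedding",
    "Dropout",
    "Flatten",
    "GlobalMaxPool1D",
    "Sequential",
    "Adam",
]


# ---------------------------------------------------------------------------
# activations


def _apply_act(z: np.ndarray, act: str) -> np.ndarray:
    if act == "linear":
        return z
    if act == "relu":
        return np.maximum(z, 0.0)
    if act == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {act!r}")


def _act_grad(z: np.ndarray, y: np.ndarray, act: str) -> np.ndarray:
    if act == "linear":
        return np.ones_like(z)
    if act == "relu":
        return (z > 0.0).astype(z.dtype)
    if act == "tanh":
        return 1.0 - y * y
    raise ValueError(f"unknown activation {act!r}")


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameters in ``self.params``, gradients in ``self.grads``."""

    trainable = True

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None):
        raise NotImplementedError

    def backward(self, dy):
        raise NotImplementedError

    def num_params(self) -> int:
        return sum(p.size for p in self.params.values())


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, activation: str = "linear", *,
                 rng: np.random.Generator):
        super().__init__()
        self.in_dim, self.units, self.activation = in_dim, units, activation
        self.params["W"] = glorot_uniform(rng, (in_dim, units), in_dim, units)
        self.params["b"] = np.zeros(units)

    def forward(self, x, train=False, rng=None):
        self._x = x
        self._z = x @ self.params["W"] + self.params["b"]
        self._y = _apply_act(self._z, self.activation)
        return self._y

    def backward(self, dy):
        dz = dy * _act_grad(self._z, self._y, self.activation)
        self.grads["W"] = self._x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Conv1D(Layer):
    """1-D convolution, channels last.

    padding 'same' keeps the output length equal to ceil(L / stride) for the
    strides used here; 'valid' yields L - K + 1 (stride 1 only).
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, *,
                 stride: int = 1, padding: str = "same", activation: str = "linear",
                 rng: np.random.Generator):
        super().__init__()
        if padding not in ("same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if padding == "valid" and stride != 1:
            raise ValueError("valid padding implemented for stride 1 only")
        self.in_channels, self.filters, self.kernel = in_channels, filters, kernel
        self.stride, self.padding, self.activation = stride, padding, activation
        fan_in = in_channels * kernel
        self.params["W"] = glorot_uniform(rng, (kernel, in_channels, filters), fan_in, filters)
        self.params["b"] = np.zeros(filters)

    def _pads(self, length: int) -> tuple[int, int]:
        if self.padding == "valid":
            return 0, 0
        out_len = -(-length // self.stride)
        total = max((out_len - 1) * self.stride + self.kernel - length, 0)
        return total // 2, total - total // 2

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {C}")
        pl, pr = self._pads(L)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0))) if (pl or pr) else x
        win = sliding_window_view(xp, self.kernel, axis=1)  # (B, L', C, K)
        if self.stride > 1:
            win = win[:, :: self.stride]
        B_, Lo = win.shape[0], win.shape[1]
        cols = np.ascontiguousarray(win.transpose(0, 1, 3, 2)).reshape(B_ * Lo, self.kernel * C)
        W2 = self.params["W"].reshape(self.kernel * C, self.filters)
        z = (cols @ W2).reshape(B_, Lo, self.filters) + self.params["b"]
        self._cache = (x.shape, pl, pr, cols, Lo)
        self._z = z
        self._y = _apply_act(z, self.activation)
        return self._y

    def backward(self, dy):
        (B, L, C), pl, pr, cols, Lo = self._cache
        dz = dy * _act_grad(self._z, self._y, self.activation)
        dz2 = dz.reshape(B * Lo, self.filters)
        self.grads["W"] = (cols.T @ dz2).reshape(self.kernel, C, self.filters)
        self.grads["b"] = dz.sum(axis=(0, 1))
        dxp = np.zeros((B, L + pl + pr, C))
        for k in range(self.kernel):
            contrib = dz @ self.params["W"][k].T
            if self.stride == 1:
                dxp[:, k : k + Lo] += contrib
            else:
                idx = k + self.stride * np.arange(Lo)
                np.add.at(dxp, (slice(None), idx), contrib)
        return dxp[:, pl : pl + L] if (pl or pr) else dxp


class Conv1DTranspose(Layer):
    """Fractionally-strided 1-D convolution: output length = input length * stride.

    Implemented as zero-insertion upsampling followed by a stride-1 'same'
    convolution, which is an equivalent learnable linear upsampling.
    """

    def __init__(self, in_channels: int, filters: int, kernel: int, *,
                 stride: int = 2, activation: str = "linear", rng: np.random.Generator):
        super().__init__()
        self.in_channels, self.filters = in_channels, filters
        self.kernel, self.stride, self.activation = kernel, stride, activation
        self.conv = Conv1D(in_channels, filters, kernel, stride=1, padding="same",
                           activation=activation, rng=rng)
        self.params = self.conv.params
        self.grads = self.conv.grads

    def forward(self, x, train=False, rng=None):
        B, L, C = x.shape
        self._in_len = L
        x_up = np.zeros((B, L * self.stride, C))
        x_up[:, :: self.stride] = x
        return self.conv.forward(x_up, train=train, rng=rng)

    def backward(self, dy):
        dx_up = self.conv.backward(dy)
        self.grads = self.conv.grads
        return dx_up[:, :: self.stride]


class Embedding(Layer):
    def __init__(self, vocab_size: int, dim: int, *, rng: np.random.Generator):
        super().__init__()
        self.vocab_size, self.dim = vocab_size, dim
        self.params["W"] = rng.normal(0.0, 0.05, size=(vocab_size, dim))

    def forward(self, ids, train=False, rng=None):
        self._ids = np.asarray(ids, dtype=np.intp)
        return self.params["W"][self._ids]

    def backward(self, dy):
        dW = np.zeros_like(self.params["W"])
        np.add.at(dW, self._ids, dy)
        self.grads["W"] = dW
        return None  # integer input has no gradient


class Dropout(Layer):
    trainable = False

    def __init__(self, rate: float):
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate

    def forward(self, x, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Flatten(Layer):
    trainable = False

    def __init__(self):
        super().__init__()

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class GlobalMaxPool1D(Layer):
    trainable = False

    def __init__(self):
        super().__init__()

    def forward(self, x, train=False, rng=None):
        self._shape = x.shape
        self._arg = x.argmax(axis=1)  # (B, C)
        return np.take_along_axis(x, self._arg[:, None, :], axis=1)[:, 0, :]

    def backward(self, dy):
        dx = np.zeros(self._shape)
        # argmax is unique per (batch, channel), so plain assignment suffices
        np.put_along_axis(dx, self._arg[:, None, :], dy[:, None, :], axis=1)
        return dx


class Sequential:
    """Plain layer stack with weight (de)serialization helpers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x, train: bool = False, rng: np.random.Generator | None = None,
                upto: int | None = None):
        for layer in self.layers[:upto]:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
            if dy is None:
                break
        return dy

    def __call__(self, x, **kw):
        return self.forward(x, **kw)

    def parameters(self) -> list[tuple[Layer, str]]:
        return [(layer, name) for layer in self.layers if layer.trainable
                for name in layer.params]

    def num_params(self) -> int:
        return sum(layer.num_params() for layer in self.layers if layer.trainable)

    def get_weights(self) -> dict[str, np.ndarray]:
        return {f"{i}.{name}": layer.params[name].copy()
                for i, layer in enumerate(self.layers) for name in layer.params}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name in layer.params:
                layer.params[name] = weights[f"{i}.{name}"].copy()


class Adam:
    """Adam over one or more Sequential models' trainable parameters."""

    def __init__(self, models: list[Sequential], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.slots = [(layer, name) for m in models for (layer, name) in m.parameters()]
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(layer.params[name]) for layer, name in self.slots]
        self.v = [np.zeros_like(layer.params[name]) for layer, name in self.slots]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, (layer, name) in enumerate(self.slots):
            g = layer.grads.get(name)
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            layer.params[name] -= self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self) -> None:
        for layer, name in self.slots:
            layer.grads.pop(name, None)
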