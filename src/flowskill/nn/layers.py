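"""Minimal numpy layers for 1-D time-series networks.

All layers operate on arrays shaped (batch, time, channels) unless noted,
implement ``forward``/``backward`` with cached activations, and expose
their parameters as ``(param, grad, weight_decay)`` triples.  Convolutions
use "same" padding by default, so the output time length is
``ceil(L / stride)``; the realised input/output lengths are recorded on the
layer for shape introspection.
"""

from __future__ import annotations

import math

import numpy as np


class Layer:
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def params_grads(self) -> list[tuple[np.ndarray, np.ndarray, bool]]:
        return []


def relu(z: np.ndarray) -> np.ndarray:
    """max(0, z) elementwise."""
    return np.maximum(0.0, np.asarray(z))


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Logistic function, bounded in (0, 1)."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """exp(z_i) / Σ_j exp(z_j); rows sum to 1."""
    z = np.asarray(z, dtype=float)
    z = z - np.max(z, axis=axis, keepdims=True)
    e = np.exp(z)
    return e / np.sum(e, axis=axis, keepdims=True)


def same_pad_amount(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out_len = math.ceil(length / stride)
    total = max((out_len - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2


def conv_output_length(length: int, kernel: int, padding: int, stride: int) -> int:
    """(L − F + 2P) / S + 1, the valid-convolution shape rule."""
    return (length - kernel + 2 * padding) // stride + 1


class Conv1D(Layer):
    """1-D convolution over time, same padding, optional stride."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, stride: int = 1,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = math.sqrt(2.0 / (kernel * in_ch))
        self.W = rng.normal(0.0, scale, size=(kernel, in_ch, out_ch))
        self.b = np.zeros(out_ch)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self.kernel, self.stride = kernel, stride
        self.in_ch, self.out_ch = in_ch, out_ch
        self.input_length: int | None = None
        self.output_length: int | None = None

    def _cols(self, xp: np.ndarray, out_len: int) -> np.ndarray:
        n, _, c = xp.shape
        cols = np.empty((n, out_len, self.kernel, c), dtype=xp.dtype)
        for j in range(self.kernel):
            cols[:, :, j, :] = xp[:, j : j + out_len * self.stride : self.stride, :]
        return cols.reshape(n, out_len, self.kernel * c)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, L, c = x.shape
        pl, pr = same_pad_amount(L, self.kernel, self.stride)
        xp = np.pad(x, ((0, 0), (pl, pr), (0, 0)))
        out_len = math.ceil(L / self.stride)  # same-padding shape rule
        self.input_length, self.output_length = L, out_len
        self._pl, self._xp_shape = pl, xp.shape
        cols = self._cols(xp, out_len)
        self._cols_cache = cols
        return cols @ self.W.reshape(-1, self.out_ch) + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, out_len, _ = dy.shape
        Wmat = self.W.reshape(-1, self.out_ch)
        self.dW[...] = (
            self._cols_cache.reshape(-1, Wmat.shape[0]).T @ dy.reshape(-1, self.out_ch)
        ).reshape(self.W.shape)
        self.db[...] = dy.sum(axis=(0, 1))
        dcols = (dy @ Wmat.T).reshape(n, out_len, self.kernel, self.in_ch)
        dxp = np.zeros(self._xp_shape, dtype=dy.dtype)
        for j in range(self.kernel):
            dxp[:, j : j + out_len * self.stride : self.stride, :] += dcols[:, :, j, :]
        pl = self._pl
        return dxp[:, pl : pl + self.input_length, :]

    def params_grads(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]


class BatchNorm1D(Layer):
    """Per-channel batch normalisation over (batch, time)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum, self.eps = momentum, eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._istd
        self._axes = axes
        self._m = x.size // x.shape[-1]
        return self.gamma * self._xhat + self.beta

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dgamma[...] = (dy * self._xhat).sum(axis=self._axes)
        self.dbeta[...] = dy.sum(axis=self._axes)
        m = self._m
        dxhat = dy * self.gamma
        return (
            self._istd
            / m
            * (m * dxhat - dxhat.sum(axis=self._axes) - self._xhat * (dxhat * self._xhat).sum(axis=self._axes))
        )

    def params_grads(self):
        return [(self.gamma, self.dgamma, False), (self.beta, self.dbeta, False)]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class GlobalAveragePooling(Layer):
    """Collapse the time axis by averaging per channel."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._L = x.shape[1]
        return x.mean(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.repeat(dy[:, None, :], self._L, axis=1) / self._L


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.W = rng.normal(0.0, math.sqrt(2.0 / in_dim), size=(in_dim, out_dim))
        self.b = np.zeros(out_dim)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T

    def params_grads(self):
        return [(self.W, self.dW, True), (self.b, self.db, False)]


class Upsample1D(Layer):
    """Nearest-neighbour repeat along time (decoder counterpart of stride)."""

    def __init__(self, factor: int = 2):
        self.factor = factor

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._L = x.shape[1]
        return np.repeat(x, self.factor, axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, Lf, c = dy.shape
        return dy.reshape(n, self._L, self.factor, c).sum(axis=2)


class CropTime(Layer):
    """Trim the time axis to a target length (after upsampling round-off)."""

    def __init__(self, length: int):
        self.length = length

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._orig = x.shape[1]
        return x[:, : self.length, :]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        pad = self._orig - dy.shape[1]
        if pad:
            dy = np.pad(dy, ((0, 0), (0, pad), (0, 0)))
        return dy


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def params_grads(self):
        out = []
        for layer in self.layers:
            out += layer.params_grads()
        return out

    def iter_layers(self):
        for layer in self.layers:
            if isinstance(layer, (Sequential, ResidualBlock1D)):
                yield from layer.iter_layers()
            else:
                yield layer


class ResidualBlock1D(Layer):
    """y = ReLU(branch(x) + shortcut(x)); shortcut is identity when shapes match."""

    def __init__(self, branch: Sequential, shortcut: Sequential | None = None):
        self.branch = branch
        self.shortcut = shortcut

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        main = self.branch.forward(x, train)
        short = self.shortcut.forward(x, train) if self.shortcut is not None else x
        self._mask = (main + short) > 0
        return np.where(self._mask, main + short, 0.0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = dy * self._mask
        dx = self.branch.backward(dy)
        if self.shortcut is not None:
            dx = dx + self.shortcut.backward(dy)
        else:
            dx = dx + dy
        return dx

    def params_grads(self):
        out = self.branch.params_grads()
        if self.shortcut is not None:
            out += self.shortcut.params_grads()
        return out

    def iter_layers(self):
        yield from self.branch.iter_layers()
        if self.shortcut is not None:
            yield from self.shortcut.iter_layers()
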