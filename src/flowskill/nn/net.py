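"""Network assembly, losses, Adam optimiser and the training loop.

Architecture builders return a :class:`Network` holding a body (everything
up to the penultimate representation) and a head (the final dense+softmax
layer), so the same trained model can either predict through its softmax
head or hand its penultimate features to an external SVM.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    BatchNorm1D,
    Conv1D,
    CropTime,
    Dense,
    Flatten,
    GlobalAveragePooling,
    Layer,
    ReLU,
    ResidualBlock1D,
    Sequential,
    Upsample1D,
    softmax,
)
from .lstm import LSTMLayer


class Adam:
    def __init__(self, params_grads, lr: float = 3e-3, l2: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 clip_norm: float = 5.0):
        self.pg = params_grads
        self.lr, self.l2 = lr, l2
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.clip_norm = clip_norm
        self.m = [np.zeros_like(p) for p, _, _ in params_grads]
        self.v = [np.zeros_like(p) for p, _, _ in params_grads]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        scale = 1.0
        if self.clip_norm is not None:
            gnorm = np.sqrt(sum(float(np.sum(g * g)) for _, g, _ in self.pg))
            if gnorm > self.clip_norm:
                scale = self.clip_norm / gnorm
        for k, (p, g, decay) in enumerate(self.pg):
            g = g * scale
            grad = g + self.l2 * p if decay else g
            self.m[k] = b1 * self.m[k] + (1 - b1) * grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * grad * grad
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def softmax_cross_entropy(logits: np.ndarray, y_idx: np.ndarray) -> tuple[float, np.ndarray]:
    probs = softmax(logits)
    n = len(y_idx)
    loss = -np.mean(np.log(probs[np.arange(n), y_idx] + 1e-12))
    dlogits = probs.copy()
    dlogits[np.arange(n), y_idx] -= 1.0
    return loss, dlogits / n


def mse_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


class Network:
    """body → penultimate features; head → logits (softmax applied on demand)."""

    def __init__(self, body: Sequential, head: Layer | None, arch_id: str):
        self.body = body
        self.head = head
        self.arch_id = arch_id

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        z = self.body.forward(x, train)
        return self.head.forward(z, train) if self.head is not None else z

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.head is not None:
            dy = self.head.backward(dy)
        return self.body.backward(dy)

    def params_grads(self):
        out = self.body.params_grads()
        if self.head is not None:
            out += self.head.params_grads()
        return out

    def _bn_layers(self):
        return [l for l in self.body.iter_layers() if isinstance(l, BatchNorm1D)]

    def get_weights(self) -> list[np.ndarray]:
        state = [p.copy() for p, _, _ in self.params_grads()]
        for bn in self._bn_layers():
            state += [bn.running_mean.copy(), bn.running_var.copy()]
        return state

    def set_weights(self, weights: list[np.ndarray]) -> None:
        pg = self.params_grads()
        for (p, _, _), w in zip(pg, weights):
            p[...] = w
        rest = weights[len(pg):]
        for k, bn in enumerate(self._bn_layers()):
            bn.running_mean = rest[2 * k].copy()
            bn.running_var = rest[2 * k + 1].copy()

    def features(self, x: np.ndarray) -> np.ndarray:
        """Penultimate-layer representation (deterministic, eval mode)."""
        return self.body.forward(x, train=False)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return softmax(self.forward(x, train=False))

    def conv_layers(self):
        return [l for l in self.body.iter_layers() if isinstance(l, Conv1D)]


def build_cnn(input_shape: tuple[int, int], n_classes: int,
              filters: tuple[int, int] = (64, 64), kernels: tuple[int, int] = (7, 5),
              rng: np.random.Generator | None = None) -> Network:
    """Two Conv1D(BN, ReLU) blocks → global average pooling → dense softmax."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = rng or np.random.default_rng(0)
    _, d = input_shape
    body = Sequential([
        Conv1D(d, filters[0], kernels[0], rng=rng), BatchNorm1D(filters[0]), ReLU(),
        Conv1D(filters[0], filters[1], kernels[1], rng=rng), BatchNorm1D(filters[1]), ReLU(),
        GlobalAveragePooling(),
    ])
    return Network(body, Dense(filters[1], n_classes, rng=rng), "cnn")


def build_lstm(input_shape: tuple[int, int], n_classes: int, hidden: tuple[int, int] = (32, 32),
               use_peepholes: bool = True, rng: np.random.Generator | None = None) -> Network:
    """Two stacked LSTM blocks → dense softmax on the final hidden state."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = rng or np.random.default_rng(0)
    _, d = input_shape
    body = Sequential([
        LSTMLayer(d, hidden[0], return_sequences=True, use_peepholes=use_peepholes, rng=rng),
        LSTMLayer(hidden[0], hidden[1], return_sequences=False, use_peepholes=use_peepholes,
                  rng=rng),
    ])
    return Network(body, Dense(hidden[1], n_classes, rng=rng), "lstm")


def build_cnn_lstm(input_shape: tuple[int, int], n_classes: int,
                   filters: tuple[int, int] = (32, 32), kernels: tuple[int, int] = (7, 5),
                   hidden: tuple[int, int] = (32, 32), use_peepholes: bool = True,
                   rng: np.random.Generator | None = None) -> Network:
    """Two conv blocks (BN, ReLU) feeding two LSTM blocks, then softmax."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = rng or np.random.default_rng(0)
    _, d = input_shape
    body = Sequential([
        Conv1D(d, filters[0], kernels[0], rng=rng), BatchNorm1D(filters[0]), ReLU(),
        Conv1D(filters[0], filters[1], kernels[1], rng=rng), BatchNorm1D(filters[1]), ReLU(),
        LSTMLayer(filters[1], hidden[0], return_sequences=True, use_peepholes=use_peepholes,
                  rng=rng),
        LSTMLayer(hidden[0], hidden[1], return_sequences=False, use_peepholes=use_peepholes,
                  rng=rng),
    ])
    return Network(body, Dense(hidden[1], n_classes, rng=rng), "cnn_lstm")


def _res_block(in_ch: int, filters: int, rng: np.random.Generator) -> ResidualBlock1D:
    branch = Sequential([
        Conv1D(in_ch, filters, 7, rng=rng), BatchNorm1D(filters), ReLU(),
        Conv1D(filters, filters, 5, rng=rng), BatchNorm1D(filters), ReLU(),
        Conv1D(filters, filters, 3, rng=rng), BatchNorm1D(filters),
    ])
    shortcut = None
    if in_ch != filters:
        shortcut = Sequential([Conv1D(in_ch, filters, 1, rng=rng), BatchNorm1D(filters)])
    return ResidualBlock1D(branch, shortcut)


def build_resnet(input_shape: tuple[int, int], n_classes: int, filters: int = 32,
                 rng: np.random.Generator | None = None) -> Network:
    """Three residual blocks (output = transform(x) + shortcut(x)) → GAP → softmax."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    rng = rng or np.random.default_rng(0)
    _, d = input_shape
    body = Sequential([
        _res_block(d, filters, rng),
        _res_block(filters, filters, rng),
        _res_block(filters, filters, rng),
        GlobalAveragePooling(),
    ])
    return Network(body, Dense(filters, n_classes, rng=rng), "resnet")


def build_conv_autoencoder(input_shape: tuple[int, int], latent_channels: int = 16,
                           enc_filters: int = 32,
                           rng: np.random.Generator | None = None) -> tuple[Network, Network]:
    """Strided-conv encoder to a compressed latent code and a conv decoder back.

    One stride-2 stage halves the time axis (keeping enough temporal
    resolution for the latent code to retain short-scale motion texture),
    then a channel bottleneck.  Returns (encoder, autoencoder); the
    autoencoder shares the encoder's layers, and the flattened encoder
    output is the latent representation handed to the SVM head.  Raises if
    the latent code does not compress the input.
    """
    rng = rng or np.random.default_rng(0)
    T, d = input_shape
    t_half = -(-T // 2)
    latent_dim = t_half * latent_channels
    if latent_dim >= T * d:
        raise ValueError(f"latent dim {latent_dim} does not compress input {T * d}")
    enc_layers = [
        Conv1D(d, enc_filters, 5, stride=2, rng=rng), ReLU(),
        Conv1D(enc_filters, latent_channels, 3, rng=rng), ReLU(),
    ]
    dec_layers = [
        Upsample1D(2), Conv1D(latent_channels, enc_filters, 3, rng=rng), ReLU(),
        Conv1D(enc_filters, d, 5, rng=rng),
        CropTime(T),
    ]
    encoder = Network(Sequential(enc_layers + [Flatten()]), None, "convauto_encoder")
    auto = Network(Sequential(enc_layers + dec_layers), None, "convauto")
    return encoder, auto
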