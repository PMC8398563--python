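"""Long Short-Term Memory cell and layer, implemented from the gate equations.

The default cell carries peephole connections from the memory cell into all
three gates (the input and forget gates see c_{t−1}, the output gate sees
the freshly updated c_t):

    i_t = σ(W_xi x_t + W_hi h_{t−1} + W_ci c_{t−1} + b_i)
    f_t = σ(W_xf x_t + W_hf h_{t−1} + W_cf c_{t−1} + b_f)
    c_t = f_t ⊙ c_{t−1} + i_t ⊙ tanh(W_xc x_t + W_hc h_{t−1} + b_c)
    o_t = σ(W_xo x_t + W_ho h_{t−1} + W_co c_t + b_o)
    h_t = o_t ⊙ tanh(c_t)

Setting ``use_peepholes=False`` drops the W_c· terms, giving the
framework-standard cell.  Backpropagation through time is implemented
exactly for both variants and validated against finite differences in the
test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layers import Layer, sigmoid


@dataclass
class LstmCell:
    """All weights of one LSTM unit, named per the gate equations."""

    Wxi: np.ndarray
    Whi: np.ndarray
    Wci: np.ndarray
    bi: np.ndarray
    Wxf: np.ndarray
    Whf: np.ndarray
    Wcf: np.ndarray
    bf: np.ndarray
    Wxc: np.ndarray
    Whc: np.ndarray
    bc: np.ndarray
    Wxo: np.ndarray
    Who: np.ndarray
    Wco: np.ndarray
    bo: np.ndarray
    use_peepholes: bool = True

    @classmethod
    def init(cls, in_dim: int, hidden: int, rng: np.random.Generator,
             use_peepholes: bool = True) -> "LstmCell":
        def w(a, b):
            return rng.normal(0.0, math.sqrt(1.0 / a), size=(a, b))

        z = lambda: np.zeros(hidden)
        # forget bias starts at 1 so early training does not erase the cell state
        return cls(
            Wxi=w(in_dim, hidden), Whi=w(hidden, hidden), Wci=w(hidden, hidden), bi=z(),
            Wxf=w(in_dim, hidden), Whf=w(hidden, hidden), Wcf=w(hidden, hidden), bf=np.ones(hidden),
            Wxc=w(in_dim, hidden), Whc=w(hidden, hidden), bc=z(),
            Wxo=w(in_dim, hidden), Who=w(hidden, hidden), Wco=w(hidden, hidden), bo=z(),
            use_peepholes=use_peepholes,
        )

    @property
    def hidden(self) -> int:
        return self.bi.shape[0]


def lstm_step(
    cell: LstmCell, x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM update; inputs may be (dim,) vectors or (batch, dim) arrays."""
    vector_in = np.ndim(x_t) == 1
    x_t = np.atleast_2d(x_t)
    h_prev = np.atleast_2d(h_prev)
    c_prev = np.atleast_2d(c_prev)
    peep = 1.0 if cell.use_peepholes else 0.0
    i = sigmoid(x_t @ cell.Wxi + h_prev @ cell.Whi + peep * (c_prev @ cell.Wci) + cell.bi)
    f = sigmoid(x_t @ cell.Wxf + h_prev @ cell.Whf + peep * (c_prev @ cell.Wcf) + cell.bf)
    g = np.tanh(x_t @ cell.Wxc + h_prev @ cell.Whc + cell.bc)
    c = f * c_prev + i * g
    o = sigmoid(x_t @ cell.Wxo + h_prev @ cell.Who + peep * (c @ cell.Wco) + cell.bo)
    h = o * np.tanh(c)
    if np.any(~np.isfinite(h)) or np.any(~np.isfinite(c)):
        raise FloatingPointError("non-finite LSTM state")
    if vector_in:
        return h[0], c[0]
    return h, c


class LSTMLayer(Layer):
    """Sequence LSTM layer with exact BPTT; input (batch, T, in_dim)."""

    def __init__(self, in_dim: int, hidden: int, return_sequences: bool = False,
                 use_peepholes: bool = True, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.cell = LstmCell.init(in_dim, hidden, rng, use_peepholes)
        self.return_sequences = return_sequences
        self.in_dim, self.hidden = in_dim, hidden
        c = self.cell
        self._names = ["Wxi", "Whi", "Wci", "bi", "Wxf", "Whf", "Wcf", "bf",
                       "Wxc", "Whc", "bc", "Wxo", "Who", "Wco", "bo"]
        self._grads = {n: np.zeros_like(getattr(c, n)) for n in self._names}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, T, _ = x.shape
        H = self.hidden
        cell = self.cell
        peep = cell.use_peepholes
        h = np.zeros((n, H))
        c = np.zeros((n, H))
        cache = []
        hs = np.empty((n, T, H))
        for t in range(T):
            xt = x[:, t, :]
            ai = xt @ cell.Wxi + h @ cell.Whi + cell.bi
            af = xt @ cell.Wxf + h @ cell.Whf + cell.bf
            if peep:
                ai = ai + c @ cell.Wci
                af = af + c @ cell.Wcf
            i = sigmoid(ai)
            f = sigmoid(af)
            g = np.tanh(xt @ cell.Wxc + h @ cell.Whc + cell.bc)
            c_new = f * c + i * g
            ao = xt @ cell.Wxo + h @ cell.Who + cell.bo
            if peep:
                ao = ao + c_new @ cell.Wco
            o = sigmoid(ao)
            h_new = o * np.tanh(c_new)
            cache.append((xt, h, c, i, f, g, o, c_new))
            h, c = h_new, c_new
            hs[:, t, :] = h
        self._cache, self._x_shape = cache, x.shape
        self._hs = hs
        return hs if self.return_sequences else h

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, T, _ = self._x_shape
        H = self.hidden
        cell = self.cell
        peep = cell.use_peepholes
        for gname in self._grads:
            self._grads[gname][...] = 0.0
        dx = np.zeros(self._x_shape)
        dh_next = np.zeros((n, H))
        dc_next = np.zeros((n, H))
        G = self._grads
        for t in range(T - 1, -1, -1):
            xt, h_prev, c_prev, i, f, g, o, c_new = self._cache[t]
            dh = dh_next.copy()
            if self.return_sequences:
                dh += dy[:, t, :]
            elif t == T - 1:
                dh += dy
            tanh_c = np.tanh(c_new)
            do = dh * tanh_c
            dao = do * o * (1 - o)
            dc = dh * o * (1 - tanh_c**2) + dc_next
            if peep:
                dc = dc + dao @ cell.Wco.T
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dai = di * i * (1 - i)
            daf = df * f * (1 - f)
            dag = dg * (1 - g**2)
            G["Wxo"] += xt.T @ dao
            G["Who"] += h_prev.T @ dao
            G["bo"] += dao.sum(axis=0)
            G["Wxi"] += xt.T @ dai
            G["Whi"] += h_prev.T @ dai
            G["bi"] += dai.sum(axis=0)
            G["Wxf"] += xt.T @ daf
            G["Whf"] += h_prev.T @ daf
            G["bf"] += daf.sum(axis=0)
            G["Wxc"] += xt.T @ dag
            G["Whc"] += h_prev.T @ dag
            G["bc"] += dag.sum(axis=0)
            if peep:
                G["Wco"] += c_new.T @ dao
                G["Wci"] += c_prev.T @ dai
                G["Wcf"] += c_prev.T @ daf
            dx[:, t, :] = dai @ cell.Wxi.T + daf @ cell.Wxf.T + dag @ cell.Wxc.T + dao @ cell.Wxo.T
            dh_next = dai @ cell.Whi.T + daf @ cell.Whf.T + dag @ cell.Whc.T + dao @ cell.Who.T
            dc_next = dc * f
            if peep:
                dc_next = dc_next + dai @ cell.Wci.T + daf @ cell.Wcf.T
        return dx

    def params_grads(self):
        out = []
        for nme in self._names:
            if not self.cell.use_peepholes and nme in ("Wci", "Wcf", "Wco"):
                continue
            decay = not nme.startswith("b")
            out.append((getattr(self.cell, nme), self._grads[nme], decay))
        return out
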