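"""Frequency-domain feature reduction for the DFT/DCT + SVM methods.

A window sample is viewed as X ∈ R^{N×L} (N univariate series of length L —
the transpose of the W×240 window).  Each row is transformed to frequency
coefficients,

    DFT:  Y_k = Σ_{l=0}^{L−1} x_l · e^{−i 2π k l / L}
    DCT:  Y_k = x_0 / 2 + Σ_{l=1}^{L−1} x_l · cos[(π / L) · l · (k + 1/2)]

(the DCT form is the type-III cosine transform), and the F highest-magnitude
coefficients per row are kept — the most significant frequencies — then
concatenated row-major into one real vector of length N·F.  Ties in
magnitude break toward the lower frequency index so the reduction is
deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import dct as _scipy_dct

TRANSFORMS = ("dft", "dct")


@dataclass(frozen=True)
class FreqConfig:
    transform: str = "dft"
    n_peaks: int = 10

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValueError(f"transform must be one of {TRANSFORMS}")
        if self.n_peaks < 1:
            raise ValueError("n_peaks must be >= 1")


def dft_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise DFT coefficients (complex), Y_k = Σ x_l e^{−i2πkl/L}."""
    return np.fft.fft(np.asarray(X, dtype=float), axis=-1)


def dct_matrix(X: np.ndarray) -> np.ndarray:
    """Row-wise type-III DCT, Y_k = x_0/2 + Σ_{l≥1} x_l cos[π l (k+1/2) / L]."""
    # scipy's unnormalised DCT-III is y_k = x_0 + 2 Σ_{l≥1} x_l cos(π l (2k+1) / 2L)
    return 0.5 * _scipy_dct(np.asarray(X, dtype=float), type=3, axis=-1, norm=None)


def top_peaks(Y: np.ndarray, n_peaks: int) -> tuple[np.ndarray, np.ndarray]:
    """Keep the F largest-|Y| coefficients per row; returns (values, indices).

    Values are magnitudes (real) ordered by decreasing magnitude within each
    row; ties break toward lower frequency index.
    """
    mag = np.abs(Y)
    L = mag.shape[-1]
    if n_peaks >= L:
        raise ValueError(f"n_peaks {n_peaks} must be < series length {L}")
    # stable sort on (-magnitude) keeps the lower index first among ties
    order = np.argsort(-mag, axis=-1, kind="stable")[..., :n_peaks]
    vals = np.take_along_axis(mag, order, axis=-1)
    return vals, order


def freq_features(sample: np.ndarray, cfg: FreqConfig) -> np.ndarray:
    """Reduce one W×N window to the flat N·F frequency-feature vector.

    ``sample`` is a (W, N) window (time-major, as produced by the windowing
    stage); it is transposed to N rows of length L=W before the row-wise
    transform.
    """
    X = np.asarray(sample, dtype=float).T  # (N, L)
    if cfg.n_peaks >= X.shape[1]:
        raise ValueError(f"n_peaks {cfg.n_peaks} must be < sample length {X.shape[1]}")
    Y = dft_matrix(X) if cfg.transform == "dft" else dct_matrix(X)
    vals, _ = top_peaks(Y, cfg.n_peaks)
    return vals.reshape(-1)


def freq_features_batch(samples: np.ndarray, cfg: FreqConfig) -> np.ndarray:
    """Vectorised :func:`freq_features` over (n, W, N) samples → (n, N·F)."""
    X = np.swapaxes(np.asarray(samples, dtype=float), 1, 2)  # (n, N, L)
    if cfg.n_peaks >= X.shape[2]:
        raise ValueError(f"n_peaks {cfg.n_peaks} must be < sample length {X.shape[2]}")
    Y = dft_matrix(X) if cfg.transform == "dft" else dct_matrix(X)
    vals, _ = top_peaks(Y, cfg.n_peaks)
    return vals.reshape(len(X), -1)
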