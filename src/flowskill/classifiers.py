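"""The six benchmark skill classifiers as scikit-learn style estimators.

Every estimator consumes samples of shape (n_samples, W, 240) — sliding
windows of the optical-flow feature matrix — and hard skill labels.  The
neural estimators (CNN, LSTM, CNN+LSTM, ResNet) train a softmax head with
L2-regularised Adam and additionally fit a linear SVM on their penultimate
(global-average-pooled or final-hidden-state) features, so predictions can
be made with either head.  The convolutional autoencoder trains
unsupervised on reconstruction error and classifies exclusively through an
SVM on its latent codes; the DFT/DCT methods feed top-peak frequency
magnitudes straight to an SVM.

Training is deterministic for a fixed ``random_state``.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.svm import SVC

from . import nn
from .frequency import FreqConfig, freq_features_batch
from .nn.net import Adam, mse_loss, softmax_cross_entropy

HEADS = ("model", "svm")


def _check_X(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 3:
        raise ValueError(f"X must be 3D (n_samples, window, features); got shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    return X


def _check_y(y, n: int) -> np.ndarray:
    y = np.asarray(y)
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain at least two classes")
    return y


class _NeuralSkillClassifier(BaseEstimator, ClassifierMixin):
    """Shared fit/predict machinery for the softmax-headed networks."""

    arch_id = "base"

    def __init__(self, epochs: int = 100, batch_size: int = 16, lr: float = 3e-3,
                 l2: float = 1e-4, patience: int = 10, tol: float = 1e-4,
                 svm_C: float = 1.0, random_state: int = 0):
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.l2 = l2
        self.patience = patience
        self.tol = tol
        self.svm_C = svm_C
        self.random_state = random_state

    def _build(self, input_shape, n_classes, rng) -> nn.Network:  # pragma: no cover
        raise NotImplementedError

    def fit(self, X, y):
        X = _check_X(X)
        y = _check_y(y, len(X))
        self.classes_, y_idx = np.unique(y, return_inverse=True)
        rng = np.random.default_rng(self.random_state)
        self.network_ = self._build(X.shape[1:], len(self.classes_), rng)
        opt = Adam(self.network_.params_grads(), lr=self.lr, l2=self.l2)
        n = len(X)
        best_loss, since_best, since_decay = np.inf, 0, 0
        best_weights = self.network_.get_weights()
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                logits = self.network_.forward(X[idx], train=True)
                loss, dlogits = softmax_cross_entropy(logits, y_idx[idx])
                self.network_.backward(dlogits)
                opt.step()
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            self.loss_history_.append(epoch_loss)
            if epoch_loss < best_loss - self.tol:
                best_loss, since_best, since_decay = epoch_loss, 0, 0
                best_weights = self.network_.get_weights()
            else:
                since_best += 1
                since_decay += 1
                if since_decay >= max(self.patience // 2, 2):
                    opt.lr = max(opt.lr * 0.5, self.lr / 16)  # plateau decay
                    since_decay = 0
                if since_best >= self.patience:
                    break
        self.network_.set_weights(best_weights)  # keep the lowest-loss epoch
        feats = self.network_.features(X)
        self.svm_head_ = SVC(kernel="linear", C=self.svm_C).fit(feats, y)
        return self

    def transform(self, X) -> np.ndarray:
        """Penultimate-layer features used by the SVM head."""
        return self.network_.features(_check_X(X))

    def predict_proba(self, X) -> np.ndarray:
        return self.network_.predict_proba(_check_X(X))

    def predict(self, X, head: str = "model") -> np.ndarray:
        if head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        X = _check_X(X)
        if head == "svm":
            return self.svm_head_.predict(self.network_.features(X))
        probs = self.network_.predict_proba(X)
        return self.classes_[np.argmax(probs, axis=1)]


class CNNSkillClassifier(_NeuralSkillClassifier):
    """Two 1-D conv blocks (BN + ReLU), global average pooling, dense softmax."""

    arch_id = "cnn"

    def __init__(self, filters=(64, 64), kernels=(7, 5), epochs: int = 100,
                 batch_size: int = 16, lr: float = 3e-3, l2: float = 1e-4,
                 patience: int = 10, tol: float = 1e-4, svm_C: float = 1.0,
                 random_state: int = 0):
        super().__init__(epochs, batch_size, lr, l2, patience, tol, svm_C, random_state)
        self.filters = filters
        self.kernels = kernels

    def _build(self, input_shape, n_classes, rng):
        return nn.build_cnn(input_shape, n_classes, tuple(self.filters),
                            tuple(self.kernels), rng=rng)


class LSTMSkillClassifier(_NeuralSkillClassifier):
    """Two stacked LSTM blocks (peephole gates by default), dense softmax."""

    arch_id = "lstm"

    def __init__(self, hidden=(16, 16), use_peepholes: bool = True, epochs: int = 80,
                 batch_size: int = 8, lr: float = 1.5e-3, l2: float = 1e-4,
                 patience: int = 20, tol: float = 1e-4, svm_C: float = 1.0,
                 random_state: int = 0):
        super().__init__(epochs, batch_size, lr, l2, patience, tol, svm_C, random_state)
        self.hidden = hidden
        self.use_peepholes = use_peepholes

    def _build(self, input_shape, n_classes, rng):
        return nn.build_lstm(input_shape, n_classes, tuple(self.hidden),
                             self.use_peepholes, rng=rng)


class CNNLSTMSkillClassifier(_NeuralSkillClassifier):
    """Two conv blocks feeding two LSTM blocks, then dense softmax."""

    arch_id = "cnn_lstm"

    def __init__(self, filters=(32, 32), kernels=(7, 5), hidden=(16, 16),
                 use_peepholes: bool = True, epochs: int = 80, batch_size: int = 8,
                 lr: float = 1.5e-3, l2: float = 1e-4, patience: int = 20,
                 tol: float = 1e-4, svm_C: float = 1.0, random_state: int = 0):
        super().__init__(epochs, batch_size, lr, l2, patience, tol, svm_C, random_state)
        self.filters = filters
        self.kernels = kernels
        self.hidden = hidden
        self.use_peepholes = use_peepholes

    def _build(self, input_shape, n_classes, rng):
        return nn.build_cnn_lstm(input_shape, n_classes, tuple(self.filters),
                                 tuple(self.kernels), tuple(self.hidden),
                                 self.use_peepholes, rng=rng)


class ResNetSkillClassifier(_NeuralSkillClassifier):
    """Three residual conv blocks with shortcut connections, GAP, softmax."""

    arch_id = "resnet"

    def __init__(self, filters: int = 32, epochs: int = 100, batch_size: int = 16,
                 lr: float = 3e-3, l2: float = 1e-4, patience: int = 10,
                 tol: float = 1e-4, svm_C: float = 1.0, random_state: int = 0):
        super().__init__(epochs, batch_size, lr, l2, patience, tol, svm_C, random_state)
        self.filters = filters

    def _build(self, input_shape, n_classes, rng):
        return nn.build_resnet(input_shape, n_classes, self.filters, rng=rng)


class ConvAutoencoderSVM(BaseEstimator, ClassifierMixin):
    """Unsupervised conv autoencoder; classification via SVM on latent codes.

    The encoder compresses each W×240 window with strided convolutions; the
    decoder reconstructs the input and the whole stack trains on mean squared
    reconstruction error.  Labels are only ever seen by the SVM fitted on the
    flattened latent codes, so both prediction heads are the SVM.
    """

    arch_id = "convauto"

    def __init__(self, latent_channels: int = 16, epochs: int = 40, batch_size: int = 16,
                 lr: float = 3e-3, l2: float = 1e-4, patience: int = 10, tol: float = 1e-5,
                 svm_C: float = 1.0, random_state: int = 0):
        self.latent_channels = latent_channels
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.l2 = l2
        self.patience = patience
        self.tol = tol
        self.svm_C = svm_C
        self.random_state = random_state

    def fit(self, X, y):
        X = _check_X(X)
        y = _check_y(y, len(X))
        self.classes_ = np.unique(y)
        rng = np.random.default_rng(self.random_state)
        self.encoder_, self.autoencoder_ = nn.build_conv_autoencoder(
            X.shape[1:], self.latent_channels, rng=rng
        )
        opt = Adam(self.autoencoder_.params_grads(), lr=self.lr, l2=self.l2)
        n = len(X)
        best_loss, since_best = np.inf, 0
        best_weights = self.autoencoder_.get_weights()
        self.loss_history_ = []
        for _ in range(self.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for s in range(0, n, self.batch_size):
                idx = order[s : s + self.batch_size]
                recon = self.autoencoder_.forward(X[idx], train=True)
                loss, dr = mse_loss(recon, X[idx])
                self.autoencoder_.backward(dr)
                opt.step()
                epoch_loss += loss * len(idx)
            epoch_loss /= n
            self.loss_history_.append(epoch_loss)
            if epoch_loss < best_loss - self.tol:
                best_loss, since_best = epoch_loss, 0
                best_weights = self.autoencoder_.get_weights()
            else:
                since_best += 1
                if since_best >= self.patience:
                    break
        self.autoencoder_.set_weights(best_weights)
        self.svm_head_ = SVC(kernel="linear", C=self.svm_C).fit(self.transform(X), y)
        return self

    def transform(self, X) -> np.ndarray:
        """Flattened latent codes from the trained encoder."""
        return self.encoder_.features(_check_X(X))

    def reconstruct(self, X) -> np.ndarray:
        return self.autoencoder_.forward(_check_X(X), train=False)

    def predict(self, X, head: str = "svm") -> np.ndarray:
        if head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        return self.svm_head_.predict(self.transform(X))


class FrequencySVMClassifier(BaseEstimator, ClassifierMixin):
    """Top-F frequency peaks (DFT or DCT) per univariate series + linear SVM."""

    def __init__(self, transform: str = "dft", n_peaks: int = 10, svm_C: float = 1.0,
                 random_state: int = 0):
        self.transform = transform
        self.n_peaks = n_peaks
        self.svm_C = svm_C
        self.random_state = random_state

    @property
    def arch_id(self) -> str:
        return self.transform

    def fit(self, X, y):
        X = _check_X(X)
        y = _check_y(y, len(X))
        self.classes_ = np.unique(y)
        self.cfg_ = FreqConfig(transform=self.transform, n_peaks=self.n_peaks)
        self.svm_head_ = SVC(kernel="linear", C=self.svm_C).fit(
            freq_features_batch(X, self.cfg_), y
        )
        return self

    def transform_features(self, X) -> np.ndarray:
        return freq_features_batch(_check_X(X), self.cfg_)

    def predict(self, X, head: str = "svm") -> np.ndarray:
        if head not in HEADS:
            raise ValueError(f"head must be one of {HEADS}")
        return self.svm_head_.predict(self.transform_features(X))


METHOD_IDS = ("cnn", "lstm", "cnn_lstm", "resnet", "convauto", "dft", "dct")


def make_classifier(method: str, **kwargs):
    """Factory mapping a benchmark method id to its estimator."""
    if method == "cnn":
        return CNNSkillClassifier(**kwargs)
    if method == "lstm":
        return LSTMSkillClassifier(**kwargs)
    if method == "cnn_lstm":
        return CNNLSTMSkillClassifier(**kwargs)
    if method == "resnet":
        return ResNetSkillClassifier(**kwargs)
    if method == "convauto":
        return ConvAutoencoderSVM(**kwargs)
    if method in ("dft", "dct"):
        return FrequencySVMClassifier(transform=method, **kwargs)
    raise ValueError(f"unknown method {method!r}; expected one of {METHOD_IDS}")
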