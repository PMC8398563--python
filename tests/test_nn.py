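"""Network building blocks: activations, shapes, LSTM gates, gradients."""

import numpy as np
import pytest

from flowskill import nn
from flowskill.nn.layers import (
    BatchNorm1D,
    Conv1D,
    Dense,
    GlobalAveragePooling,
    ReLU,
    Sequential,
)
from flowskill.nn.lstm import LstmCell, LSTMLayer, lstm_step
from flowskill.nn.net import mse_loss, softmax_cross_entropy


class TestActivations:
    def test_relu_values(self):
        assert nn.relu(-2) == 0 and nn.relu(3) == 3
        np.testing.assert_array_equal(nn.relu(np.array([-1.0, 0.0, 2.5])), [0, 0, 2.5])

    def test_sigmoid_midpoint_and_bounds(self):
        assert nn.sigmoid(0) == pytest.approx(0.5)
        z = np.linspace(-30, 30, 101)
        s = nn.sigmoid(z)
        assert np.all((s > 0) & (s < 1)) and np.all(np.diff(s) >= 0)

    def test_softmax_symmetry_and_normalisation(self):
        np.testing.assert_allclose(nn.softmax(np.array([2.0, 2.0, 2.0])), np.full(3, 1 / 3))
        rng = np.random.default_rng(0)
        z = rng.normal(scale=10, size=(16, 5))
        p = nn.softmax(z)
        assert np.all(p > 0)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)


class TestPaddingLaw:
    @pytest.mark.parametrize("L,k,s", [(60, 7, 1), (60, 5, 2), (59, 3, 2), (31, 8, 3)])
    def test_same_padding_output_length(self, L, k, s):
        """Conv output time length equals ceil(L / stride) under same padding."""
        conv = Conv1D(4, 6, k, stride=s)
        y = conv.forward(np.zeros((2, L, 4)))
        assert y.shape[1] == conv.output_length == -(-L // s)

    def test_valid_shape_rule(self):
        # (L − F + 2P)/S + 1 with explicit padding
        assert nn.conv_output_length(60, 7, 3, 1) == 60
        assert nn.conv_output_length(28, 5, 0, 1) == 24
        assert nn.conv_output_length(28, 5, 2, 2) == 14

    @pytest.mark.parametrize("builder,kw", [
        (nn.build_cnn, dict(n_classes=3)),
        (nn.build_cnn_lstm, dict(n_classes=2)),
        (nn.build_resnet, dict(n_classes=2)),
    ])
    def test_every_instantiated_conv_obeys_the_law(self, builder, kw):
        net = builder((30, 12), **kw)
        net.forward(np.random.default_rng(0).normal(size=(2, 30, 12)), train=False)
        convs = net.conv_layers()
        assert convs
        for c in convs:
            assert c.output_length == -(-c.input_length // c.stride)

    def test_autoencoder_convs_and_shape(self):
        enc, auto = nn.build_conv_autoencoder((60, 24))
        x = np.random.default_rng(1).normal(size=(3, 60, 24))
        recon = auto.forward(x, train=False)
        assert recon.shape == x.shape
        for c in [l for l in auto.body.iter_layers() if isinstance(l, Conv1D)]:
            assert c.output_length == -(-c.input_length // c.stride)

    def test_autoencoder_must_compress(self):
        with pytest.raises(ValueError, match="compress"):
            nn.build_conv_autoencoder((4, 2), latent_channels=16)


class TestLstm:
    def _zero_cell(self, d=3, h=4, peep=True):
        z = lambda *s: np.zeros(s)
        return LstmCell(
            Wxi=z(d, h), Whi=z(h, h), Wci=z(h, h), bi=z(h),
            Wxf=z(d, h), Whf=z(h, h), Wcf=z(h, h), bf=z(h),
            Wxc=z(d, h), Whc=z(h, h), bc=z(h),
            Wxo=z(d, h), Who=z(h, h), Wco=z(h, h), bo=z(h),
            use_peepholes=peep,
        )

    def test_zero_weights_closed_form(self):
        """All-zero weights: gates are 0.5, c halves, h = 0.5·tanh(c)."""
        cell = self._zero_cell()
        c_prev = np.array([1.0, -2.0, 0.5, 0.0])
        h, c = lstm_step(cell, np.zeros(3), np.zeros(4), c_prev)
        np.testing.assert_allclose(c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_forced_gates_perfect_memory(self):
        """f≈1, i≈0 → the cell state passes through unchanged."""
        cell = self._zero_cell()
        cell.bf[:] = 50.0
        cell.bi[:] = -50.0
        c_prev = np.array([0.3, -1.2, 2.0, 0.7])
        _, c = lstm_step(cell, np.ones(3), np.zeros(4), c_prev)
        np.testing.assert_allclose(c, c_prev, atol=1e-12)

    @pytest.mark.parametrize("peep", [True, False])
    def test_step_matches_literal_transcription(self, peep):
        """lstm_step ≡ an independent straight-line coding of the equations."""
        rng = np.random.default_rng(7)
        d, H = 5, 4
        cell = LstmCell.init(d, H, rng, use_peepholes=peep)
        x = rng.normal(size=d)
        h0 = rng.normal(size=H)
        c0 = rng.normal(size=H)

        sig = lambda z: 1.0 / (1.0 + np.exp(-z))
        pe = 1.0 if peep else 0.0
        i = sig(x @ cell.Wxi + h0 @ cell.Whi + pe * (c0 @ cell.Wci) + cell.bi)
        f = sig(x @ cell.Wxf + h0 @ cell.Whf + pe * (c0 @ cell.Wcf) + cell.bf)
        c_ref = f * c0 + i * np.tanh(x @ cell.Wxc + h0 @ cell.Whc + cell.bc)
        o = sig(x @ cell.Wxo + h0 @ cell.Who + pe * (c_ref @ cell.Wco) + cell.bo)
        h_ref = o * np.tanh(c_ref)

        h, c = lstm_step(cell, x, h0, c0)
        np.testing.assert_allclose(h, h_ref, atol=1e-6)
        np.testing.assert_allclose(c, c_ref, atol=1e-6)

    def test_layer_forward_matches_step_rollout(self):
        rng = np.random.default_rng(3)
        layer = LSTMLayer(4, 3, return_sequences=True, rng=rng)
        x = rng.normal(size=(2, 6, 4))
        hs = layer.forward(x, train=False)
        h = np.zeros((2, 3))
        c = np.zeros((2, 3))
        for t in range(6):
            h, c = lstm_step(layer.cell, x[:, t, :], h, c)
            np.testing.assert_allclose(hs[:, t, :], h, atol=1e-12)

    def test_nan_state_raises(self):
        cell = self._zero_cell()
        with pytest.raises(FloatingPointError):
            lstm_step(cell, np.full(3, np.nan), np.zeros(4), np.zeros(4))


def numeric_grad(f, x, eps=1e-6):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


class TestGradients:
    """Finite-difference checks of backpropagation for every layer family."""

    def _check(self, net, x, target_idx=None, mse_target=None, tol=2e-5):
        # perturb every parameter (incl. zero-init biases) so no ReLU input
        # sits exactly on the kink, where the subgradient is one-sided
        rng = np.random.default_rng(99)
        for p, _, _ in net.params_grads():
            p += rng.normal(0.0, 0.05, size=p.shape)

        def loss_fn():
            out = net.forward(x.copy(), train=True)
            if mse_target is not None:
                return mse_loss(out, mse_target)[0]
            return softmax_cross_entropy(out, target_idx)[0]

        out = net.forward(x.copy(), train=True)
        if mse_target is not None:
            _, d = mse_loss(out, mse_target)
        else:
            _, d = softmax_cross_entropy(out, target_idx)
        net.backward(d)
        for p, g, _ in net.params_grads():
            num = numeric_grad(loss_fn, p)
            np.testing.assert_allclose(g, num, rtol=tol, atol=1e-7)

    def test_conv_bn_dense_chain(self):
        rng = np.random.default_rng(0)
        net = nn.Network(
            Sequential([Conv1D(3, 4, 3, rng=rng), BatchNorm1D(4), ReLU(),
                        GlobalAveragePooling()]),
            Dense(4, 2, rng=rng), "t")
        x = rng.normal(size=(5, 8, 3))
        self._check(net, x, target_idx=np.array([0, 1, 0, 1, 1]))

    def test_strided_conv_autoencoder_path(self):
        rng = np.random.default_rng(1)
        _, auto = nn.build_conv_autoencoder((8, 3), latent_channels=2, enc_filters=4,
                                            rng=rng)
        x = rng.normal(size=(3, 8, 3))
        self._check(auto, x, mse_target=rng.normal(size=(3, 8, 3)))

    @pytest.mark.parametrize("peep", [True, False])
    def test_lstm_bptt(self, peep):
        rng = np.random.default_rng(2)
        net = nn.Network(Sequential([LSTMLayer(3, 4, use_peepholes=peep, rng=rng)]),
                         Dense(4, 2, rng=rng), "t")
        x = rng.normal(size=(4, 5, 3))
        self._check(net, x, target_idx=np.array([0, 1, 1, 0]))

    def test_residual_block(self):
        rng = np.random.default_rng(3)
        net = nn.build_resnet((6, 3), 2, filters=4, rng=rng)
        x = rng.normal(size=(3, 6, 3))
        self._check(net, x, target_idx=np.array([0, 1, 0]), tol=5e-5)


class TestArchitectureContracts:
    def test_cnn_head_lengths(self):
        for k in (2, 3):
            net = nn.build_cnn((20, 6), k)
            p = net.predict_proba(np.random.default_rng(0).normal(size=(4, 20, 6)))
            assert p.shape == (4, k)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_n_classes_below_two_rejected(self):
        for builder in (nn.build_cnn, nn.build_lstm, nn.build_cnn_lstm, nn.build_resnet):
            with pytest.raises(ValueError):
                builder((20, 6), 1)

    def test_resnet_zero_branches_pass_identity(self):
        """With all residual-branch weights zeroed, blocks forward x unchanged."""
        rng = np.random.default_rng(0)
        from flowskill.nn.net import _res_block

        block = _res_block(4, 4, rng)  # matching channels → identity shortcut
        for p, _, _ in block.params_grads():
            p[...] = 0.0
        for bn in [l for l in block.iter_layers() if isinstance(l, BatchNorm1D)]:
            bn.gamma[...] = 0.0  # silence the branch entirely
        x = np.abs(rng.normal(size=(2, 10, 4)))  # non-negative so final ReLU is inert
        y = block.forward(x, train=False)
        np.testing.assert_allclose(y, x, atol=1e-12)

    def test_softmax_head_normalised_for_all_architectures(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(3, 12, 5))
        for builder in (nn.build_cnn, nn.build_lstm, nn.build_cnn_lstm, nn.build_resnet):
            p = builder((12, 5), 3, rng=np.random.default_rng(1)).predict_proba(x)
            assert np.all(p > 0)
            np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_cnn_lstm_end_to_end(self):
        net = nn.build_cnn_lstm((60, 240), 2, rng=np.random.default_rng(0))
        p = net.predict_proba(np.random.default_rng(1).normal(size=(2, 60, 240)))
        assert p.shape == (2, 2)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-12)
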