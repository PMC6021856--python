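"""GRU/conv primitives vs independent oracles, autodiff gradient checks,
autoencoder training behaviour."""

import math

import numpy as np
import pytest

from homesig import autodiff as ad
from homesig.autodiff import Tensor
from homesig.nn import (
    AEConfig,
    Conv1DLayerParams,
    ConvAutoencoder,
    GRUAutoencoder,
    GRUCellParams,
    binary_log_loss,
    conv1d_forward,
    encode_days,
    gru_cell_forward,
    train_autoencoder,
)


def scalar_gru_oracle(wz, uz, bz, wr, ur, br, wh, uh, bh, x, h):
    """Hand-rolled scalar evaluation of the gated-recurrence equations."""
    sig = lambda v: 1.0 / (1.0 + math.exp(-v))
    z = sig(wz * x + uz * h + bz)
    r = sig(wr * x + ur * h + br)
    cand = math.tanh(wh * x + uh * (r * h) + bh)
    return (1.0 - z) * h + z * cand


def make_cell(rng, n_in, hidden):
    def m(a, b):
        return rng.normal(0, 0.5, size=(a, b))

    return GRUCellParams(
        W_z=m(n_in, hidden), U_z=m(hidden, hidden), b_z=rng.normal(0, 0.5, hidden),
        W_r=m(n_in, hidden), U_r=m(hidden, hidden), b_r=rng.normal(0, 0.5, hidden),
        W_h=m(n_in, hidden), U_h=m(hidden, hidden), b_h=rng.normal(0, 0.5, hidden),
    )


class TestGRUCell:
    def test_zero_weights_zero_state(self):
        cell = make_cell(np.random.default_rng(0), 3, 4)
        zero = GRUCellParams(*[np.zeros_like(getattr(cell, f)) for f in
                               ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")])
        h = gru_cell_forward(zero, np.ones(3), np.zeros(4))
        np.testing.assert_allclose(h, 0.0)

    def test_zero_weights_halve_state(self):
        cell = make_cell(np.random.default_rng(0), 3, 4)
        zero = GRUCellParams(*[np.zeros_like(getattr(cell, f)) for f in
                               ("W_z", "U_z", "b_z", "W_r", "U_r", "b_r", "W_h", "U_h", "b_h")])
        v = np.array([0.2, -0.4, 1.0, 3.0])
        h = gru_cell_forward(zero, np.ones(3), v)
        np.testing.assert_allclose(h[0], 0.5 * v)

    def test_matches_scalar_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            w = rng.normal(0, 1, 9)
            x, h = rng.normal(0, 1, 2)
            cell = GRUCellParams(*[np.array([[v]]) if i % 3 != 2 else np.array([v])
                                   for i, v in enumerate(w)])
            got = gru_cell_forward(cell, np.array([x]), np.array([h]))[0, 0]
            want = scalar_gru_oracle(*w, x, h)
            assert got == pytest.approx(want, abs=1e-10)

    def test_shape_mismatch(self):
        cell = make_cell(np.random.default_rng(2), 3, 4)
        with pytest.raises(ValueError):
            gru_cell_forward(cell, np.ones(5), np.zeros(4))


def conv_oracle(kernels, biases, x):
    """Brute-force sliding-window sum, one output position at a time."""
    K, Ci, Co = kernels.shape
    T = x.shape[0]
    y = np.zeros((T - K + 1, Co))
    for t in range(T - K + 1):
        for j in range(Co):
            acc = biases[j]
            for i in range(Ci):
                for k in range(K):
                    acc += kernels[k, i, j] * x[t + k, i]
            y[t, j] = max(acc, 0.0)
    return y


class TestConv1D:
    def test_identity_kernel_is_relu(self):
        params = Conv1DLayerParams(np.ones((1, 1, 1)), np.zeros(1))
        x = np.array([[-1.0], [2.0], [-3.0], [4.0]])
        np.testing.assert_allclose(conv1d_forward(params, x), np.maximum(x, 0))

    def test_all_negative_preactivation_zero(self):
        params = Conv1DLayerParams(np.ones((2, 1, 1)), np.array([-100.0]))
        x = np.random.default_rng(0).uniform(size=(10, 1))
        assert (conv1d_forward(params, x) == 0).all()

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            kernels = rng.normal(size=(3, 2, 4))
            biases = rng.normal(size=4)
            x = rng.normal(size=(12, 2))
            got = conv1d_forward(Conv1DLayerParams(kernels, biases), x)
            np.testing.assert_allclose(got, conv_oracle(kernels, biases, x), atol=1e-10)

    def test_maxpool(self):
        params = Conv1DLayerParams(np.ones((1, 1, 1)), np.zeros(1), pool=2)
        x = np.array([[1.0], [5.0], [2.0], [3.0], [9.0]])
        np.testing.assert_allclose(conv1d_forward(params, x), [[5.0], [3.0]])

    def test_kernel_longer_than_input(self):
        params = Conv1DLayerParams(np.ones((5, 1, 1)), np.zeros(1))
        with pytest.raises(ValueError):
            conv1d_forward(params, np.ones((3, 1)))


class TestAutodiff:
    @staticmethod
    def numeric_grad(f, x, eps=1e-6):
        g = np.zeros_like(x)
        it = np.nditer(x, flags=["multi_index"])
        for _ in it:
            i = it.multi_index
            x[i] += eps
            hi = f()
            x[i] -= 2 * eps
            lo = f()
            x[i] += eps
            g[i] = (hi - lo) / (2 * eps)
        return g

    def test_dense_graph_gradients(self):
        rng = np.random.default_rng(4)
        W = Tensor(rng.normal(size=(3, 2)), requires_grad=True)
        b = Tensor(rng.normal(size=2), requires_grad=True)
        x = np.array([[0.3, -0.5, 1.2], [1.0, 0.4, -0.2]])
        y = np.array([[1.0, 0.0], [0.0, 1.0]])

        def loss_value():
            return float(ad.bce_with_logits((Tensor(x) @ W + b).tanh() * 3.0, y).data)

        loss = ad.bce_with_logits((Tensor(x) @ W + b).tanh() * 3.0, y)
        loss.backward()
        np.testing.assert_allclose(W.grad, self.numeric_grad(loss_value, W.data), atol=1e-6)
        np.testing.assert_allclose(b.grad, self.numeric_grad(loss_value, b.data), atol=1e-6)

    def test_conv_pool_graph_gradients(self):
        rng = np.random.default_rng(5)
        w = Tensor(rng.normal(size=(3, 2, 2)), requires_grad=True)
        b = Tensor(rng.normal(size=2), requires_grad=True)
        x = rng.normal(size=(2, 8, 2))
        y = (rng.uniform(size=(2, 3, 2)) < 0.5).astype(float)

        def build():
            return ad.bce_with_logits(ad.maxpool1d(ad.conv1d(Tensor(x), w, b).relu(), 2), y)

        loss = build()
        loss.backward()
        np.testing.assert_allclose(
            w.grad, self.numeric_grad(lambda: float(build().data), w.data), atol=1e-5
        )
        np.testing.assert_allclose(
            b.grad, self.numeric_grad(lambda: float(build().data), b.data), atol=1e-5
        )

    def test_gru_graph_matches_numpy_cell(self):
        """One autodiff GRU step equals the plain-numpy cell forward."""
        cfg = AEConfig(arch="gru", time_steps=4, n_sensors=3, hidden=5, seed=7)
        model = GRUAutoencoder(cfg)
        batch = (np.random.default_rng(8).uniform(size=(2, 4, 3)) < 0.4).astype(float)
        x = Tensor(batch)
        flat = x.reshape(8, 3)
        xw = {g: (flat @ model.params[f"enc_W{g}"]).reshape(2, 4, 5) for g in "zrh"}
        h, _ = model._gru_pass("enc", xw, Tensor(np.zeros((2, 5))), 4)
        np.testing.assert_allclose(h.data, model.encode(batch), atol=1e-12)


class TestLossAndTraining:
    def test_half_prediction_gives_ln2(self):
        y = np.array([0.0, 1.0, 1.0, 0.0])
        assert binary_log_loss(y, np.full(4, 0.5)) == pytest.approx(math.log(2))
        assert float(ad.bce_with_logits(Tensor(np.zeros(4)), y).data) == pytest.approx(math.log(2))

    def test_perfect_prediction_loss_vanishes(self):
        y = np.array([0.0, 1.0])
        assert binary_log_loss(y, np.array([1e-9, 1 - 1e-9])) < 1e-6

    def test_rejects_non_binary_input(self):
        days = np.full((31, 48, 2), 0.5)
        with pytest.raises(ValueError, match="binary"):
            train_autoencoder(days, AEConfig(arch="conv1d", n_sensors=2, epochs=1))

    def test_rejects_too_few_days(self):
        days = np.zeros((10, 48, 2))
        with pytest.raises(ValueError, match="30 days"):
            train_autoencoder(days, AEConfig(arch="conv1d", n_sensors=2, epochs=1))

    @pytest.mark.parametrize("arch", ["gru", "conv1d"])
    def test_training_reduces_loss_and_is_deterministic(self, arch):
        rng = np.random.default_rng(9)
        proto = (rng.uniform(size=(48, 2)) < 0.3).astype(float)
        days = np.array([(rng.uniform(size=(48, 2)) < np.clip(proto * 0.9 + 0.02, 0, 1)).astype(float)
                         for _ in range(32)])
        cfg = AEConfig(arch=arch, n_sensors=2, epochs=8, seed=1)
        m1, c1 = train_autoencoder(days, cfg)
        m2, c2 = train_autoencoder(days, cfg)
        assert c1[-1] < c1[0]
        assert c1 == c2
        np.testing.assert_array_equal(encode_days(m1, days).vectors, encode_days(m2, days).vectors)

    def test_encode_identical_days_identical_vectors(self):
        day = (np.random.default_rng(10).uniform(size=(48, 2)) < 0.4).astype(float)
        days = np.stack([day] * 32)
        cfg = AEConfig(arch="conv1d", n_sensors=2, epochs=2, seed=0)
        model, _ = train_autoencoder(days, cfg)
        emb = encode_days(model, days)
        assert np.ptp(emb.vectors, axis=0).max() == 0.0

    def test_encode_empty_set(self):
        cfg = AEConfig(arch="conv1d", n_sensors=2, epochs=1, seed=0)
        model = ConvAutoencoder(cfg)
        emb = encode_days(model, [])
        assert emb.vectors.shape == (0, cfg.resolved_latent)

    def test_geometry_mismatch_rejected(self):
        cfg = AEConfig(arch="conv1d", n_sensors=2, epochs=1, seed=0)
        model = ConvAutoencoder(cfg)
        with pytest.raises(ValueError, match="geometry"):
            encode_days(model, np.zeros((5, 48, 3)))

    def test_latent_must_compress(self):
        with pytest.raises(ValueError, match="compress"):
            AEConfig(arch="conv1d", time_steps=4, n_sensors=2, latent_dim=8)
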