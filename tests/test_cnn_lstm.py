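import numpy as np
import pytest

from btsforecast.cnn_lstm import (
    CnnLstmSpec,
    TrainingError,
    _backward,
    conv1d,
    fit_cnn_lstm,
    init_model,
    mse_loss,
    predict_multi,
    sapt_pretrain,
    tune_cnn_lstm,
)
from btsforecast.dataset import make_supervised
from btsforecast.pso import PsoConfig


def brute_force_conv(X, W):
    """Triple-loop oracle for valid cross-channel temporal convolution."""
    K, C, w = W.shape
    B, _, T = X.shape
    out = np.zeros((B, K, T - w + 1))
    for b in range(B):
        for k in range(K):
            for j in range(T - w + 1):
                s = 0.0
                for c in range(C):
                    for u in range(w):
                        s += W[k, c, u] * X[b, c, j + u]
                out[b, k, j] = s
    return out


class TestConv1d:
    def test_identity_kernel(self):
        x = np.array([[1.0, 2.0, 4.0]])
        np.testing.assert_array_equal(conv1d(x, np.array([[[1.0]]])), x[None][0])

    def test_difference_kernel(self):
        x = np.array([[1.0, 2.0, 4.0]])
        out = conv1d(x, np.array([[[1.0, -1.0]]]))
        np.testing.assert_array_equal(out, [[-1.0, -2.0]])

    def test_two_channels_of_ones(self):
        x = np.ones((2, 3))
        out = conv1d(x, np.ones((1, 2, 2)))
        np.testing.assert_array_equal(out, [[4.0, 4.0]])

    def test_kernel_wider_than_window_rejected(self):
        with pytest.raises(ValueError):
            conv1d(np.ones((1, 3)), np.ones((1, 1, 4)))

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(5):
            B, C, T, K, w = 3, rng.integers(1, 5), rng.integers(4, 17), 2, rng.integers(1, 4)
            X = rng.normal(size=(B, C, T))
            W = rng.normal(size=(K, C, w))
            np.testing.assert_allclose(conv1d(X, W), brute_force_conv(X, W), atol=1e-10)


class TestGradients:
    @pytest.mark.parametrize("use_conv,conv_relu", [(True, False), (True, True), (False, False)])
    def test_analytic_gradients_match_finite_differences(self, rng, use_conv, conv_relu):
        ss = make_supervised(rng.normal(size=(3, 30)), 8)
        spec = CnnLstmSpec(n_hidden=4, n_kernels=3, kernel_width=2,
                           use_conv=use_conv, conv_relu=conv_relu)
        m = init_model(spec, 3, seed=2)
        _, grads = _backward(m, ss.inputs, ss.targets)
        eps = 1e-6
        for name, g in zip(["Wc", "bc", "Wx", "Wh", "b", "v"], grads[:-1]):
            arr = getattr(m, name)
            for idx in [tuple(0 for _ in arr.shape), tuple(s - 1 for s in arr.shape)]:
                orig = arr[idx]
                arr[idx] = orig + eps
                lp, _ = _backward(m, ss.inputs, ss.targets)
                arr[idx] = orig - eps
                lm, _ = _backward(m, ss.inputs, ss.targets)
                arr[idx] = orig
                fd = (lp - lm) / (2 * eps)
                if not use_conv and name in ("Wc", "bc"):
                    continue  # conv weights unused in the ablated architecture
                assert abs(fd - g[idx]) < 1e-7, f"{name}{idx}: {fd} vs {g[idx]}"


class TestTraining:
    def test_learns_noiseless_sinusoid(self):
        t = np.arange(300)
        sig = np.sin(2 * np.pi * t / 20)
        ss = make_supervised(sig[None, :], 8)
        spec = CnnLstmSpec(n_epochs=400, n_hidden=12, learning_rate=0.05, n_kernels=8)
        _, hist = fit_cnn_lstm(ss, None, spec, seed=0)
        assert hist["train_loss"][-1] < 1e-2 * sig.var()

    def test_deterministic_under_seed(self, rng):
        ss = make_supervised(rng.normal(size=(2, 60)), 8)
        spec = CnnLstmSpec(n_epochs=30, n_hidden=6, n_kernels=4)
        m1, h1 = fit_cnn_lstm(ss, None, spec, seed=3)
        m2, h2 = fit_cnn_lstm(ss, None, spec, seed=3)
        assert h1["train_loss"] == h2["train_loss"]
        for a, b in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(a, b)

    def test_zero_epochs_warns_and_returns_init(self, rng):
        ss = make_supervised(rng.normal(size=(2, 40)), 8)
        spec = CnnLstmSpec(n_epochs=0)
        with pytest.warns(UserWarning):
            m, hist = fit_cnn_lstm(ss, None, spec, seed=4)
        ref = init_model(spec, 2, seed=4)
        for a, b in zip(m.params(), ref.params()):
            np.testing.assert_array_equal(a, b)

    def test_non_finite_loss_raises_with_epoch(self, rng):
        ss = make_supervised(rng.normal(size=(1, 40)), 8)
        ss.inputs[0, 0, 0] = np.nan  # corrupt batch -> non-finite loss
        with pytest.raises(TrainingError, match="epoch 0"):
            fit_cnn_lstm(ss, None, CnnLstmSpec(n_epochs=5), seed=5)

    def test_loss_decreases_on_learnable_signal(self):
        t = np.arange(200)
        sig = np.sin(2 * np.pi * t / 25) + 0.5 * np.cos(2 * np.pi * t / 7)
        ss = make_supervised(sig[None, :], 8)
        ok = 0
        for seed in range(10):
            _, hist = fit_cnn_lstm(ss, None, CnnLstmSpec(n_epochs=100, learning_rate=0.02), seed=seed)
            ok += hist["train_loss"][-1] <= hist["train_loss"][0]
        assert ok >= 9


class TestPredict:
    def test_output_length_and_determinism(self, rng):
        ss = make_supervised(rng.normal(size=(2, 50)), 8)
        m, _ = fit_cnn_lstm(ss, None, CnnLstmSpec(n_epochs=10), seed=6)
        p1, p2 = predict_multi(m, ss), predict_multi(m, ss)
        assert p1.shape == (ss.n_samples,)
        np.testing.assert_array_equal(p1, p2)
        assert np.isfinite(p1).all()

    def test_channel_mismatch_rejected(self, rng):
        ss2 = make_supervised(rng.normal(size=(2, 50)), 8)
        ss3 = make_supervised(rng.normal(size=(3, 50)), 8)
        m, _ = fit_cnn_lstm(ss2, None, CnnLstmSpec(n_epochs=1), seed=7)
        with pytest.raises(ValueError):
            predict_multi(m, ss3)


class TestSapt:
    @pytest.fixture
    def sets(self, rng):
        # learnable structure so per-channel pre-training can improve
        t = np.arange(90)
        mat = np.stack([np.sin(2 * np.pi * t / p) for p in (12, 17, 23)])
        mat += 0.05 * rng.normal(size=mat.shape)
        tr = make_supervised(mat[:, :70], 8)
        va = make_supervised(mat[:, 70:], 8)
        return tr, va

    def test_patience_zero_is_noop(self, sets):
        tr, va = sets
        m = init_model(CnnLstmSpec(), 3, seed=8)
        out = sapt_pretrain(m, tr, va, patience=0)
        assert out is m

    def test_pretraining_changes_weights(self, sets):
        tr, va = sets
        m = init_model(CnnLstmSpec(n_epochs=20), 3, seed=9)
        out = sapt_pretrain(m, tr, va, patience=2, max_epochs=10)
        changed = any(
            not np.array_equal(a, b) for a, b in zip(m.params(), out.params())
        )
        assert changed


class TestTune:
    def test_tuned_not_worse_than_default_and_deterministic(self, rng):
        mat = np.cumsum(rng.normal(size=(2, 120)), axis=1) * 0.1
        tr = make_supervised(mat[:, :90], 8)
        va = make_supervised(mat[:, 90:], 8)
        base = CnnLstmSpec(n_epochs=30, n_hidden=6, n_kernels=4)
        cfg = PsoConfig(swarm_size=3, iterations=2, seed=0)
        spec1, res1 = tune_cnn_lstm(tr, va, bounds=((10, 60), (4, 12), (-3, -1)),
                                    pso_config=cfg, base_spec=base, seed=0)
        spec2, res2 = tune_cnn_lstm(tr, va, bounds=((10, 60), (4, 12), (-3, -1)),
                                    pso_config=cfg, base_spec=base, seed=0)
        assert spec1 == spec2 and res1.best_fitness == res2.best_fitness
        m_def, _ = fit_cnn_lstm(tr, None, base, seed=0)
        assert res1.best_fitness <= mse_loss(m_def, va) + 1e-12
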