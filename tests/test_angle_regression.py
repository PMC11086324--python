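"""Backprop regressor: update rules, gradients, training dynamics."""

import numpy as np
import pytest

from semg_motionmap.angle_regression import (
    BPAngleRegressor,
    N_INPUTS,
    adapt_learning_rate,
    bp_forward,
    init_bp,
    momentum_step,
    predict_trajectory,
    weighted_mse,
)
from semg_motionmap.signal_processing import FeatureSeries
from semg_motionmap.trajectory import DOF_NAMES, DOF_RANGES


class TestInit:
    def test_seed_determinism(self):
        a, b = init_bp(seed=7), init_bp(seed=7)
        assert np.array_equal(a.W1_, b.W1_) and np.array_equal(a.W2_, b.W2_)

    def test_default_shapes(self):
        net = init_bp(seed=0)
        assert net.W1_.shape == (8, 20)
        assert net.W2_.shape == (20, 1)
        assert np.all(net.b1_ == 0.0) and np.all(net.b2_ == 0.0)
        assert np.all(np.abs(net.W1_) <= 0.5)

    def test_minimal_hidden(self):
        net = init_bp(seed=0, H=1)
        assert net.W1_.shape == (8, 1)

    def test_invalid_hidden_rejected(self):
        with pytest.raises(ValueError):
            init_bp(seed=0, H=0)


class TestForward:
    def test_zero_parameters_give_inverse_scaled_midpoint(self):
        net = init_bp(seed=0, angle_range=(0.0, 100.0))
        net.W1_ *= 0.0
        net.W2_ *= 0.0
        # sigmoid(0) = 0.5 hidden, zero output weights -> scaled output 0 -> lo
        assert bp_forward(net, np.zeros(8)) == pytest.approx(0.0)

    def test_wrong_length_rejected(self):
        net = init_bp(seed=0)
        with pytest.raises(ValueError):
            bp_forward(net, np.zeros(5))

    def test_continuity(self):
        net = init_bp(seed=3, angle_range=(0.0, 1.0))
        x = np.full(8, 0.3)
        base = bp_forward(net, x)
        assert abs(bp_forward(net, x + 1e-9) - base) < 1e-6


class TestGradients:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_analytic_matches_central_differences(self, seed):
        """Core correctness oracle: backprop gradients vs numeric differentiation."""
        rng = np.random.default_rng(seed)
        net = init_bp(seed=seed, H=20, angle_range=(0.0, 1.0))
        X = rng.uniform(0, 1, size=(12, N_INPUTS))
        y = rng.uniform(0, 1, size=12)
        w = np.ones(12)
        grads = net._gradients(X, y, w)

        def loss():
            yhat, _ = net._forward_scaled(X)
            return 0.5 * np.sum(w * (y - yhat) ** 2) / len(y)

        eps = 1e-6
        for key, param in (("W1", net.W1_), ("b1", net.b1_), ("W2", net.W2_), ("b2", net.b2_)):
            scale = max(np.max(np.abs(grads[key])), 1e-8)
            it = np.nditer(param, flags=["multi_index"])
            for _ in it:
                idx = it.multi_index
                orig = param[idx]
                param[idx] = orig + eps
                lp = loss()
                param[idx] = orig - eps
                lm = loss()
                param[idx] = orig
                numeric = -(lp - lm) / (2 * eps)  # descent direction
                analytic = grads[key][idx]
                # relative to the gradient scale: near-zero entries would
                # otherwise be dominated by finite-difference round-off
                denom = max(abs(numeric), abs(analytic), 1e-3 * scale)
                assert abs(numeric - analytic) / denom < 1e-6, (key, idx)


class TestUpdateRules:
    def test_momentum_zero_is_plain_step(self):
        assert momentum_step(np.array(2.0), np.array(9.0), eta=0.1, mc=0.0) == pytest.approx(0.2)

    def test_momentum_one_ignores_gradient(self):
        assert momentum_step(np.array(2.0), np.array(0.3), eta=0.1, mc=1.0) == pytest.approx(0.3)

    def test_momentum_blend_example(self):
        assert momentum_step(np.array(1.0), np.array(0.2), eta=0.1, mc=0.5) == pytest.approx(0.15)

    @pytest.mark.parametrize(
        "sse_new, sse_old, factor",
        [(0.9, 1.0, 1.05), (1.05, 1.0, 0.7), (1.0, 1.0, 1.0), (1.03, 1.0, 1.0)],
    )
    def test_adaptive_rate_branches(self, sse_new, sse_old, factor):
        assert adapt_learning_rate(0.2, sse_new, sse_old) == pytest.approx(0.2 * factor)

    def test_negative_sse_rejected(self):
        with pytest.raises(ValueError):
            adapt_learning_rate(0.1, -1.0, 1.0)


class TestWeightedMse:
    def test_perfect_prediction_is_zero(self):
        assert weighted_mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_direct_example(self):
        assert weighted_mse([1.0, 3.0], [0.0, 1.0]) == pytest.approx(2.5)

    def test_linear_in_weights(self, rng):
        y = rng.standard_normal(10)
        yh = rng.standard_normal(10)
        w = rng.uniform(0.5, 2.0, 10)
        assert weighted_mse(y, yh, 2 * w) == pytest.approx(2 * weighted_mse(y, yh, w))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            weighted_mse([1.0], [1.0, 2.0])


def _linear_dataset(n=200, seed=3):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0, 1, size=(n, N_INPUTS))
    y = X.sum(axis=1)  # in [0, 8]
    return X, y


class TestTraining:
    def test_learns_noiseless_linear_target(self):
        X, y = _linear_dataset()
        reg = BPAngleRegressor(epochs=500, eta0=0.5, seed=3, angle_range=(0.0, 8.0))
        reg.fit(X, y)
        rmse = np.sqrt(np.mean((reg.predict(X) - y) ** 2))
        assert rmse < 1.0 / 8.0  # < 1 degree equivalent on an 8-unit range

    def test_training_reduces_sse(self):
        X, y = _linear_dataset()
        reg = BPAngleRegressor(epochs=200, seed=0, angle_range=(0.0, 8.0)).fit(X, y)
        hist = reg.train_state_.sse_history
        assert hist[-1] < hist[0]

    def test_eta_trace_reconstructable_from_sse_history(self):
        """The realised learning-rate sequence is exactly the three-branch
        schedule applied to the recorded SSE history."""
        X, y = _linear_dataset()
        reg = BPAngleRegressor(epochs=300, seed=1, angle_range=(0.0, 8.0)).fit(X, y)
        st = reg.train_state_
        eta = st.eta_history[0]
        for k in range(1, len(st.sse_history)):
            eta = adapt_learning_rate(eta, st.sse_history[k], st.sse_history[k - 1])
            assert st.eta_history[k] == pytest.approx(eta, rel=1e-12)
            if st.sse_history[k] < st.sse_history[k - 1]:
                assert st.eta_history[k] == pytest.approx(1.05 * st.eta_history[k - 1])

    def test_seed_reproducibility(self):
        X, y = _linear_dataset()
        r1 = BPAngleRegressor(epochs=100, seed=5, angle_range=(0.0, 8.0)).fit(X, y)
        r2 = BPAngleRegressor(epochs=100, seed=5, angle_range=(0.0, 8.0)).fit(X, y)
        assert np.array_equal(r1.W1_, r2.W1_)
        assert r1.train_state_.sse_history == r2.train_state_.sse_history

    def test_mc_zero_matches_plain_gradient_descent_oracle(self):
        """With zero momentum and a fixed rate, the trainer must reproduce a
        textbook gradient-descent loop implemented independently."""
        X, y = _linear_dataset(n=50, seed=7)
        eta = 0.3
        epochs = 60
        reg = BPAngleRegressor(
            epochs=epochs, mc=0.0, eta0=eta, adapt_lr=False, seed=9, angle_range=(0.0, 8.0)
        ).fit(X, y)

        # independent oracle: same init scheme, explicit loops, no momentum
        rng = np.random.default_rng(9)
        W1 = rng.uniform(-0.5, 0.5, size=(8, 20))
        b1 = np.zeros(20)
        W2 = rng.uniform(-0.5, 0.5, size=(20, 1))
        b2 = np.zeros(1)
        ys = y / 8.0
        n = len(ys)
        sse_hist = []
        for _ in range(epochs):
            z = X @ W1 + b1
            a = 1.0 / (1.0 + np.exp(-z))
            yhat = (a @ W2 + b2).ravel()
            err = (ys - yhat) / n
            sse_hist.append(float(np.sum((ys - yhat) ** 2)))
            dW2 = a.T @ err[:, None]
            db2 = np.array([err.sum()])
            dh = (err[:, None] @ W2.T) * a * (1 - a)
            dW1 = X.T @ dh
            db1 = dh.sum(axis=0)
            W1 += eta * dW1
            b1 += eta * db1
            W2 += eta * dW2
            b2 += eta * db2
        assert np.allclose(reg.train_state_.sse_history, sse_hist, rtol=0, atol=1e-10)

    def test_divergence_guard(self):
        X, y = _linear_dataset(n=20)
        reg = BPAngleRegressor(epochs=5000, eta0=1e5, adapt_lr=False, seed=0, angle_range=(0.0, 8.0))
        with pytest.raises(RuntimeError, match="divergence"):
            reg.fit(X, y)

    def test_scaling_round_trip(self):
        reg = BPAngleRegressor(angle_range=(-30.0, 150.0))
        reg.angle_range_ = (-30.0, 150.0)
        y = np.linspace(-30, 150, 11)
        assert np.allclose(reg._unscale_y(reg._scale_y(y)), y, rtol=1e-12)

    def test_parameter_recovery_on_monotone_map(self):
        """Held-out RMSE stays within 2 degrees when targets follow a known
        monotone activation-to-angle map plus 1-degree noise."""
        rng = np.random.default_rng(12)
        X = rng.uniform(0, 1, size=(3000, N_INPUTS))
        angles = 90.0 * (X[:, 2] ** 1.5)  # monotone in one muscle channel
        y = angles + rng.normal(0, 1.0, size=3000)
        reg = BPAngleRegressor(epochs=4000, eta0=1.0, seed=4, angle_range=(0.0, 90.0))
        reg.fit(X[:2000], y[:2000])
        rmse = np.sqrt(np.mean((reg.predict(X[2000:]) - angles[2000:]) ** 2))
        assert rmse <= 2.0


class TestPredictTrajectory:
    @staticmethod
    def _trained_models():
        X, y = _linear_dataset(n=100)
        models = {}
        for i, dof in enumerate(DOF_NAMES):
            reg = BPAngleRegressor(epochs=5, seed=i, angle_range=DOF_RANGES[dof])
            reg.fit(X, np.clip(y * 10, *DOF_RANGES[dof]))
            models[dof] = reg
        return models

    def test_missing_model_rejected(self):
        models = self._trained_models()
        models.pop("elbow_flex")
        feats = FeatureSeries(np.zeros((7, 4)), np.arange(4.0))
        with pytest.raises(ValueError, match="elbow_flex"):
            predict_trajectory(models, feats, np.zeros(4))

    def test_output_clamped_to_ranges(self):
        models = self._trained_models()
        feats = FeatureSeries(np.ones((7, 6)), np.arange(6.0))
        traj = predict_trajectory(models, feats, np.linspace(0, 1, 6))
        for i, dof in enumerate(DOF_NAMES):
            lo, hi = DOF_RANGES[dof]
            assert np.all(traj.angles[i] >= lo - 5.0) and np.all(traj.angles[i] <= hi + 5.0)

    def test_constant_input_gives_constant_output(self):
        models = self._trained_models()
        feats = FeatureSeries(np.full((7, 10), 0.2), np.arange(10.0))
        traj = predict_trajectory(models, feats, np.full(10, 0.5))
        assert np.all(np.var(traj.angles, axis=1) < 0.5)
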