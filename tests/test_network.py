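"""Splitting, scaling, the network forward pass, and LM training."""

import numpy as np
import pytest

from ringdose.network import (MinMaxScaler, NetworkModel, TrainingConfig,
                              fit_scalers, forward, init_model, jacobian,
                              lm_train, make_split, predict, train_with_restarts)


class TestMakeSplit:
    @pytest.mark.parametrize("n,expected", [(218, (152, 33, 33)), (20, (14, 3, 3)),
                                            (10, (7, 2, 1))])
    def test_largest_remainder_sizes(self, n, expected):
        assert make_split(n, seed=0).sizes == expected

    def test_partition_and_determinism(self):
        s1 = make_split(50, seed=3)
        s2 = make_split(50, seed=3)
        s3 = make_split(50, seed=4)
        all_idx = np.sort(np.concatenate([s1.train_idx, s1.val_idx, s1.test_idx]))
        np.testing.assert_array_equal(all_idx, np.arange(50))
        np.testing.assert_array_equal(s1.train_idx, s2.train_idx)
        assert not np.array_equal(s1.train_idx, s3.train_idx)
        assert s3.sizes == s1.sizes

    def test_grouped_split_keeps_patients_together(self):
        groups = np.repeat(np.arange(20), 3)  # 20 patients x 3 fractions
        s = make_split(60, seed=1, group_ids=groups)
        for idx in (s.train_idx, s.val_idx, s.test_idx):
            present = set(groups[idx])
            for g in present:
                assert np.all(np.isin(np.flatnonzero(groups == g), idx))

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            make_split(2, seed=0)


class TestScalers:
    def test_min_max_map(self):
        sc = MinMaxScaler.fit(np.array([[0.0], [0.5]]))
        assert sc.transform(np.array([[0.25]]))[0, 0] == pytest.approx(0.0)
        assert sc.transform(np.array([[0.0]]))[0, 0] == pytest.approx(-1.0)
        assert sc.transform(np.array([[0.5]]))[0, 0] == pytest.approx(1.0)

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(-5, 9, size=(40, 6))
        sc = MinMaxScaler.fit(x)
        np.testing.assert_allclose(sc.inverse(sc.transform(x)), x, atol=1e-12)

    def test_constant_variable_maps_to_zero(self):
        x = np.column_stack([np.ones(10), np.arange(10.0)])
        sc = MinMaxScaler.fit(x)
        out = sc.transform(x)
        assert np.all(out[:, 0] == 0)
        assert out[:, 1].min() == -1 and out[:, 1].max() == 1


def toy_model(h=1, d=1):
    insc = MinMaxScaler(np.zeros(d) - 1, np.zeros(d) + 1)  # identity on [-1,1]
    tgsc = MinMaxScaler(np.array([-1.0]), np.array([1.0]))
    return NetworkModel(np.ones((h, d)), np.zeros(h), 2 * np.ones(h), 0.0, insc, tgsc)


class TestForward:
    def test_zero_weights_constant_output(self):
        m = toy_model()
        m.hidden_weights[:] = 0
        m.output_weights[:] = 0
        m.output_bias = 0.3
        x = np.random.default_rng(0).uniform(-1, 1, size=(5, 1))
        out = forward(m, x)
        expected = m.target_scaler.inverse(np.array([[0.3]]))[0, 0]
        np.testing.assert_allclose(out, expected)

    def test_hand_computed_single_unit(self):
        """Scaled x=0.5, W1=1, b1=0, W2=2, b2=0 -> 2 tanh(0.5) ~ 0.9242."""
        m = toy_model()
        out = forward(m, np.array([[0.5]]))
        scaled = 2 * np.tanh(0.5)
        expected = m.target_scaler.inverse(np.array([[scaled]]))[0, 0]
        assert out[0] == pytest.approx(expected)
        assert scaled == pytest.approx(0.92423, abs=1e-5)

    def test_unit_invariance_via_scaler(self):
        """Rescaling a raw feature and its scaler leaves predictions unchanged."""
        rng = np.random.default_rng(1)
        x = rng.uniform(10, 20, size=(30, 3))
        y = x @ np.array([0.3, -0.2, 0.1])
        insc, tgsc = fit_scalers(x, y)
        m = init_model(3, 4, np.random.default_rng(2), insc, tgsc)
        p1 = forward(m, x)
        x2 = x.copy()
        x2[:, 0] *= 1000.0
        insc2 = MinMaxScaler(insc.data_min * [1000, 1, 1], insc.data_max * [1000, 1, 1])
        m2 = NetworkModel(m.hidden_weights, m.hidden_bias, m.output_weights,
                          m.output_bias, insc2, tgsc)
        np.testing.assert_allclose(forward(m2, x2), p1, rtol=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            forward(toy_model(), np.ones((2, 3)))


def test_jacobian_matches_central_differences():
    rng = np.random.default_rng(3)
    insc = MinMaxScaler(-np.ones(4), np.ones(4))
    tgsc = MinMaxScaler(np.array([-1.0]), np.array([1.0]))
    m = init_model(4, 3, rng, insc, tgsc, output_bias0=0.1)
    xs = rng.uniform(-1, 1, size=(7, 4))
    J = jacobian(m, xs)
    theta0 = m.get_params()
    eps = 1e-6

    def f(theta):
        m.set_params(theta)
        a = np.tanh(xs @ m.hidden_weights.T + m.hidden_bias)
        return a @ m.output_weights + m.output_bias

    for k in range(len(theta0)):
        tp, tm = theta0.copy(), theta0.copy()
        tp[k] += eps
        tm[k] -= eps
        fd = (f(tp) - f(tm)) / (2 * eps)
        np.testing.assert_allclose(J[:, k], fd, rtol=1e-6, atol=1e-8)
    m.set_params(theta0)


def linear_problem(n=200, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, size=(n, 2))
    y = 3 * x[:, 0] - 2 * x[:, 1] + 1
    return x, y


class TestLmTrain:
    def test_noiseless_linear_target_matches_ols(self):
        x, y = linear_problem()
        insc, tgsc = fit_scalers(x, y)
        m = init_model(2, 10, np.random.default_rng(1), insc, tgsc,
                       output_bias0=float(tgsc.transform(y.reshape(-1, 1)).mean()))
        cfg = TrainingConfig(n_restarts=1, max_epochs=200)
        m, hist = lm_train(m, x, y, None, None, cfg)
        pred = forward(m, x)
        # least-squares oracle
        A = np.column_stack([x, np.ones(len(x))])
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        ols = A @ coef
        assert np.mean((pred - y) ** 2) <= 1e-8
        assert np.sqrt(np.mean((pred - ols) ** 2)) <= 1e-4

    def test_accepted_epoch_mse_strictly_decreasing(self):
        x, y = linear_problem(80, seed=2)
        insc, tgsc = fit_scalers(x, y)
        m = init_model(2, 5, np.random.default_rng(2), insc, tgsc)
        m, hist = lm_train(m, x, y, None, None, TrainingConfig(n_restarts=1, max_epochs=60))
        mses = hist.train_mse_per_epoch
        assert len(mses) > 3
        assert np.all(np.diff(mses) < 0)

    def test_zero_gradient_stops_immediately(self):
        """Targets equal to the initial model output -> no accepted epochs."""
        x = np.random.default_rng(4).uniform(0, 1, size=(30, 2))
        insc = MinMaxScaler(x.min(axis=0), x.max(axis=0))
        tgsc = MinMaxScaler(np.array([-1.0]), np.array([1.0]))
        m = init_model(2, 3, np.random.default_rng(5), insc, tgsc)
        y = forward(m, x)
        m2, hist = lm_train(m, x, y, None, None, TrainingConfig(n_restarts=1))
        assert hist.stop_reason == "min_grad"
        assert len(hist.epochs) == 0

    def test_empty_training_set_rejected(self):
        m = toy_model()
        with pytest.raises(ValueError):
            lm_train(m, np.empty((0, 1)), np.empty(0), None, None,
                     TrainingConfig(n_restarts=1))


class TestLmStepDirections:
    """LM interpolates between Gauss-Newton (mu=0) and gradient descent (mu large)."""

    def setup_method(self):
        rng = np.random.default_rng(6)
        self.xs = rng.uniform(-1, 1, size=(20, 1))
        insc = MinMaxScaler(np.array([-1.0]), np.array([1.0]))
        tgsc = MinMaxScaler(np.array([-1.0]), np.array([1.0]))
        self.m = init_model(1, 1, rng, insc, tgsc)
        self.ys = np.tanh(1.3 * self.xs[:, 0]) * 0.7 - 0.1

    def _J_e(self):
        a = np.tanh(self.xs @ self.m.hidden_weights.T + self.m.hidden_bias)
        pred = a @ self.m.output_weights + self.m.output_bias
        e = self.ys - pred
        return jacobian(self.m, self.xs), e

    def test_large_mu_step_parallels_gradient(self):
        J, e = self._J_e()
        g = J.T @ e
        mu = 1e9
        step = np.linalg.solve(J.T @ J + mu * np.eye(len(g)), g)
        cos = step @ g / (np.linalg.norm(step) * np.linalg.norm(g))
        assert cos == pytest.approx(1.0, abs=1e-6)

    def test_zero_mu_equals_gauss_newton(self):
        J, e = self._J_e()
        g = J.T @ e
        gn = np.linalg.solve(J.T @ J, g)
        lm = np.linalg.solve(J.T @ J + 0.0 * np.eye(len(g)), g)
        np.testing.assert_allclose(lm, gn, rtol=1e-10)


class TestRestarts:
    def test_single_restart_equals_lm_train(self):
        x, y = linear_problem(60, seed=7)
        split = make_split(60, seed=7)
        cfg = TrainingConfig(n_restarts=1, seed=9, hidden_size=4)
        best, summary = train_with_restarts(x, y, split, cfg)
        # replicate: same seed stream, same init, same data slices
        insc, tgsc = fit_scalers(x[split.train_idx], y[split.train_idx])
        rng = np.random.default_rng(np.random.SeedSequence(9).spawn(1)[0])
        m = init_model(2, 4, rng, insc, tgsc,
                       output_bias0=float(tgsc.transform(y[split.train_idx].reshape(-1, 1)).mean()))
        m, _ = lm_train(m, x[split.train_idx], y[split.train_idx],
                        x[split.val_idx], y[split.val_idx], cfg)
        np.testing.assert_allclose(best.get_params(), m.get_params())

    def test_best_of_many_no_worse_than_first(self):
        x, y = linear_problem(100, seed=8)
        y = y + 0.05 * np.random.default_rng(0).standard_normal(len(y))
        split = make_split(100, seed=8)
        s1 = train_with_restarts(x, y, split, TrainingConfig(n_restarts=1, seed=5, hidden_size=4))[1]
        s20 = train_with_restarts(x, y, split, TrainingConfig(n_restarts=20, seed=5, hidden_size=4))[1]
        assert s20["val_mse"].min() <= s1["val_mse"].iloc[0] + 1e-15
        assert len(s20) == 20
        assert {"restart", "train_mse", "val_mse", "epochs", "stop_reason"} <= set(s20.columns)


def test_planted_network_recovery():
    """Targets from a same-architecture teacher + sigma=0.02 noise: test R >= 0.95."""
    from scipy.stats import pearsonr

    rng = np.random.default_rng(12)
    n, d, h = 300, 5, 10
    x = rng.uniform(0, 1, size=(n, d))
    w1 = rng.normal(scale=1.0, size=(h, d))
    b1 = rng.normal(scale=0.5, size=h)
    w2 = rng.normal(scale=0.7, size=h)
    y = np.tanh(x @ w1.T + b1) @ w2 + 0.3 + 0.02 * rng.standard_normal(n)
    split = make_split(n, seed=12)
    model, _ = train_with_restarts(x, y, split, TrainingConfig(n_restarts=20, seed=12))
    pred = forward(model, x)
    r = pearsonr(pred[split.test_idx], y[split.test_idx]).statistic
    assert r >= 0.95


def test_predict_combines_ratio_and_d90():
    from ringdose.rings import SubOrganDecomposition

    x, y = linear_problem(50, seed=3)
    # embed the 2 informative features in the 16-slot layout
    X16 = np.zeros((50, 16))
    X16[:, 0:2] = x
    X16[:, 15] = 50.0 + x[:, 0]
    split = make_split(50, seed=3)
    model, _ = train_with_restarts(X16, y, split, TrainingConfig(n_restarts=2, seed=3, hidden_size=3))
    dec = SubOrganDecomposition(
        oar_label="bladder", ring_width_mm=3.0, n_rings=2,
        ring_volumes_cc=np.array([10.0, 20.0]),
        normalized_volumes=np.array([x[0, 0], x[0, 1]]),
        oar_volume_cc=100.0, hrctv_volume_cc=50.0 + x[0, 0],
        inside_volume_cc=0.0, far_volume_cc=70.0)
    ratio = predict(model, dec, hrctv_volume_cc=50.0 + x[0, 0])
    ratio2, absolute = predict(model, dec, hrctv_volume_cc=50.0 + x[0, 0], d90_gy=7.0)
    assert ratio == ratio2
    assert absolute == pytest.approx(7.0 * ratio)
    assert np.isfinite(ratio)
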