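"""Tests for the elastic-net regression: objective, solver, CV, selection."""

import numpy as np
import pytest

from stainmap.model import (
    DEFAULT_ALPHA_GRID, ElasticNetSpec, TrainingSet, cross_validate, fit,
    objective, predict, select_hyperparameters,
)


def make_set(m=40, n=4, sparsity=None, sigma=1.0, seed=0, n_groups=4):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(m, n))
    w = np.zeros(n)
    w[: (sparsity or n)] = rng.uniform(2, 6, size=(sparsity or n))
    y = np.clip(50 + X @ w + rng.normal(0, sigma, m), 0, 100)
    groups = np.repeat(np.arange(n_groups), m // n_groups)
    return TrainingSet(X, y, groups), w


class TestObjective:
    def test_zero_weights_reduce_to_mean_square(self):
        X = np.zeros((2, 1))
        assert objective(X, np.array([2.0, 2.0]), np.zeros(1), 1.0, 0.5) == 2.0

    def test_alpha_zero_is_pure_least_squares(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        w = np.array([1.0, -2.0])
        resid = X @ w - y
        assert objective(X, y, w, 0.0, 0.7) == pytest.approx(resid @ resid / 10)

    def test_term_by_term_hand_evaluation(self):
        X = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        y = np.array([1.0, 2.0, 3.0])
        w = np.array([1.0, -1.0])
        # residuals: (0, -3, -3); SSE=18; (1/2m)=18/6=3
        # L1: 1*0.5*2 = 1; L2: (1*0.5/2)*2 = 0.5
        assert objective(X, y, w, 1.0, 0.5) == pytest.approx(3 + 1 + 0.5)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            objective(np.zeros((3, 2)), np.zeros(3), np.zeros(3), 0.1, 0.5)


class TestFit:
    def test_alpha_zero_matches_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        y = rng.uniform(10, 90, size=5)
        ts = TrainingSet(X, y, np.arange(5))
        spec = fit(ts, 0.0, 0.5)
        Xs = (X - X.mean(0)) / X.std(0)
        coef = np.linalg.lstsq(np.column_stack([np.ones(5), Xs]), y, rcond=None)[0]
        assert np.abs(spec.omega - coef[1:]).max() < 1e-8
        assert spec.intercept == pytest.approx(coef[0])

    def test_total_shrinkage_limit(self):
        ts, _ = make_set(seed=2)
        spec = fit(ts, 1e6, 0.5)
        assert np.allclose(spec.omega, 0.0)
        assert np.allclose(predict(spec, ts.X), spec.intercept)

    def test_beats_brute_force_weight_grid(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(4, 2))
        y = rng.uniform(0, 10, size=4)
        ts = TrainingSet(X, y, np.arange(4))
        alpha, rho = 0.1, 0.5
        spec = fit(ts, alpha, rho)
        Xs = (X - X.mean(0)) / X.std(0)
        yc = y - y.mean()
        fitted = objective(Xs, yc, spec.omega, alpha, rho)
        grid = np.linspace(-3, 3, 200)
        w0, w1 = np.meshgrid(grid, grid, indexing="ij")
        best = np.inf
        for a in range(200):
            resid = Xs @ np.vstack([np.full(200, grid[a]), grid]) - yc[:, None]
            vals = (resid ** 2).sum(0) / (2 * 4) \
                + alpha * rho * (abs(grid[a]) + np.abs(grid)) \
                + alpha * (1 - rho) / 2 * (grid[a] ** 2 + grid ** 2)
            best = min(best, vals.min())
        assert fitted <= best + 1e-9

    def test_matches_sklearn_elastic_net(self):
        sklearn = pytest.importorskip("sklearn.linear_model")
        ts, _ = make_set(m=200, n=5, sigma=2.0, seed=4)
        for alpha, rho in [(0.5, 0.5), (0.1, 1.0), (2.0, 0.2)]:
            spec = fit(ts, alpha, rho)
            Xs = (ts.X - ts.X.mean(0)) / ts.X.std(0)
            ref = sklearn.ElasticNet(alpha=alpha, l1_ratio=rho, fit_intercept=True,
                                     tol=1e-10, max_iter=100000).fit(Xs, ts.y)
            assert np.abs(spec.omega - ref.coef_).max() < 1e-4

    def test_constant_feature_gets_zero_weight(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 3))
        X[:, 1] = 7.0
        y = np.clip(50 + X[:, 0], 0, 100)
        spec = fit(TrainingSet(X, y, np.arange(30)), 0.01, 0.5)
        assert spec.omega[1] == 0.0

    def test_objective_monotone_in_alpha(self):
        ts, _ = make_set(m=100, n=4, sigma=2.0, seed=6)
        Xs = (ts.X - ts.X.mean(0)) / ts.X.std(0)
        yc = ts.y - ts.y.mean()
        last = -np.inf
        for alpha in [0.0, 0.01, 0.1, 1.0, 10.0]:
            spec = fit(ts, alpha, 0.5)
            value = objective(Xs, yc, spec.omega, alpha, 0.5)
            assert value >= last - 1e-10
            last = value

    def test_l1_norm_shrinks_with_alpha(self):
        ts, _ = make_set(m=100, n=4, sigma=2.0, seed=7)
        norms = [np.abs(fit(ts, alpha, 0.5).omega).sum()
                 for alpha in [1e-3, 1e-2, 1e-1, 1.0, 10.0]]
        for a, b in zip(norms, norms[1:]):
            assert b <= a + 1e-8

    def test_sparse_signal_recovery(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(400, 7))
        w_true = np.array([4.0, 0, 0, -3.0, 0, 0, 2.0])
        y = np.clip(50 + X @ w_true + rng.normal(0, 0.5, 400), 0, 100)
        ts = TrainingSet(X, y, np.repeat(np.arange(10), 40))
        spec = fit(ts, 0.01, 1.0)
        w_hat = spec.omega / spec.scale  # back to the raw-feature scale
        assert (np.sign(w_hat[np.abs(w_true) > 0]) ==
                np.sign(w_true[np.abs(w_true) > 0])).all()
        assert np.abs(w_hat - w_true).max() <= 0.1 * np.abs(w_true).max()


class TestCrossValidate:
    def test_folds_are_groups(self):
        ts, _ = make_set(m=400, n=3, n_groups=10, seed=9)
        per_fold, mean_value = cross_validate(ts, 0.1, 0.5)
        assert len(per_fold) == 10
        assert mean_value == pytest.approx(per_fold.mean())

    def test_degenerate_leave_one_out(self):
        # two groups of one example each at alpha=0: each fold predicts the
        # other example's value through the intercept
        ts = TrainingSet(np.array([[1.0], [2.0]]), np.array([10.0, 30.0]),
                         np.array(["a", "b"]))
        per_fold, _ = cross_validate(ts, 0.0, 0.5, criterion="mse")
        assert per_fold[0] == pytest.approx((10.0 - 30.0) ** 2)
        assert per_fold[1] == pytest.approx((30.0 - 10.0) ** 2)

    def test_single_group_rejected(self):
        ts, _ = make_set(n_groups=1)
        with pytest.raises(ValueError):
            cross_validate(ts, 0.1, 0.5)


class TestSelectHyperparameters:
    def test_singleton_grid(self):
        ts, _ = make_set(seed=10)
        alpha, rho, report = select_hyperparameters(ts, [0.3], [0.7])
        assert (alpha, rho) == (0.3, 0.7)
        assert len(report) == 1

    def test_exhaustive_minimum(self):
        ts, _ = make_set(m=200, n=5, sparsity=2, sigma=0.5, seed=11, n_groups=5)
        alphas, rhos = [1e-3, 1e-2, 1e-1, 1.0], [0.3, 0.7, 1.0]
        alpha, rho, report = select_hyperparameters(ts, alphas, rhos)
        chosen = [r for r in report if r["alpha"] == alpha and r["rho"] == rho][0]
        assert all(chosen["mean_cv_value"] <= r["mean_cv_value"] for r in report)

    def test_tie_breaks_toward_larger_alpha(self):
        ts, _ = make_set(seed=12)
        # at extreme shrinkage every grid point collapses to the intercept
        alpha, rho, _ = select_hyperparameters(ts, [1e7, 1e9], [0.5, 1.0])
        assert alpha == 1e9 and rho == 1.0


class TestPredict:
    def test_zero_weights_predict_intercept(self):
        spec = ElasticNetSpec(omega=np.zeros(2), intercept=42.0, alpha=1, rho=0.5,
                              mean=np.zeros(2), scale=np.ones(2))
        assert np.allclose(predict(spec, np.random.default_rng(0).normal(size=(5, 2))),
                           42.0)

    def test_identity_standardization_passthrough(self):
        spec = ElasticNetSpec(omega=np.array([1.0, 0.0]), intercept=0.0, alpha=0,
                              rho=0.5, mean=np.zeros(2), scale=np.ones(2))
        X = np.array([[3.0, 9.0], [-1.0, 4.0]])
        assert np.allclose(predict(spec, X), X[:, 0])

    def test_clipping(self):
        spec = ElasticNetSpec(omega=np.array([100.0]), intercept=50.0, alpha=0,
                              rho=0.5, mean=np.zeros(1), scale=np.ones(1))
        out = predict(spec, np.array([[10.0], [-10.0]]), clip=True)
        assert out.min() >= 0.0 and out.max() <= 100.0

    def test_generative_rmse_near_noise_floor(self):
        rng = np.random.default_rng(13)
        X = rng.normal(size=(400, 3))
        y = np.clip(50 + 0.5 * X[:, 0] * 20 + rng.normal(0, 1.0, 400), 0, 100)
        ts = TrainingSet(X, y, np.repeat(np.arange(10), 40))
        spec = fit(ts, 1e-3, 0.5)
        rmse = float(np.sqrt(np.mean((predict(spec, X) - y) ** 2)))
        assert abs(rmse - 1.0) < 0.2

    def test_wrong_column_count(self):
        spec = ElasticNetSpec(omega=np.zeros(3), intercept=0.0, alpha=0, rho=0.5,
                              mean=np.zeros(3), scale=np.ones(3))
        with pytest.raises(ValueError):
            predict(spec, np.zeros((2, 2)))


class TestSerialization:
    def test_json_round_trip(self):
        ts, _ = make_set(seed=14)
        spec = fit(ts, 0.2, 0.8)
        back = ElasticNetSpec.from_json(spec.to_json())
        assert np.allclose(back.omega, spec.omega)
        assert back.alpha == spec.alpha and back.rho == spec.rho
        assert np.allclose(predict(back, ts.X), predict(spec, ts.X))
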