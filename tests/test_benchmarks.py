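"""MLR, classical SIMPLS and LSSVM comparators."""

import numpy as np
import pytest

from bittertongue import benchmarks, selection


class TestMLR:
    def test_simple_regression(self):
        m = benchmarks.mlr_fit(np.array([[1.0], [2.0], [3.0]]), [2.0, 4.0, 6.0])
        assert m.coefficients[0] == pytest.approx(2.0)
        assert m.intercept == pytest.approx(0.0, abs=1e-12)

    def test_constant_response(self):
        rng = np.random.default_rng(0)
        m = benchmarks.mlr_fit(rng.normal(size=(10, 2)), np.full(10, 4.2))
        assert np.abs(m.coefficients).max() < 1e-10
        assert m.intercept == pytest.approx(4.2)

    def test_normal_equations(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        m = benchmarks.mlr_fit(X, y)
        resid = y - m.predict(X)
        assert np.abs(X.T @ resid).max() < 1e-8

    def test_rank_deficiency_suggests_pls(self):
        X = np.outer(np.arange(6.0), [1.0, 2.0])
        with pytest.raises(ValueError, match="PLS"):
            benchmarks.mlr_fit(X, np.arange(6.0))


class TestSIMPLS:
    def test_full_rank_equals_mlr(self, small_regression):
        X, y, _ = small_regression
        pls = benchmarks.simpls_fit(X, y, k=5)
        ml = benchmarks.mlr_fit(X, y)
        assert np.abs(pls.coefficients - ml.coefficients).max() < 1e-8

    def test_handles_collinearity(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=12)
        X = np.column_stack([x, x])  # perfectly collinear
        y = 2 * x + rng.normal(size=12) * 0.01
        with pytest.raises(ValueError):
            benchmarks.mlr_fit(X, y)
        pls = benchmarks.simpls_fit(X, y, k=1)
        assert np.corrcoef(pls.predict(X), y)[0, 1] > 0.99

    def test_univariate_equals_simple_regression(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=15)
        y = 3 * x + 1 + rng.normal(size=15) * 0.1
        pls = benchmarks.simpls_fit(x.reshape(-1, 1), y, k=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        assert pls.coefficients[0] == pytest.approx(slope, rel=1e-10)

    def test_matches_sklearn_pls1(self, small_regression):
        PLSRegression = pytest.importorskip(
            "sklearn.cross_decomposition"
        ).PLSRegression
        X, y, _ = small_regression
        for k in (1, 2, 3):
            ours = benchmarks.simpls_fit(X, y, k=k)
            ref = PLSRegression(n_components=k, scale=False).fit(X, y)
            assert np.abs(ours.coefficients - ref.coef_.ravel()).max() < 1e-10


class TestLSSVM:
    def test_system_residual_contract(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        m = benchmarks.lssvm_fit(X, y, 100.0, 10.0, standardize=False)
        K = benchmarks._rbf_kernel(X, X, 10.0)
        A = np.zeros((21, 21))
        A[0, 1:] = 1.0
        A[1:, 0] = 1.0
        A[1:, 1:] = K + np.eye(20) / 100.0
        sol = np.concatenate([[m.bias], m.alphas])
        rhs = np.concatenate([[0.0], y])
        assert np.linalg.norm(A @ sol - rhs) <= 1e-8 * np.linalg.norm(rhs)

    def test_single_point_interpolated_at_high_regularization(self):
        m = benchmarks.lssvm_fit(np.array([[1.0, 2.0]]), [3.7], 1e8, 1.0)
        assert m.predict([[1.0, 2.0]])[0] == pytest.approx(3.7, abs=1e-4)

    def test_interpolation_limit(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 2))
        y = rng.normal(size=5)
        m = benchmarks.lssvm_fit(X, y, 1e8, 2.0)
        assert np.abs(m.predict(X) - y).max() < 1e-4

    def test_loo_shortcut_equals_naive_refit(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(18, 3))
        y = X @ [1.0, 2.0, -1.0] + rng.normal(size=18) * 0.3
        fast = benchmarks.lssvm_loocv_residuals(X, y, 100.0, 10.0, standardize=False)
        naive = y - selection.loocv_predictions(
            X,
            y,
            lambda Xa, ya, seed=0: benchmarks.lssvm_fit(
                Xa, ya, 100.0, 10.0, standardize=False
            ),
        )
        assert np.abs(fast - naive).max() < 1e-10

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            benchmarks.lssvm_fit(np.zeros((3, 1)), np.zeros(3), -1.0, 1.0)


class TestTuneLSSVM:
    def test_single_point_grid(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        hp, res = benchmarks.tune_lssvm(X, y, reg_grid=(10.0,), width_grid=(1.0,))
        assert hp == {"reg_gamma": 10.0, "kernel_width": 1.0}

    def test_argmin_matches_exhaustive_recomputation(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 2))
        y = X @ [1.0, -2.0] + rng.normal(size=15) * 0.2
        reg_grid, width_grid = (0.1, 10.0, 1000.0), (0.5, 5.0)
        hp, _ = benchmarks.tune_lssvm(X, y, reg_grid, width_grid)
        scores = {
            (rg, wd): np.sqrt(
                (benchmarks.lssvm_loocv_residuals(X, y, rg, wd) ** 2).mean()
            )
            for rg in reg_grid
            for wd in width_grid
        }
        best = min(scores, key=lambda key: (scores[key], key))
        assert (hp["reg_gamma"], hp["kernel_width"]) == best

    def test_tuned_close_to_mlr_on_linear_data(self, clean_dataset):
        ds, _ = clean_dataset
        hp, res = benchmarks.tune_lssvm(ds.X, ds.y, seed=0)
        mlr_res = benchmarks.evaluate_method(ds.X, ds.y, "mlr", seed=0)
        assert res.rmsecv <= 1.5 * mlr_res.rmsecv


class TestEvaluateMethod:
    def test_exact_linear_data(self):
        X = np.arange(1.0, 7.0).reshape(-1, 1)
        y = 2 * X.ravel() + 1
        res = benchmarks.evaluate_method(X, y, "mlr")
        assert res.rmsecv < 1e-10
        assert res.r2_cv == pytest.approx(1.0)

    def test_degenerate_predictions_flagged(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(8, 1))
        y = np.full(8, 2.0)
        res = benchmarks.evaluate_method(X, y, "mlr")
        assert res.degenerate_r2
        assert res.r2_cv == 0.0

    def test_deterministic(self, clean_dataset):
        ds, _ = clean_dataset
        a = benchmarks.evaluate_method(ds.X, ds.y, "rpls", {"k": 1}, seed=3)
        b = benchmarks.evaluate_method(ds.X, ds.y, "rpls", {"k": 1}, seed=3)
        assert a.rmsecv == b.rmsecv and a.r2_cv == b.r2_cv

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="unknown method"):
            benchmarks.evaluate_method(np.zeros((5, 1)), np.arange(5.0), "bpnn")
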