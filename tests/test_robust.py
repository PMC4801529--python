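"""Robust estimators: MCD (exact and fast), robust PCA, robust SIMPLS."""

import itertools

import numpy as np
import pytest

from bittertongue import robust
from bittertongue.benchmarks import mlr_fit, simpls_fit
from bittertongue.synthetic import SyntheticConfig, generate_dataset


class TestExactMCD:
    def test_outlier_excluded_1d(self):
        res = robust.exact_mcd(np.array([0.0, 0.0, 0.0, 100.0]), h=3)
        assert res.center[0] == 0.0
        assert res.support.tolist() == [0, 1, 2]

    def test_h_equals_n_is_classical(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(8, 2))
        res = robust.exact_mcd(X, h=8)
        assert np.allclose(res.center, X.mean(axis=0))
        assert np.allclose(res.scatter, np.cov(X.T, ddof=1))

    def test_planted_points_outside_support_and_det_minimal(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(8, 2))
        X[3] += 40.0
        X[6] -= 40.0
        res = robust.exact_mcd(X, h=6)
        assert 3 not in res.support and 6 not in res.support
        # full scan: no 6-subset has a smaller covariance determinant
        best = np.linalg.det(np.cov(X[res.support].T, ddof=1))
        for comb in itertools.combinations(range(8), 6):
            det = np.linalg.det(np.cov(X[list(comb)].T, ddof=1))
            assert best <= det + 1e-12

    def test_refuses_large_n(self):
        with pytest.raises(ValueError, match="n must be"):
            robust.exact_mcd(np.zeros((16, 1)), h=10)


class TestFastMCD:
    def test_matches_exact_on_small_instances(self):
        mismatches = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            n = int(rng.integers(8, 13))
            d = int(rng.integers(1, 4))
            X = rng.normal(size=(n, d))
            n_out = int(rng.integers(1, 3))
            X[:n_out] += 10.0
            h = max(int(np.floor(0.75 * n)), int(np.ceil((n + d + 1) / 2)))
            e = robust.exact_mcd(X, h=h)
            f = robust.fast_mcd(X, h=h, seed=seed)
            if not np.array_equal(np.sort(e.support), np.sort(f.support)):
                mismatches += 1
        assert mismatches == 0

    def test_clean_bivariate_center(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 2)) + [1.0, -2.0]
        res = robust.fast_mcd(X, alpha=0.75, seed=0)
        assert np.linalg.norm(res.center - [1.0, -2.0]) < 0.15
        # consistency correction keeps the scatter near the identity
        assert np.all(np.abs(np.diag(res.scatter) - 1.0) < 0.25)

    def test_determinant_non_increasing(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(60, 3))
        X[:6] += 8.0
        res = robust.fast_mcd(X, seed=1)
        trace = np.asarray(res.det_trace)
        assert np.all(np.diff(trace) <= 1e-9)

    def test_h_equals_n_classical(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 2))
        res = robust.fast_mcd(X, h=40, seed=0)
        assert np.allclose(res.center, X.mean(axis=0))
        assert np.allclose(res.scatter, np.cov(X.T, ddof=1))

    def test_agrees_with_sklearn_mincovdet(self):
        sklearn_cov = pytest.importorskip("sklearn.covariance")
        rng = np.random.default_rng(6)
        X = rng.normal(size=(200, 3))
        X[:20] += 12.0
        ours = robust.fast_mcd(X, alpha=0.5, seed=0)
        ref = sklearn_cov.MinCovDet(random_state=0, support_fraction=0.5).fit(X)
        assert np.linalg.norm(ours.center - ref.location_) < 0.3
        # both must exclude the planted block from the raw support
        assert not set(range(20)) & set(ours.support.tolist())

    def test_exact_fit_detected(self):
        X = np.zeros((20, 2))
        X[:, 0] = np.arange(20)  # all points on a line
        with pytest.raises(robust.ExactFitError):
            robust.fast_mcd(X, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(80, 3))
        a = robust.fast_mcd(X, seed=42)
        b = robust.fast_mcd(X, seed=42)
        assert np.array_equal(a.support, b.support)
        assert np.array_equal(a.scatter, b.scatter)


class TestRobpca:
    def test_clean_eigenvalues_near_classical(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(1000, 3)) * np.array([3.0, 2.0, 1.0])
        res = robust.robpca(X, k=3, alpha=0.75, seed=0)
        robust_eigs = np.sort(np.linalg.eigvalsh(res.location_scatter.scatter))[::-1]
        classical_eigs = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=1)))[::-1]
        assert np.all(np.abs(robust_eigs / classical_eigs - 1.0) < 0.25)

    def test_orthogonal_outliers_outside_h_subset(self):
        rng = np.random.default_rng(10)
        n = 200
        T = rng.normal(size=(n, 2)) @ np.array([[4.0, 0.0, 0.0], [0.0, 2.0, 0.0]])
        X = T + 0.1 * rng.normal(size=(n, 3))
        planted = np.arange(0, n, 10)  # 10%
        X[planted, 2] += 50 * 0.1
        res = robust.robpca(X, k=2, alpha=0.75, seed=0)
        assert not set(planted.tolist()) & set(res.h_subset.tolist())
        # and their outlyingness dominates that of the clean points
        clean = np.setdiff1d(np.arange(n), planted)
        assert res.outlyingness[planted].min() > res.outlyingness[clean].max()

    def test_alpha_one_is_classical_pca(self):
        rng = np.random.default_rng(11)
        X = rng.normal(size=(100, 4)) * np.array([3.0, 2.0, 1.0, 0.5])
        loadings = robust.robpca(X, k=2, alpha=1.0, seed=0).loadings
        vals, vecs = np.linalg.eigh(np.cov(X.T, ddof=1))
        classical = vecs[:, ::-1][:, :2]
        # principal angles between the two subspaces
        s = np.linalg.svd(loadings.T @ classical, compute_uv=False)
        angles = np.arccos(np.clip(s, -1, 1))
        assert np.max(angles) < 1e-6

    def test_k_beyond_rank_refused(self):
        X = np.outer(np.arange(10.0), [1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="rank"):
            robust.robpca(X, k=2, alpha=0.75, seed=0)


class TestRSIMPLS:
    def test_close_to_classical_on_clean_data(self, clean_dataset):
        ds, truth = clean_dataset
        rm = robust.rsimpls_fit(ds.X, ds.y, 1, alpha=0.75, seed=1)
        cm = simpls_fit(ds.X, ds.y, 1)
        rel = np.linalg.norm(rm.coefficients - cm.coefficients) / np.linalg.norm(
            cm.coefficients
        )
        assert rel < 0.02

    def test_resists_bad_leverage(self, leverage_dataset):
        ds, truth = leverage_dataset
        beta = truth.regression_coefficients
        rm = robust.rsimpls_fit(ds.X, ds.y, 1, alpha=0.75, seed=1)
        cm = simpls_fit(ds.X, ds.y, 1)
        err_robust = np.linalg.norm(rm.coefficients - beta)
        err_classical = np.linalg.norm(cm.coefficients - beta)
        assert err_robust <= 0.2 * err_classical

    def test_classical_full_rank_equals_mlr(self, small_regression):
        X, y, _ = small_regression
        m = robust.rsimpls_fit(X, y, 5, alpha=1.0)
        ml = mlr_fit(X, y)
        assert np.abs(m.coefficients - ml.coefficients).max() < 1e-8
        assert abs(m.intercept - ml.intercept) < 1e-8

    def test_prediction_round_trips(self, small_regression):
        X, y, _ = small_regression
        m = robust.rsimpls_fit(X, y, 3, alpha=0.75, seed=0)
        pred_direct = robust.rpls_predict(m, X)
        eq = robust.equation_original_form(m, sensor_names=[f"s{i}" for i in range(5)])
        assert np.abs(eq.predict(X) - pred_direct).max() < 1e-10
        zero = robust.RPLSModel(
            k=1, weights=np.zeros((5, 1)), x_center=np.zeros(5),
            scores=None, score_center=np.zeros(1), score_scatter=np.eye(1),
            coefficients=np.zeros(5), intercept=3.5, residual_scale=1.0,
            case_weights=np.ones(30), alpha=1.0, seed=0,
        )
        assert np.all(zero.predict(X) == 3.5)

    def test_column_scaling_equivariance_full_rank(self, clean_dataset):
        # PLS weights are scale-dependent for k < p, so the clean
        # coefficient-rescaling identity is a full-rank (k = p) property
        ds, _ = clean_dataset
        m1 = robust.rsimpls_fit(ds.X, ds.y, 7, alpha=0.75, seed=3)
        X2 = ds.X.copy()
        X2[:, 2] *= 10.0
        m2 = robust.rsimpls_fit(X2, ds.y, 7, alpha=0.75, seed=3)
        assert m2.coefficients[2] == pytest.approx(m1.coefficients[2] / 10.0, rel=1e-8)
        assert np.abs(m2.predict(X2) - m1.predict(ds.X)).max() < 1e-8

    def test_affine_equivariance_of_predictions(self, clean_dataset):
        ds, _ = clean_dataset
        m1 = robust.rsimpls_fit(ds.X, ds.y, 7, alpha=0.75, seed=4)
        scale = np.array([2.0, 0.5, 3.0, 1.0, 0.1, 5.0, 1.5])
        shift = np.array([10.0, -5.0, 0.0, 100.0, 3.0, -2.0, 7.0])
        X2 = ds.X * scale + shift
        m2 = robust.rsimpls_fit(X2, ds.y, 7, alpha=0.75, seed=4)
        assert np.abs(m2.predict(X2) - m1.predict(ds.X)).max() < 1e-8

    def test_single_response_outlier_bounded(self, clean_dataset):
        ds, _ = clean_dataset
        base = robust.rsimpls_fit(ds.X, ds.y, 1, alpha=0.75, seed=5)
        shifts = []
        for magnitude in (50.0, 500.0):
            y2 = ds.y.copy()
            y2[0] += magnitude
            m = robust.rsimpls_fit(ds.X, y2, 1, alpha=0.75, seed=5)
            shifts.append(
                np.linalg.norm(m.coefficients - base.coefficients)
                / np.linalg.norm(base.coefficients)
            )
        # a tenfold larger outlier must not move the fit further
        assert shifts[1] <= shifts[0] + 1e-8
        assert shifts[1] < 0.5

    def test_serialization_round_trip(self, tmp_path, small_regression):
        X, y, _ = small_regression
        m = robust.rsimpls_fit(X, y, 2, alpha=0.75, seed=6)
        path = tmp_path / "model.json"
        m.save(path)
        back = robust.RPLSModel.load(path)
        assert np.array_equal(back.predict(X), m.predict(X))
        assert back.k == m.k and back.alpha == m.alpha

    def test_invalid_inputs(self, small_regression):
        X, y, _ = small_regression
        with pytest.raises(ValueError, match="k="):
            robust.rsimpls_fit(X, y, 6)
        with pytest.raises(ValueError, match="zero variance"):
            robust.rsimpls_fit(X, np.ones_like(y), 2)
        with pytest.raises(ValueError, match="alpha"):
            robust.rsimpls_fit(X, y, 2, alpha=0.3)
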