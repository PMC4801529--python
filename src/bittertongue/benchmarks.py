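"""Benchmark regressors: MLR, classical SIMPLS, and RBF-kernel LSSVM.

These are the comparison methods the robust calibration is judged
against, each evaluated by leave-one-out cross-validation (RMSECV and the
squared correlation R2_CV between the held-out predictions and the panel
response).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import selection
from .robust import RPLSModel, rsimpls_fit, simpls_weights

METHODS = ("mlr", "pls", "lssvm", "rpls")

#: Default joint log-spaced LSSVM tuning grid.
DEFAULT_REG_GRID = tuple(10.0**e for e in range(-2, 7))
DEFAULT_WIDTH_GRID = tuple(10.0**e for e in range(-2, 5))


@dataclass
class LinearModel:
    """Ordinary linear model: yhat = intercept + X b."""

    coefficients: np.ndarray
    intercept: float

    def predict(self, X_new) -> np.ndarray:
        return self.intercept + np.asarray(X_new, dtype=float) @ self.coefficients


@dataclass
class LSSVMModel:
    """Least squares SVM regressor with an RBF kernel.

    The kernel is K(x, z) = exp(-||x - z||^2 / width): ``width`` is the
    squared length-scale appearing in the exponent denominator.  When the
    model was fit with standardization, distances are taken on per-column
    z-scores of the training data so that one width grid serves any
    sensor scale.
    """

    X_train: np.ndarray  # stored on the kernel scale
    alphas: np.ndarray
    bias: float
    reg_gamma: float
    width: float
    x_mean: np.ndarray = None
    x_scale: np.ndarray = None

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if self.x_mean is not None:
            X_new = (X_new - self.x_mean) / self.x_scale
        K = _rbf_kernel(X_new, self.X_train, self.width)
        return self.bias + K @ self.alphas


@dataclass
class BenchmarkResult:
    """LOOCV performance of one method on one dataset variant."""

    method: str
    hyperparams: dict
    r2_cv: float
    rmsecv: float
    dataset_variant: str = "pre_screen"
    degenerate_r2: bool = False
    predictions: np.ndarray = field(default=None, repr=False)


def mlr_fit(X, y, seed: int = 0) -> LinearModel:
    """Ordinary least squares through a rank-revealing lstsq solve."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if n <= p:
        raise ValueError(f"MLR needs n > p (n={n}, p={p})")
    A = np.column_stack([np.ones(n), X])
    sol, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        raise ValueError(
            "predictor matrix is rank deficient; use PLS for collinear sensors"
        )
    return LinearModel(coefficients=sol[1:], intercept=float(sol[0]))


def simpls_fit(X, y, k: int, seed: int = 0) -> RPLSModel:
    """Classical SIMPLS: the robust fit on the all-weights-1 classical path."""
    return rsimpls_fit(X, y, k, alpha=1.0, seed=seed)


def _rbf_kernel(A: np.ndarray, B: np.ndarray, width: float) -> np.ndarray:
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
    return np.exp(-d2 / width)


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def lssvm_fit(
    X, y, reg_gamma: float, kernel_width: float, seed: int = 0,
    *, standardize: bool = True,
) -> LSSVMModel:
    """Solve the LSSVM dual system [[0, 1'], [1, K + I/reg_gamma]] [b; a] = [0; y].

    With ``standardize`` (default) the kernel acts on per-column z-scores
    of the training data.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if reg_gamma <= 0 or kernel_width <= 0:
        raise ValueError("reg_gamma and kernel_width must be positive")
    n = X.shape[0]
    x_mean = x_scale = None
    if standardize:
        X, x_mean, x_scale = _standardize(X)
    K = _rbf_kernel(X, X, kernel_width)
    A = np.zeros((n + 1, n + 1))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(n) / reg_gamma
    rhs = np.concatenate([[0.0], y])
    sol = np.linalg.solve(A, rhs)
    resid = np.linalg.norm(A @ sol - rhs)
    ynorm = max(np.linalg.norm(rhs), 1e-300)
    if resid > 1e-8 * ynorm:
        cond = np.linalg.cond(A)
        warnings.warn(
            f"LSSVM system ill-conditioned (cond ~ {cond:.2e}); "
            f"relative residual {resid / ynorm:.2e}",
            stacklevel=2,
        )
    return LSSVMModel(
        X_train=X,
        alphas=sol[1:],
        bias=float(sol[0]),
        reg_gamma=reg_gamma,
        width=kernel_width,
        x_mean=x_mean,
        x_scale=x_scale,
    )


def _fitter_for(method: str, hyperparams: dict):
    hp = dict(hyperparams or {})
    if method == "mlr":
        return lambda X, y, seed=0: mlr_fit(X, y)
    if method == "pls":
        k = hp.get("k", 1)
        return lambda X, y, seed=0: simpls_fit(X, y, min(k, X.shape[0] - 1), seed=seed)
    if method == "lssvm":
        return lambda X, y, seed=0: lssvm_fit(
            X, y, hp.get("reg_gamma", 1e2), hp.get("kernel_width", 1e2)
        )
    if method == "rpls":
        k = hp.get("k", 1)
        alpha = hp.get("alpha", 0.75)
        return lambda X, y, seed=0: rsimpls_fit(
            X, y, min(k, X.shape[0] - 1), alpha=alpha, seed=seed
        )
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def evaluate_method(
    X, y, method: str, hyperparams: dict | None = None, *, seed: int = 0,
    dataset_variant: str = "pre_screen", robust_weights: bool | None = None,
) -> BenchmarkResult:
    """LOOCV RMSECV and R2_CV for one method at fixed hyperparameters.

    R2_CV is the squared Pearson correlation between the response and the
    held-out predictions; it is reported as 0 with a degeneracy flag when
    the predictions have zero variance.

    For the robust method the recorded errors are the robust (R-) variants:
    the case weights of a robust fit on the evaluation data zero out the
    samples it flags, since the robust model declines to fit gross outliers
    by design and charging it for their prediction errors would measure the
    opposite of what it promises.  The classical comparators are scored on
    all samples (all weights 1).  Set ``robust_weights`` to override.
    """
    y = np.asarray(y, dtype=float).ravel()
    preds = selection.loocv_predictions(
        X, y, _fitter_for(method, hyperparams), seed=seed
    )
    if robust_weights is None:
        robust_weights = method == "rpls"
    if robust_weights:
        hp = dict(hyperparams or {})
        k = min(hp.get("k", 1), X.shape[0] - 2)
        ref = rsimpls_fit(X, y, k, alpha=hp.get("alpha", 0.75), seed=seed)
        w = ref.case_weights
    else:
        w = np.ones_like(y)
    rmsecv = selection.weighted_rmse(y, preds, w)
    kept = w > 0
    degenerate = np.std(preds[kept]) == 0 or np.std(y[kept]) == 0
    r2 = (
        0.0
        if degenerate
        else float(np.corrcoef(y[kept], preds[kept])[0, 1] ** 2)
    )
    return BenchmarkResult(
        method=method,
        hyperparams=dict(hyperparams or {}),
        r2_cv=r2,
        rmsecv=rmsecv,
        dataset_variant=dataset_variant,
        degenerate_r2=degenerate,
        predictions=preds,
    )


def lssvm_loocv_residuals(
    X, y, reg_gamma: float, kernel_width: float, *, standardize: bool = True
) -> np.ndarray:
    """Approximate leave-one-out residuals of the LSSVM from one full solve.

    For the augmented system C [b; a] = [0; y] the held-out residual of
    sample i is a_i / (C^{-1})_{i+1, i+1}, the standard closed form for
    regularized kernel regression with an unpenalized bias.  (With
    standardization the z-scoring is done once on the full data, so the
    residuals differ from fold-by-fold refitting only through the fold's
    column means/sds; without standardization the identity is exact.)
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if standardize:
        X, _, _ = _standardize(X)
    K = _rbf_kernel(X, X, kernel_width)
    C = np.zeros((n + 1, n + 1))
    C[0, 1:] = 1.0
    C[1:, 0] = 1.0
    C[1:, 1:] = K + np.eye(n) / reg_gamma
    Cinv = np.linalg.inv(C)
    sol = Cinv @ np.concatenate([[0.0], y])
    alphas = sol[1:]
    diag = np.diag(Cinv)[1:]
    return alphas / diag


def tune_lssvm(
    X,
    y,
    reg_grid=DEFAULT_REG_GRID,
    width_grid=DEFAULT_WIDTH_GRID,
    *,
    seed: int = 0,
) -> tuple[dict, BenchmarkResult]:
    """Joint grid search of (reg_gamma, kernel_width) by LOOCV RMSECV.

    Uses the closed-form LOO residuals; ties break toward the smallest
    reg_gamma, then the smallest width.
    """
    y = np.asarray(y, dtype=float).ravel()
    reg_grid = tuple(reg_grid)
    width_grid = tuple(width_grid)
    if not reg_grid or not width_grid:
        raise ValueError("tuning grids must be non-empty")
    best = None
    for rg in sorted(reg_grid):
        for wd in sorted(width_grid):
            rmsecv = float(
                np.sqrt((lssvm_loocv_residuals(X, y, rg, wd) ** 2).mean())
            )
            if best is None or rmsecv < best[0]:
                best = (rmsecv, {"reg_gamma": rg, "kernel_width": wd})
    hp = best[1]
    return hp, evaluate_method(X, y, "lssvm", hp, seed=seed)


def results_table(results) -> pd.DataFrame:
    """Flatten BenchmarkResults into the comparison table layout."""
    rows = []
    for r in results:
        rows.append(
            {
                "method": r.method,
                "variant": r.dataset_variant,
                "hyperparams": ";".join(
                    f"{k}={v:.6g}" if isinstance(v, float) else f"{k}={v}"
                    for k, v in sorted(r.hyperparams.items())
                ),
                "r2_cv": r.r2_cv,
                "rmsecv": r.rmsecv,
            }
        )
    return pd.DataFrame(rows)
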