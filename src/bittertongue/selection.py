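"""Latent-variable selection: LOOCV, robust RMSE(CV), and the RCS statistic.

The number of PLS latent variables k is chosen with the robust component
selection statistic

    RCS_k = sqrt( gamma * R-RMSECV_k^2 + (1 - gamma) * R-RMSE_k^2 )

which blends the quality of leave-one-out predictions (R-RMSECV) with the
goodness of fit (R-RMSE); both robust variants exclude the samples a
preliminary robust fit downweights.  gamma = 1 keeps only the
cross-validated term, gamma = 0 only the fit term, gamma = 0.5 weights
them equally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .robust import rsimpls_fit


def weighted_rmse(y, yhat, case_weights=None) -> float:
    """Root mean squared error over the weight-1 samples.

    All-ones weights give the plain RMSE / RMSECV; zeroing a sample's
    weight excludes it, giving the robust (R-) variants.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError("y and yhat have different lengths")
    if case_weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(case_weights, dtype=float).ravel()
        if w.shape != y.shape:
            raise ValueError("case_weights length mismatch")
    total = w.sum()
    if total <= 0:
        raise ValueError("all case weights are zero")
    return float(np.sqrt((w * (y - yhat) ** 2).sum() / total))


def rcs_statistic(gamma: float, r_rmsecv: float, r_rmse: float) -> float:
    """Robust component selection statistic blending CV and fit error."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    if r_rmsecv < 0 or r_rmse < 0:
        raise ValueError("error terms must be non-negative")
    return float(np.sqrt(gamma * r_rmsecv**2 + (1.0 - gamma) * r_rmse**2))


def loocv_predictions(X, y, fitter, *, seed: int = 0, **fit_kwargs) -> np.ndarray:
    """Leave-one-out cross-validated predictions.

    ``fitter(X, y, seed=..., **fit_kwargs)`` must return an object with a
    ``predict`` method.  Fold i is fit on all samples but i with seed
    ``seed + i`` so stochastic fitters are reproducible per fold.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    preds = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            model = fitter(X[mask], y[mask], seed=seed + i, **fit_kwargs)
        except Exception as err:  # noqa: BLE001 - annotate the failing fold
            raise RuntimeError(f"LOOCV fold {i} (sample index {i}) failed: {err}") from err
        preds[i] = float(np.asarray(model.predict(X[i : i + 1])).ravel()[0])
        mask[i] = True
    return preds


def _rsimpls_fitter(X, y, *, seed=0, k=1, alpha=0.75, **kw):
    return rsimpls_fit(X, y, k, alpha=alpha, seed=seed, **kw)


@dataclass
class SelectionCurve:
    """Per-k robust fit/CV errors and the RCS curves for several gammas."""

    gammas: tuple
    table: pd.DataFrame  # columns: gamma, k, r_rmse, r_rmsecv, rcs
    chosen_k: int  # smallest k at the RCS plateau (gamma = 0.5)
    argmin_k: int  # k minimizing RCS at gamma = 0.5
    plateau_tol: float

    def curve(self, gamma: float) -> pd.DataFrame:
        return self.table[np.isclose(self.table["gamma"], gamma)].reset_index(
            drop=True
        )

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def select_num_components(
    X,
    y,
    k_max: int,
    *,
    gammas=(0.0, 0.5, 1.0),
    plateau_tol: float = 0.05,
    alpha: float = 0.75,
    seed: int = 0,
    fit_kwargs: dict | None = None,
) -> SelectionCurve:
    """Scan k = 1..k_max and pick the plateau of the RCS curve.

    For each k a robust fit on the full data supplies case weights; R-RMSE
    is the weighted in-sample error of that fit and R-RMSECV the weighted
    error of the LOOCV predictions at the same k.  ``chosen_k`` is the
    smallest k whose relative RCS improvement to k+1 (at gamma = 0.5)
    falls below ``plateau_tol``; the argmin-RCS k is reported alongside.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if k_max > min(n - 1, p):
        raise ValueError(f"k_max={k_max} exceeds min(n-1, p)={min(n - 1, p)}")
    fit_kwargs = dict(fit_kwargs or {})
    gammas = tuple(gammas)

    rows = []
    rcs_half = []
    for k in range(1, k_max + 1):
        full = rsimpls_fit(X, y, k, alpha=alpha, seed=seed, **fit_kwargs)
        w = full.case_weights
        r_rmse = weighted_rmse(y, full.predict(X), w)
        preds_cv = loocv_predictions(
            X, y, _rsimpls_fitter, seed=seed, k=k, alpha=alpha, **fit_kwargs
        )
        r_rmsecv = weighted_rmse(y, preds_cv, w)
        rcs_half.append(rcs_statistic(0.5, r_rmsecv, r_rmse))
        for g in gammas:
            rows.append(
                {
                    "gamma": g,
                    "k": k,
                    "r_rmse": r_rmse,
                    "r_rmsecv": r_rmsecv,
                    "rcs": rcs_statistic(g, r_rmsecv, r_rmse),
                }
            )

    rcs_half = np.asarray(rcs_half)
    chosen_k = k_max
    for k in range(1, k_max):
        cur, nxt = rcs_half[k - 1], rcs_half[k]
        rel_improvement = (cur - nxt) / cur if cur > 0 else 0.0
        if rel_improvement < plateau_tol:
            chosen_k = k
            break
    argmin_k = int(np.argmin(rcs_half)) + 1

    return SelectionCurve(
        gammas=gammas,
        table=pd.DataFrame(rows),
        chosen_k=chosen_k,
        argmin_k=argmin_k,
        plateau_tol=plateau_tol,
    )
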