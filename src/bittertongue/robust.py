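"""Robust location/scatter, robust PCA and the robust PLS calibration fit.

The calibration model at the package's core is a robust SIMPLS-type partial
least squares regression: instead of the classical mean and covariance of
the joined (sensors, response) block, it plugs high-breakdown estimates
into the SIMPLS weight extraction, so that a minority of aberrant samples
(bad leverage points, vertical outliers) cannot drag the fitted bitterness
predictor.

The robust moments come from a projection-pursuit robust PCA: sample
outlyingness is measured along many random directions through point pairs
(Stahel-Donoho style), the least outlying half-set picks a subspace, and a
minimum covariance determinant (MCD) estimate is computed inside it.  The
MCD itself is the batched C-step algorithm with random restarts
(FAST-MCD); a brute-force enumerated MCD is provided as a small-n oracle.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

_EIG_TOL = 1e-10


class ExactFitError(RuntimeError):
    """At least h observations lie on a lower-dimensional affine subspace.

    The MCD scatter is singular; ``direction`` is a unit vector orthogonal
    to the degenerate subspace.
    """

    def __init__(self, direction):
        super().__init__(
            "exact fit: an h-subset has singular covariance; "
            "reduce the dimension or inspect the degenerate direction"
        )
        self.direction = np.asarray(direction)


@dataclass
class RobustLocationScatter:
    """Robust center and scatter with the covered h-subset."""

    center: np.ndarray
    scatter: np.ndarray
    support: np.ndarray  # sorted indices of the raw h-subset
    h: int
    consistency_applied: bool
    raw_center: np.ndarray = None
    raw_scatter: np.ndarray = None
    weights: np.ndarray = None  # reweighting 0/1 weights (fast_mcd only)
    det_trace: list = field(default_factory=list)


def _h_default(n: int, d: int, alpha: float) -> int:
    hmin = math.ceil((n + d + 1) / 2)
    return max(int(math.floor(alpha * n)), hmin)


def _validate_h(n: int, d: int, h: int) -> None:
    hmin = math.ceil((n + d + 1) / 2)
    if not hmin <= h <= n:
        raise ValueError(f"h={h} outside valid range [{hmin}, {n}] for n={n}, d={d}")


def mcd_consistency_factor(fraction: float, d: int) -> float:
    """Asymptotic factor making an ellipsoidally truncated scatter unbiased.

    For a Gaussian sample truncated to its central ``fraction`` mass the
    scatter shrinks by chi2_cdf(q, d+2)/fraction with q the chi2_d quantile
    at ``fraction``; the scatter is multiplied by the reciprocal.
    """
    if fraction >= 1.0:
        return 1.0
    q = stats.chi2.ppf(fraction, d)
    return fraction / stats.chi2.cdf(q, d + 2)


def residual_trim_consistency(cutoff: float) -> float:
    """Scale factor undoing the bias of a +/- cutoff*sigma residual trim."""
    a = 2.0 * stats.norm.cdf(cutoff) - 1.0
    kept_var = (a - 2.0 * cutoff * stats.norm.pdf(cutoff)) / a
    return 1.0 / math.sqrt(kept_var)


def _subset_mean_cov(X: np.ndarray, idx) -> tuple[np.ndarray, np.ndarray]:
    sub = X[np.asarray(idx)]
    mean = sub.mean(axis=0)
    dev = sub - mean
    cov = dev.T @ dev / (len(sub) - 1)
    return mean, np.atleast_2d(cov)


def exact_mcd(data, h: int) -> RobustLocationScatter:
    """Enumerated MCD for tiny n: scan all C(n, h) subsets.

    Ties in the determinant are broken toward the lexicographically
    smallest index set (enumeration order).  Combinatorial oracle only;
    refuses n > 15.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, d = X.shape
    if n > 15:
        raise ValueError("exact_mcd is an enumeration oracle; n must be <= 15")
    _validate_h(n, d, h)
    best_det = np.inf
    best = None
    for comb in itertools.combinations(range(n), h):
        mean, cov = _subset_mean_cov(X, comb)
        sign, logdet = np.linalg.slogdet(cov)
        det = sign * math.exp(logdet) if np.isfinite(logdet) else 0.0
        if det < best_det:
            best_det = det
            best = (comb, mean, cov)
    comb, mean, cov = best
    return RobustLocationScatter(
        center=mean,
        scatter=cov,
        support=np.asarray(comb),
        h=h,
        consistency_applied=False,
        raw_center=mean,
        raw_scatter=cov,
    )


def _batch_mean_cov(X: np.ndarray, subsets: np.ndarray):
    """Means and covariances for m equal-size index subsets (m, size)."""
    sub = X[subsets]  # m x size x d
    means = sub.mean(axis=1)
    dev = sub - means[:, None, :]
    covs = dev.transpose(0, 2, 1) @ dev / (subsets.shape[1] - 1)
    return means, covs


def _batch_distances(X: np.ndarray, means: np.ndarray, covs: np.ndarray):
    """Squared Mahalanobis distances of all points to each (mean, cov)."""
    inv = np.linalg.inv(covs)
    diff = X[None, :, :] - means[:, None, :]
    return ((diff @ inv) * diff).sum(axis=2)


def _check_exact_fit(cov: np.ndarray):
    vals, vecs = np.linalg.eigh(cov)
    if vals[-1] <= 0 or vals[0] <= _EIG_TOL * max(vals[-1], 1.0):
        raise ExactFitError(vecs[:, 0])


def fast_mcd(
    data,
    h: int | None = None,
    *,
    alpha: float = 0.75,
    seed: int = 0,
    n_subsets: int = 500,
    n_keep: int = 10,
    n_initial_csteps: int = 2,
    max_csteps: int = 100,
    det_tol: float = 1e-12,
) -> RobustLocationScatter:
    """FAST-MCD: concentration steps from many random elemental subsets.

    ``n_subsets`` random (d+1)-point subsets are each concentrated with
    ``n_initial_csteps`` C-steps; the ``n_keep`` candidates of smallest
    covariance determinant are iterated to convergence.  The winning raw
    h-subset estimate is consistency-corrected and reweighted at the 0.975
    chi-square cutoff.  Deterministic for a given ``seed``.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, d = X.shape
    if n <= d:
        raise ValueError("need n > d observations")
    if h is None:
        h = _h_default(n, d, alpha)
    _validate_h(n, d, h)

    if h == n:
        mean = X.mean(axis=0)
        cov = np.atleast_2d(np.cov(X.T, ddof=1))
        return RobustLocationScatter(
            center=mean,
            scatter=cov,
            support=np.arange(n),
            h=n,
            consistency_applied=False,
            raw_center=mean,
            raw_scatter=cov,
            weights=np.ones(n),
        )

    rng = np.random.default_rng(seed)

    # -- elemental starts: (d+1)-subsets, grown if their covariance is flat
    m = n_subsets
    starts = np.argsort(rng.random((m, n)), axis=1)[:, : d + 1]
    means, covs = _batch_mean_cov(X, starts)
    dets = np.linalg.slogdet(covs)
    singular = ~((dets[0] > 0) & np.isfinite(dets[1]))
    for i in np.nonzero(singular)[0]:
        idx = list(starts[i])
        pool = [j for j in range(n) if j not in set(idx)]
        rng_i = np.random.default_rng(seed + 104729 + i)
        order = rng_i.permutation(pool)
        ptr = 0
        mean_i, cov_i = _subset_mean_cov(X, idx)
        while len(idx) < h:
            sign, logdet = np.linalg.slogdet(cov_i)
            if sign > 0 and np.isfinite(logdet):
                break
            idx.append(int(order[ptr]))
            ptr += 1
            mean_i, cov_i = _subset_mean_cov(X, idx)
        else:
            _check_exact_fit(cov_i)
        means[i], covs[i] = mean_i, cov_i

    md2 = _batch_distances(X, means, covs)
    hsubs = np.argpartition(md2, h - 1, axis=1)[:, :h]

    def cstep(hs):
        mns, cvs = _batch_mean_cov(X, hs)
        sign, logdet = np.linalg.slogdet(cvs)
        bad = ~((sign > 0) & np.isfinite(logdet))
        if bad.any():
            _check_exact_fit(cvs[np.nonzero(bad)[0][0]])
        d2 = _batch_distances(X, mns, cvs)
        new = np.argpartition(d2, h - 1, axis=1)[:, :h]
        return new, logdet

    logdets = None
    for _ in range(n_initial_csteps):
        hsubs, logdets = cstep(hsubs)

    # keep the most promising candidates, iterate each to a fixed point
    _, final_logdets = cstep(hsubs)  # determinant after the last step
    order = np.argsort(final_logdets, kind="stable")[:n_keep]
    cands = np.sort(hsubs[order], axis=1)
    cands = np.unique(cands, axis=0)

    best_logdet = np.inf
    best_sub = None
    det_trace: list = []
    for sub in cands:
        cur = sub
        trace = []
        prev_logdet = np.inf
        for _ in range(max_csteps):
            new, logdet = cstep(cur[None, :])
            logdet = float(logdet[0])
            assert logdet <= prev_logdet + 1e-9, "C-step determinant increased"
            trace.append(logdet)
            new = np.sort(new[0])
            if np.array_equal(new, np.sort(cur)) or prev_logdet - logdet < det_tol:
                cur = new
                break
            prev_logdet = logdet
            cur = new
        if trace[-1] < best_logdet - 1e-15 or (
            best_sub is None
        ) or (
            abs(trace[-1] - best_logdet) <= 1e-15
            and tuple(cur) < tuple(best_sub)
        ):
            best_logdet = trace[-1]
            best_sub = np.sort(cur)
            det_trace = trace

    raw_center, raw_scatter = _subset_mean_cov(X, best_sub)
    _check_exact_fit(raw_scatter)
    raw_scatter = raw_scatter * mcd_consistency_factor(h / n, d)

    # reweighting at the 0.975 chi-square cutoff
    inv = np.linalg.inv(raw_scatter)
    diff = X - raw_center
    d2 = np.einsum("nd,de,ne->n", diff, inv, diff)
    w = d2 <= stats.chi2.ppf(0.975, d)
    if w.sum() <= d:
        w = np.zeros(n, bool)
        w[best_sub] = True
    center, scatter = _subset_mean_cov(X, np.nonzero(w)[0])
    scatter = scatter * mcd_consistency_factor(0.975, d)

    return RobustLocationScatter(
        center=center,
        scatter=scatter,
        support=np.asarray(best_sub),
        h=h,
        consistency_applied=True,
        raw_center=raw_center,
        raw_scatter=raw_scatter,
        weights=w.astype(float),
        det_trace=det_trace,
    )


def _affine_span(X: np.ndarray):
    """Orthonormal basis of the affine span of the rows and coordinates."""
    mu = X.mean(axis=0)
    centered = X - mu
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    tol = s.max(initial=0.0) * max(X.shape) * np.finfo(float).eps
    r = int((s > tol).sum())
    basis = vt[:r].T  # d x r
    coords = centered @ basis
    return mu, basis, coords, r


_MAD_NORMAL = 1.482602218505602  # 1 / norm.ppf(0.75)


def _outlyingness(U: np.ndarray, n_directions: int, rng) -> np.ndarray:
    """Stahel-Donoho outlyingness over random point-pair directions.

    Directions with zero spread (median absolute deviation ~ 0) carry no
    information and are dropped.
    """
    n = U.shape[0]
    i = rng.integers(0, n, size=n_directions)
    j = (i + 1 + rng.integers(0, n - 1, size=n_directions)) % n  # j != i
    V = U[i] - U[j]  # m x r
    norms = np.linalg.norm(V, axis=1)
    keep = norms > 1e-12
    V = V[keep] / norms[keep, None]
    proj = U @ V.T  # n x m
    med = np.median(proj, axis=0)
    mad = _MAD_NORMAL * np.median(np.abs(proj - med), axis=0)
    ok = mad > 1e-12
    if not ok.any():
        return np.zeros(n)
    score = np.abs(proj[:, ok] - med[ok]) / mad[ok]
    return score.max(axis=1)


@dataclass
class ROBPCAResult:
    """Robust PCA output.

    ``location_scatter`` holds the robust center (length d) and the rank-k
    scatter (d x d) in the original coordinates; ``loadings`` the
    orthonormal d x k subspace basis; ``outlyingness`` the per-sample
    projection-pursuit outlyingness and ``h_subset`` the indices of the h
    least-outlying samples (the set orthogonal outliers fall outside of).
    """

    location_scatter: RobustLocationScatter
    loadings: np.ndarray
    outlyingness: np.ndarray
    h_subset: np.ndarray


def robpca(
    data,
    k: int,
    *,
    alpha: float = 0.75,
    seed: int = 0,
    n_directions: int = 250,
    n_subsets: int = 500,
) -> "ROBPCAResult":
    """Projection-pursuit robust PCA.

    Projects to the affine span, ranks samples by outlyingness along random
    point-pair directions, picks the k-dimensional subspace spanned by the
    leading eigenvectors of the least-outlying half-set, and runs FAST-MCD
    inside that subspace.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    n, d = X.shape
    if not 1 <= k <= min(n - 1, d):
        raise ValueError(f"k={k} outside [1, min(n-1, d)={min(n - 1, d)}]")
    mu0, basis, U, r = _affine_span(X)
    if k > r:
        raise ValueError(
            f"k={k} exceeds the rank {r} of the data (exact fit in {r} dims)"
        )

    if alpha >= 1.0:  # classical PCA path
        S = np.atleast_2d(np.cov(U.T, ddof=1))
        vals, vecs = np.linalg.eigh(S)
        E = vecs[:, ::-1][:, :k]
        T = (U - U.mean(axis=0)) @ E
        mu_t = T.mean(axis=0)
        S_t = np.atleast_2d(np.cov(T.T, ddof=1))
        loadings = basis @ E
        center = mu0 + basis @ (U.mean(axis=0) + E @ mu_t)
        scatter = loadings @ S_t @ loadings.T
        return ROBPCAResult(
            location_scatter=RobustLocationScatter(
                center=center,
                scatter=scatter,
                support=np.arange(n),
                h=n,
                consistency_applied=False,
            ),
            loadings=loadings,
            outlyingness=np.zeros(n),
            h_subset=np.arange(n),
        )

    rng = np.random.default_rng(seed)
    outl = _outlyingness(U, n_directions, rng)
    h = _h_default(n, k, alpha)
    idx_h = np.argsort(outl, kind="stable")[:h]
    mean_h, cov_h = _subset_mean_cov(U, idx_h)
    vals, vecs = np.linalg.eigh(cov_h)
    E = vecs[:, ::-1][:, :k]  # r x k
    T = (U - mean_h) @ E

    mcd = fast_mcd(T, alpha=alpha, seed=seed + 1, n_subsets=n_subsets)
    loadings = basis @ E  # d x k
    center = mu0 + basis @ (mean_h + E @ mcd.center)
    scatter = loadings @ mcd.scatter @ loadings.T
    return ROBPCAResult(
        location_scatter=RobustLocationScatter(
            center=center,
            scatter=scatter,
            support=mcd.support,
            h=mcd.h,
            consistency_applied=True,
            weights=mcd.weights,
        ),
        loadings=loadings,
        outlyingness=outl,
        h_subset=np.sort(idx_h),
    )


# ---------------------------------------------------------------------------
# SIMPLS weight extraction from (possibly robust) second moments
# ---------------------------------------------------------------------------


def simpls_weights(Sxx: np.ndarray, sxy: np.ndarray, k: int) -> np.ndarray:
    """SIMPLS weight vectors from a cross-covariance with loading deflation.

    For a univariate response the a-th weight is the current deflated
    cross-covariance; after each extraction the covariance is deflated by
    the orthonormalized x-loading so later weights explore new directions.
    """
    p = Sxx.shape[0]
    if not 1 <= k <= p:
        raise ValueError(f"k={k} outside [1, p={p}]")
    s = np.asarray(sxy, dtype=float).copy()
    R = np.zeros((p, k))
    V = np.zeros((p, k))
    for a in range(k):
        norm = np.linalg.norm(s)
        if norm < 1e-14:
            raise ValueError(
                f"cross-covariance fully deflated after {a} components; "
                "reduce k"
            )
        r = s / norm
        t_var = float(r @ Sxx @ r)
        if t_var <= 0:
            raise ValueError("non-positive score variance; scatter not PD")
        p_a = Sxx @ r / t_var
        v = p_a - V[:, :a] @ (V[:, :a].T @ p_a)
        v_norm = np.linalg.norm(v)
        if v_norm < 1e-14:
            raise ValueError("loading deflation collapsed; reduce k")
        v /= v_norm
        s = s - v * float(v @ s)
        R[:, a] = r
        V[:, a] = v
    return R


@dataclass
class ModelEquation:
    """The fitted calibration in original sensor units: I = sum c_j * sensor_j + intercept."""

    sensor_names: tuple
    coefficients: np.ndarray
    intercept: float

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        return self.intercept + X_new @ self.coefficients

    def format(self) -> str:
        terms = []
        for c, name in zip(self.coefficients, self.sensor_names):
            sign = "-" if c < 0 else "+"
            terms.append(f"{sign} {abs(c):.6g} x {name}")
        body = " ".join(terms).lstrip("+ ")
        isign = "-" if self.intercept < 0 else "+"
        return f"I = {body} {isign} {abs(self.intercept):.6g}"


@dataclass
class RPLSModel:
    """A fitted (robust) SIMPLS calibration with its diagnostics parameters."""

    k: int
    weights: np.ndarray  # p x k SIMPLS weight vectors
    x_center: np.ndarray  # robust predictor center (length p)
    scores: np.ndarray  # n x k training scores (X - x_center) @ weights
    score_center: np.ndarray  # robust score center mu_t
    score_scatter: np.ndarray  # robust score scatter Sigma_t (k x k)
    coefficients: np.ndarray  # length p, original sensor units
    intercept: float
    residual_scale: float  # robust residual scale s
    case_weights: np.ndarray  # 0/1, outliers downweighted to 0
    alpha: float
    seed: int
    sensor_names: tuple = None

    @property
    def p(self) -> int:
        return self.coefficients.shape[0]

    def predict(self, X_new) -> np.ndarray:
        X_new = np.asarray(X_new, dtype=float)
        if X_new.ndim == 1:
            X_new = X_new.reshape(1, -1)
        if X_new.shape[1] != self.p:
            raise ValueError(
                f"X_new has {X_new.shape[1]} columns, model expects {self.p}"
            )
        return self.intercept + X_new @ self.coefficients

    def transform(self, X_new) -> np.ndarray:
        """Latent scores of new samples."""
        X_new = np.asarray(X_new, dtype=float)
        return (X_new - self.x_center) @ self.weights

    def to_dict(self) -> dict:
        return {
            "k": int(self.k),
            "weights": self.weights.tolist(),
            "x_center": self.x_center.tolist(),
            "score_center": self.score_center.tolist(),
            "score_scatter": self.score_scatter.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercept": float(self.intercept),
            "residual_scale": float(self.residual_scale),
            "case_weights": self.case_weights.tolist(),
            "alpha": float(self.alpha),
            "seed": int(self.seed),
            "sensor_names": list(self.sensor_names) if self.sensor_names else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_dict(cls, doc: dict) -> "RPLSModel":
        return cls(
            k=doc["k"],
            weights=np.asarray(doc["weights"]),
            x_center=np.asarray(doc["x_center"]),
            scores=None,
            score_center=np.asarray(doc["score_center"]),
            score_scatter=np.asarray(doc["score_scatter"]),
            coefficients=np.asarray(doc["coefficients"]),
            intercept=doc["intercept"],
            residual_scale=doc["residual_scale"],
            case_weights=np.asarray(doc["case_weights"]),
            alpha=doc["alpha"],
            seed=doc["seed"],
            sensor_names=tuple(doc["sensor_names"]) if doc["sensor_names"] else None,
        )

    @classmethod
    def load(cls, path) -> "RPLSModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _trimmed_residual_scale(resid: np.ndarray, h: int) -> float:
    """Consistent scale from the h smallest squared residuals (LTS-style)."""
    n = resid.size
    r2 = np.sort(resid**2)[:h]
    a = h / n
    if a >= 1.0:
        return float(np.sqrt(r2.mean()))
    q = stats.norm.ppf((1.0 + a) / 2.0)
    consistency = (a - 2.0 * q * stats.norm.pdf(q)) / a
    return float(np.sqrt(r2.mean() / consistency))


def rsimpls_fit(
    X,
    y,
    k: int,
    *,
    alpha: float = 0.75,
    seed: int = 0,
    sr_threshold: float = 2.5,
    sd_quantile: float = 0.975,
    n_directions: int = 250,
    n_subsets: int = 500,
    sensor_names=None,
) -> RPLSModel:
    """Fit the robust SIMPLS calibration with k latent variables.

    The joined (X, y) block is summarized by a robust center and scatter
    (projection-pursuit robust PCA at coverage ``alpha``); SIMPLS weights
    are extracted from the robust cross-covariance; the score regression is
    then refit once with case weights that zero out samples whose absolute
    residual exceeds ``sr_threshold`` robust scales or whose score distance
    exceeds the ``sd_quantile`` chi-square cutoff.

    ``alpha=1`` forces the classical path (all case weights 1, classical
    moments): the "fraction of outliers set to zero" retrain mode used
    after the flagged samples have been removed from the training set.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("X and y have different lengths")
    if not 1 <= k <= min(n - 1, p):
        raise ValueError(f"k={k} outside [1, min(n-1, p)={min(n - 1, p)}]")
    if not 0.5 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0.5, 1]")
    if y.std() == 0:
        raise ValueError("response has zero variance")

    Z = np.column_stack([X, y])
    if alpha >= 1.0:
        mu = Z.mean(axis=0)
        S = np.atleast_2d(np.cov(Z.T, ddof=1))
    else:
        k0 = min(n - 1, p + 1)
        res = robpca(
            Z,
            k=k0,
            alpha=alpha,
            seed=seed,
            n_directions=n_directions,
            n_subsets=n_subsets,
        )
        mu, S = res.location_scatter.center, res.location_scatter.scatter

    mux, muy = mu[:p], mu[p]
    Sxx, sxy = S[:p, :p], S[:p, p]

    R = simpls_weights(Sxx, sxy, k)
    T = (X - mux) @ R  # scores, centered at the robust x-center
    St0 = R.T @ Sxx @ R  # robust score scatter of the initial fit

    q0 = np.linalg.solve(St0, R.T @ sxy)
    b0 = R @ q0
    resid0 = y - (muy - mux @ b0) - X @ b0

    if alpha >= 1.0:
        w = np.ones(n, dtype=bool)
    else:
        h = _h_default(n, 1, alpha)
        sigma0 = _trimmed_residual_scale(resid0, h)
        sd0 = np.sqrt(
            np.einsum("nk,kl,nl->n", T, np.linalg.inv(St0), T)
        )
        sd_cut = math.sqrt(stats.chi2.ppf(sd_quantile, k))
        w = (np.abs(resid0) <= sr_threshold * max(sigma0, 1e-300)) & (sd0 <= sd_cut)
        if w.sum() < k + 2:  # pathological trim: keep the h best residuals
            w = np.zeros(n, dtype=bool)
            w[np.argsort(np.abs(resid0), kind="stable")[:h]] = True

    # weighted least squares refit of y on the scores
    A = np.column_stack([np.ones(w.sum()), T[w]])
    sol, *_ = np.linalg.lstsq(A, y[w], rcond=None)
    c_t, q1 = sol[0], sol[1:]
    b = R @ q1
    intercept = float(c_t - mux @ b)

    resid = y - (intercept + X @ b)
    dof = max(int(w.sum()) - k - 1, 1)
    s = math.sqrt(float((resid[w] ** 2).sum()) / dof)
    if alpha < 1.0:
        s *= residual_trim_consistency(sr_threshold)

    mu_t = T[w].mean(axis=0)
    Sigma_t = np.atleast_2d(np.cov(T[w].T, ddof=1))
    if alpha < 1.0:
        Sigma_t = Sigma_t * mcd_consistency_factor(sd_quantile, k)

    return RPLSModel(
        k=k,
        weights=R,
        x_center=mux,
        scores=T,
        score_center=mu_t,
        score_scatter=Sigma_t,
        coefficients=b,
        intercept=intercept,
        residual_scale=s,
        case_weights=w.astype(float),
        alpha=alpha,
        seed=seed,
        sensor_names=tuple(sensor_names) if sensor_names is not None else None,
    )


def rpls_predict(model: RPLSModel, X_new) -> np.ndarray:
    """Predict bitterness intensities for new sensor rows."""
    return model.predict(X_new)


def equation_original_form(model: RPLSModel, sensor_names=None) -> ModelEquation:
    """Express the fitted calibration on raw sensor units.

    All centering is absorbed into the intercept, so the equation evaluates
    identically to :func:`rpls_predict`.
    """
    names = sensor_names or model.sensor_names
    if names is None:
        names = tuple(f"x{j + 1}" for j in range(model.p))
    if len(names) != model.p:
        raise ValueError("sensor name count does not match coefficient count")
    return ModelEquation(tuple(names), model.coefficients.copy(), float(model.intercept))
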