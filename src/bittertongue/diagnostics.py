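"""Outlier-map diagnostics: standardized residuals, score distances, labels.

Every calibration sample is placed on an outlier map with two coordinates:

* Sr, the standardized residual r_i / s, and
* SD, the (rooted) Mahalanobis distance of the sample's latent scores from
  the robust score center.

Crossing the Sr cutoff (default 2.5, two-sided) marks a response outlier,
crossing the SD cutoff (the rooted 0.975 chi-square quantile with k
degrees of freedom) marks a leverage point, and the combination defines
the three outlier classes: good leverage (SD only — far along the model
line but consistent with it), bad leverage (both), and vertical (Sr only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

LABELS = ("regular", "good_leverage", "bad_leverage", "vertical")


@dataclass
class DiagnosticsResult:
    """Per-sample outlier-map coordinates, cutoffs and labels."""

    ids: np.ndarray
    sr: np.ndarray
    sd: np.ndarray
    sr_cutoff: float
    sd_cutoff: float
    labels: np.ndarray  # one of LABELS per sample
    exact_fit: bool = False

    def flagged_ids(self, classes=("bad_leverage", "vertical")) -> list:
        """Ids of the removal candidates (bad leverage + vertical default)."""
        mask = np.isin(self.labels, list(classes))
        return list(self.ids[mask])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": self.ids, "sr": self.sr, "sd": self.sd, "label": self.labels}
        )

    def to_csv(self, path) -> None:
        frame = self.to_frame()
        frame["sr_cutoff"] = self.sr_cutoff
        frame["sd_cutoff"] = self.sd_cutoff
        frame.to_csv(path, index=False, float_format="%.10g")

    def plot(self, path=None, ax=None):
        """Render the outlier map (Sr vs SD) with cutoff lines."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        for label, marker in zip(LABELS, ("o", "^", "s", "v")):
            m = self.labels == label
            ax.scatter(self.sd[m], self.sr[m], marker=marker, label=label)
        ax.axhline(self.sr_cutoff, ls="--", c="gray")
        ax.axhline(-self.sr_cutoff, ls="--", c="gray")
        ax.axvline(self.sd_cutoff, ls="--", c="gray")
        for i, sid in enumerate(self.ids):
            if self.labels[i] != "regular":
                ax.annotate(str(sid), (self.sd[i], self.sr[i]), fontsize=8)
        ax.set_xlabel("score distance (SD)")
        ax.set_ylabel("standardized residual (Sr)")
        ax.legend(fontsize=8)
        if path is not None:
            ax.figure.savefig(path, dpi=150, bbox_inches="tight")
            plt.close(ax.figure)
        return ax


def standardized_residuals(y, yhat, p: int):
    """Classical standardized residuals: Sr_i = r_i / s.

    The residual scale uses the regression degrees of freedom,
    s = sqrt(sum r_i^2 / (n - p - 1)) with p the number of predictors.
    A perfect fit (s = 0) returns all-zero Sr with an exact-fit flag.
    """
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    n = y.shape[0]
    if yhat.shape[0] != n:
        raise ValueError("y and yhat have different lengths")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (n={n}, p={p})")
    r = y - yhat
    s = math.sqrt(float((r**2).sum()) / (n - p - 1))
    if s == 0.0:
        return np.zeros(n), 0.0
    return r / s, s


def score_distances(scores, score_center, score_scatter) -> np.ndarray:
    """Rooted Mahalanobis distance of each score row from the robust center."""
    T = np.asarray(scores, dtype=float)
    if T.ndim == 1:
        T = T.reshape(-1, 1)
    center = np.asarray(score_center, dtype=float).ravel()
    S = np.atleast_2d(np.asarray(score_scatter, dtype=float))
    vals = np.linalg.eigvalsh(S)
    if vals[0] <= 1e-12 * max(vals[-1], 1.0):
        raise ValueError(
            "score scatter is singular: reduce the number of latent variables"
        )
    diff = T - center
    d2 = np.einsum("nk,kl,nl->n", diff, np.linalg.inv(S), diff)
    return np.sqrt(d2)


def sd_cutoff(k: int, quantile: float = 0.975) -> float:
    """Rooted chi-square cutoff for the score distance with k latent variables."""
    if k < 1:
        raise ValueError("k must be at least 1")
    return math.sqrt(stats.chi2.ppf(quantile, k))


def classify_samples(
    sr, sd, sr_cutoff: float = 2.5, sd_cutoff: float = None, *, k: int = None, ids=None
) -> DiagnosticsResult:
    """Label each sample by which cutoffs it exceeds.

    good_leverage: SD only; bad_leverage: both; vertical: |Sr| only;
    regular otherwise.  ``sd_cutoff`` may be given directly or derived
    from ``k``.
    """
    sr = np.asarray(sr, dtype=float).ravel()
    sd = np.asarray(sd, dtype=float).ravel()
    if sr.shape != sd.shape:
        raise ValueError("Sr and SD have different lengths")
    if sd_cutoff is None:
        if k is None:
            raise ValueError("provide sd_cutoff or k")
        sd_cutoff = globals()["sd_cutoff"](k)
    res_out = np.abs(sr) > sr_cutoff
    lev_out = sd > sd_cutoff
    labels = np.where(
        res_out & lev_out,
        "bad_leverage",
        np.where(res_out, "vertical", np.where(lev_out, "good_leverage", "regular")),
    )
    if ids is None:
        ids = np.arange(1, sr.size + 1)
    return DiagnosticsResult(
        ids=np.asarray(ids),
        sr=sr,
        sd=sd,
        sr_cutoff=float(sr_cutoff),
        sd_cutoff=float(sd_cutoff),
        labels=labels,
    )


def diagnose_model(
    model, X, y, *, ids=None, sr_cutoff: float = 2.5, sd_quantile: float = 0.975
) -> DiagnosticsResult:
    """Outlier map of a fitted robust calibration.

    Residuals are standardized by the model's robust residual scale (the
    trimmed, consistency-corrected s of the reweighted fit) so that gross
    outliers cannot mask themselves by inflating the scale; score
    distances use the model's robust score center and scatter.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    resid = y - model.predict(X)
    s = model.residual_scale
    exact = s <= 0
    sr = np.zeros_like(resid) if exact else resid / s
    sd = score_distances(model.transform(X), model.score_center, model.score_scatter)
    result = classify_samples(
        sr, sd, sr_cutoff=sr_cutoff, sd_cutoff=sd_cutoff(model.k, sd_quantile), ids=ids
    )
    result.exact_fit = bool(exact)
    return result
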