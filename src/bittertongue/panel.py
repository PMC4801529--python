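"""Human taste-panel score processing.

Trained assessors rate the bitterness of each decoction on a continuous
0.5-5.5 scale anchored by berberine reference solutions.  Individual
assessor scores are screened for gross errors with an iterative two-sided
Grubbs test, reduced to per-sample mean +/- sd records, and mapped onto the
five-rank bitterness scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reference import RANK_SCALE

SCALE_MIN = 0.5
SCALE_MAX = 5.5


class InsufficientReplicationError(ValueError):
    """Raised when fewer than three scores are available for screening."""


@dataclass
class PanelRecord:
    """Per-sample summary of assessor bitterness scores (mean +/- sd form)."""

    sample_id: object
    mean_intensity: float
    sd_intensity: float
    n_assessors: int
    degenerate: bool = False  # single assessor: sd is not estimable


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value from the Student-t quantile.

    G_crit = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2)) with
    t = t_{1-alpha/(2n), n-2}.
    """
    if n < 3:
        raise InsufficientReplicationError("Grubbs test needs at least 3 values")
    t = stats.t.ppf(1.0 - alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def grubbs_screen(scores, alpha: float = 0.05):
    """Iteratively remove single gross outliers from assessor scores.

    At each pass the most extreme value is tested with the two-sided Grubbs
    statistic G = max|x_i - xbar| / s; it is removed if G exceeds the
    critical value, and the test repeats on the remainder.  Screening stops
    when G no longer exceeds the critical value, when the scores have zero
    variance (G undefined), or when only 3 values remain.

    Parameters
    ----------
    scores : array-like
        Assessor bitterness intensities, length >= 3.
    alpha : float
        Two-sided significance level, in (0, 0.5).

    Returns
    -------
    cleaned : ndarray
        Retained scores, original order preserved.
    removed : list of (original index, G statistic)
        Removals in the order they happened.
    """
    x = np.asarray(scores, dtype=float).ravel()
    if x.size < 3:
        raise InsufficientReplicationError(
            f"need at least 3 scores for Grubbs screening, got {x.size}"
        )
    if not np.isfinite(x).all():
        raise ValueError("scores must be finite")
    if not 0.0 < alpha < 0.5:
        raise ValueError("alpha must lie in (0, 0.5)")

    keep = np.arange(x.size)
    removed: list[tuple[int, float]] = []
    while keep.size > 3:
        vals = x[keep]
        s = vals.std(ddof=1)
        if s == 0.0:
            break
        dev = np.abs(vals - vals.mean())
        j = int(np.argmax(dev))  # ties: lowest index, one removal per pass
        g = dev[j] / s
        if g > grubbs_critical_value(keep.size, alpha):
            removed.append((int(keep[j]), float(g)))
            keep = np.delete(keep, j)
        else:
            break
    return x[keep], removed


def summarize_panel(scores, sample_id=None) -> PanelRecord:
    """Reduce assessor scores to a mean +/- sd record (n-1 denominator sd)."""
    x = np.asarray(scores, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot summarize an empty score set")
    degenerate = x.size == 1
    if degenerate:
        warnings.warn(
            f"sample {sample_id!r}: single assessor score, sd reported as 0",
            stacklevel=2,
        )
    sd = 0.0 if degenerate else float(x.std(ddof=1))
    return PanelRecord(sample_id, float(x.mean()), sd, int(x.size), degenerate)


def rank_from_intensity(intensity: float, scale=RANK_SCALE) -> str:
    """Map a bitterness intensity to its rank label (I-V).

    Intervals are half-open [lo, hi) except the top rank, closed at both
    ends.  An off-scale intensity raises ``ValueError``.
    """
    for label, lo, hi, hi_closed, _conc in scale:
        if lo <= intensity < hi or (hi_closed and intensity == hi):
            return label
    raise ValueError(
        f"intensity {intensity} is off the {scale[0][1]}-{scale[-1][2]} scale"
    )


def screen_panel_table(
    table: pd.DataFrame, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Screen a long-format assessor table and summarize per sample.

    ``table`` needs columns ``sample_id``, ``assessor_id``, ``score``.
    Returns the per-sample records (mean, sd, n_assessors) in first-seen
    sample order, plus a dict mapping sample_id -> list of removals.
    """
    for col in ("sample_id", "assessor_id", "score"):
        if col not in table.columns:
            raise ValueError(f"assessor table is missing column {col!r}")
    records = []
    removals: dict = {}
    for sid in table["sample_id"].drop_duplicates():
        scores = table.loc[table["sample_id"] == sid, "score"].to_numpy(float)
        cleaned, removed = grubbs_screen(scores, alpha=alpha)
        if removed:
            removals[sid] = removed
        rec = summarize_panel(cleaned, sample_id=sid)
        records.append(rec)
    out = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "mean": [r.mean_intensity for r in records],
            "sd": [r.sd_intensity for r in records],
            "n_assessors": [r.n_assessors for r in records],
        }
    )
    return out, removals


def read_assessor_scores(path) -> pd.DataFrame:
    """Read a long-format assessor score CSV (sample_id, assessor_id, score)."""
    table = pd.read_csv(path)
    for col in ("sample_id", "assessor_id", "score"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return table


def write_panel_records(records: pd.DataFrame, path, ph=None) -> None:
    """Write per-sample records as CSV; optional pH passthrough column."""
    out = records.copy()
    if ph is not None:
        out["pH"] = np.asarray(ph)
    out.to_csv(path, index=False)
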