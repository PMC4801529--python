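"""Synthetic e-tongue calibration data with known ground truth.

The published 35x7 sensor matrix was never deposited, so every stage of
the pipeline is exercised on simulated data instead.  The generator
emulates the study's structure: a latent bitterness intensity drawn from
the observed design range drives all seven sensors linearly on top of
large per-sensor baselines; the panel response is the latent intensity
plus assessor noise; replicate series show an early stabilization drift;
and outliers of the three diagnostic classes (good leverage, bad
leverage, vertical) can be planted with exact counts and recorded in a
truth record.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import Dataset
from .ingest import ReplicateSeries
from .reference import SENSOR_NAMES

OUTLIER_TYPES = ("good_leverage", "bad_leverage", "vertical")

#: Per-sensor response change per unit of bitterness intensity.  Mixed
#: signs mirror a cross-sensitive array; the implied regression
#: coefficients (~loading/||loading||^2) are of order 1e-3 against
#: baselines of order 1e3, matching the scale of a published original-form
#: calibration equation.
DEFAULT_LOADINGS = (-120.0, 180.0, 95.0, 140.0, 160.0, -110.0, 60.0)
DEFAULT_BASELINES = (1800.0, 2400.0, 1500.0, 2100.0, 1900.0, 1300.0, 2600.0)


@dataclass
class ReplicatePlan:
    """Acquisition-cycle plan: early cycles drift, later ones are stable."""

    n_cycles: int = 7
    drift_magnitude: float = 100.0
    stabilization_cycle: int = 3
    noise_sd: float = 0.0


@dataclass
class SyntheticConfig:
    """Generative settings mirroring the study conditions.

    n_samples defaults to the study's 35 decoctions; the contamination
    plan defaults to the published mix (one good leverage point retained,
    a handful of bad leverage and vertical outliers) at a gross magnitude
    of 10 clean standard deviations.
    """

    n_samples: int = 35
    sensor_names: tuple = SENSOR_NAMES
    loadings: tuple = DEFAULT_LOADINGS
    baselines: tuple = DEFAULT_BASELINES
    sensor_noise_sd: float = 20.0
    response_noise_sd: float = 0.2
    bitterness_range: tuple = (0.63, 4.78)
    contamination: tuple = (
        ("good_leverage", 1 / 35, 10.0),
        ("bad_leverage", 3 / 35, 10.0),
        ("vertical", 2 / 35, 10.0),
    )
    n_assessors: int = 10
    panel_sd_range: tuple = (0.15, 1.2)
    replicate_plan: ReplicatePlan = field(default_factory=ReplicatePlan)
    #: "uniform" draws the latent bitterness uniformly on bitterness_range
    #: (the design of a spanning calibration set); "normal" draws a
    #: Gaussian with the same mean and variance (used to check that the
    #: diagnostic flag rates sit at their Gaussian nominal levels).
    latent_distribution: str = "uniform"
    seed: int = 0

    def __post_init__(self):
        if len(self.loadings) != len(self.sensor_names) or len(
            self.baselines
        ) != len(self.sensor_names):
            raise ValueError("loadings/baselines must match sensor_names")
        lo, hi = self.bitterness_range
        if not (0.5 <= lo < hi <= 5.5):
            raise ValueError("bitterness_range must lie within [0.5, 5.5]")
        if self.sensor_noise_sd < 0 or self.response_noise_sd < 0:
            raise ValueError("noise sds must be non-negative")
        for typ, frac, mag in self.contamination:
            if typ not in OUTLIER_TYPES:
                raise ValueError(f"unknown contamination type {typ!r}")
            if not 0 <= frac < 0.5 or mag < 0:
                raise ValueError("contamination fractions in [0, 0.5), magnitude >= 0")
        if sum(frac for _, frac, _ in self.contamination) >= 0.5:
            raise ValueError("total contamination fraction must be below 0.5")
        if self.latent_distribution not in ("uniform", "normal"):
            raise ValueError("latent_distribution must be 'uniform' or 'normal'")

    def without_contamination(self) -> "SyntheticConfig":
        return replace(self, contamination=())


@dataclass
class SyntheticTruth:
    """Ground truth behind a generated dataset."""

    latent: np.ndarray  # clean latent bitterness per sample
    regression_coefficients: np.ndarray  # population coefficients of y on X
    regression_intercept: float
    outlier_ids: dict  # type -> list of 1-based sample ids
    config: SyntheticConfig

    @property
    def all_outlier_ids(self) -> list:
        return sorted(i for ids in self.outlier_ids.values() for i in ids)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for typ, ids in sorted(self.outlier_ids.items()):
            for i in ids:
                rows.append({"sample_id": i, "outlier_type": typ})
        return pd.DataFrame(rows, columns=["sample_id", "outlier_type"])


def population_coefficients(config: SyntheticConfig):
    """Closed-form best linear predictor of the response from the sensors.

    With X = baseline + loading * tau + noise and y = tau + noise_y, the
    population coefficients are beta = var(tau) * Sigma_xx^{-1} loading
    = loading * var(tau) / (sensor_noise_sd^2 + var(tau) ||loading||^2)
    (Sherman-Morrison on the rank-one signal covariance).
    """
    lo, hi = config.bitterness_range
    var_tau = (hi - lo) ** 2 / 12.0
    load = np.asarray(config.loadings, dtype=float)
    base = np.asarray(config.baselines, dtype=float)
    denom = config.sensor_noise_sd**2 + var_tau * (load @ load)
    beta = load * var_tau / denom
    mu_tau = (lo + hi) / 2.0
    intercept = mu_tau - beta @ (base + load * mu_tau)
    return beta, float(intercept)


def generate_dataset(config: SyntheticConfig) -> tuple[Dataset, SyntheticTruth]:
    """Draw a clean linear e-tongue dataset and plant the configured outliers.

    Contamination is applied last to disjoint sample sets with exact
    counts round(fraction * n):

    * vertical: the response is shifted by magnitude * response_noise_sd,
      the sensors untouched;
    * bad_leverage: the sensor vector is displaced along the latent
      direction by magnitude clean column-sds while the response keeps its
      clean value, putting the sample far off the regression plane;
    * good_leverage: the latent value is moved beyond the design range (by
      magnitude * response_noise_sd) and both sensors and response follow
      it consistently.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    p = len(config.sensor_names)
    lo, hi = config.bitterness_range
    load = np.asarray(config.loadings, dtype=float)
    base = np.asarray(config.baselines, dtype=float)

    counts = {typ: int(round(frac * n)) for typ, frac, _ in config.contamination}
    total_out = sum(counts.values())
    if total_out >= math.floor(n / 2):
        raise ValueError(
            f"{total_out} planted outliers in {n} samples would exceed the "
            "breakdown point of the robust estimator"
        )

    if config.latent_distribution == "uniform":
        tau = rng.uniform(lo, hi, size=n)
    else:
        tau = rng.normal((lo + hi) / 2.0, (hi - lo) / math.sqrt(12.0), size=n)
    X = base + np.outer(tau, load) + rng.normal(0.0, config.sensor_noise_sd, (n, p))
    y = tau + rng.normal(0.0, config.response_noise_sd, n)

    sd_tau = (hi - lo) / math.sqrt(12.0)
    chosen = rng.choice(n, size=total_out, replace=False)
    outlier_ids: dict = {}
    pos = 0
    for typ, frac, mag in config.contamination:
        idx = chosen[pos : pos + counts[typ]]
        pos += counts[typ]
        if typ == "vertical":
            y[idx] = y[idx] + mag * config.response_noise_sd
        elif typ == "bad_leverage":
            # displace along the latent direction, response left clean
            X[idx] = X[idx] + mag * sd_tau * load
        elif typ == "good_leverage":
            # on-model extension beyond the design range; the step is in
            # response units so a well-estimated slope still predicts it
            tau_out = hi + mag * config.response_noise_sd
            X[idx] = base + np.outer(
                np.full(idx.size, tau_out), load
            ) + rng.normal(0.0, config.sensor_noise_sd, (idx.size, p))
            y[idx] = tau_out + rng.normal(0.0, config.response_noise_sd, idx.size)
            tau[idx] = tau_out
        outlier_ids[typ] = sorted(int(i) + 1 for i in idx)

    beta, intercept = population_coefficients(config)
    dataset = Dataset(
        X, y, ids=np.arange(1, n + 1), sensor_names=config.sensor_names
    )
    truth = SyntheticTruth(
        latent=tau,
        regression_coefficients=beta,
        regression_intercept=intercept,
        outlier_ids=outlier_ids,
        config=config,
    )
    return dataset, truth


def generate_panel_scores(
    true_intensity: float, n_assessors: int, sd: float, seed: int = 0
) -> np.ndarray:
    """Assessor scores around the true intensity, clipped to the 0.5-5.5 scale."""
    if sd < 0 or n_assessors < 1:
        raise ValueError("sd must be >= 0 and n_assessors >= 1")
    rng = np.random.default_rng(seed)
    return np.clip(rng.normal(true_intensity, sd, n_assessors), 0.5, 5.5)


def generate_replicate_series(
    clean_value: float,
    plan: ReplicatePlan,
    seed: int = 0,
    *,
    sample_id=None,
    sensor_name: str = "",
) -> ReplicateSeries:
    """Per-cycle readings with decaying early drift and stable later cycles.

    Cycles up to the stabilization cycle carry a geometrically decaying
    bias of initial size ``drift_magnitude``; later cycles are the clean
    value plus noise, so with zero noise the mean of the stabilized window
    is exactly the clean value.
    """
    if plan.n_cycles < plan.stabilization_cycle:
        raise ValueError("n_cycles must reach the stabilization cycle")
    rng = np.random.default_rng(seed)
    readings = np.full(plan.n_cycles, float(clean_value))
    for c in range(plan.stabilization_cycle):
        readings[c] += plan.drift_magnitude * 0.5**c
    readings += rng.normal(0.0, plan.noise_sd, plan.n_cycles)
    return ReplicateSeries(sample_id, sensor_name, readings)


def generate_replicate_table(config: SyntheticConfig) -> tuple[pd.DataFrame, Dataset, SyntheticTruth]:
    """Long-format replicate CSV rows whose averaged values reproduce X.

    Returns (replicate table, dataset, truth); the table's per-(sample,
    sensor) mean of the last four cycles equals the dataset's entry when
    the plan's noise is zero.
    """
    dataset, truth = generate_dataset(config)
    rows = []
    for i, sid in enumerate(dataset.ids):
        for j, sensor in enumerate(dataset.sensor_names):
            series = generate_replicate_series(
                dataset.X[i, j],
                config.replicate_plan,
                seed=config.seed + 7919 * (i * dataset.p + j + 1),
                sample_id=sid,
                sensor_name=sensor,
            )
            for c, v in enumerate(series.readings, start=1):
                rows.append(
                    {"sample_id": sid, "sensor": sensor, "cycle": c, "value": v}
                )
    return pd.DataFrame(rows), dataset, truth


def generate_assessor_table(
    dataset: Dataset, config: SyntheticConfig
) -> pd.DataFrame:
    """Long-format assessor scores whose per-sample means track the response."""
    rng = np.random.default_rng(config.seed + 65537)
    lo_sd, hi_sd = config.panel_sd_range
    rows = []
    for i, sid in enumerate(dataset.ids):
        sd = rng.uniform(lo_sd, hi_sd)
        scores = generate_panel_scores(
            dataset.y[i], config.n_assessors, sd, seed=config.seed + 131 * (i + 1)
        )
        for a, sc in enumerate(scores, start=1):
            rows.append({"sample_id": sid, "assessor_id": a, "score": sc})
    return pd.DataFrame(rows)
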