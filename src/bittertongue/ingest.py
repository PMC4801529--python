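"""E-tongue replicate ingestion and predictor-matrix assembly.

Each sample is measured for several acquisition cycles per sensor; the
per-cycle value at the end of the 120 s acquisition is the cycle's final
output.  Signals fluctuate during the first cycles and stabilize after 2-3,
so only the mean of the last few cycles (default 4) enters the analysis.
The averaged responses are assembled into a fixed-column-order
samples-by-sensors matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataset import Dataset
from .reference import SENSOR_NAMES


@dataclass
class ReplicateSeries:
    """Per-cycle final readings for one (sample, sensor) pair."""

    sample_id: object
    sensor_name: str
    readings: np.ndarray

    def __post_init__(self):
        self.readings = np.asarray(self.readings, dtype=float).ravel()


def average_replicates(series: ReplicateSeries, n_last: int = 4) -> float:
    """Mean of the last ``n_last`` cycle readings (stabilized window)."""
    r = series.readings
    if r.size < n_last:
        raise ValueError(
            f"sample {series.sample_id!r} sensor {series.sensor_name}: "
            f"{r.size} readings, need at least {n_last}"
        )
    return float(r[-n_last:].mean())


def assemble_matrix(
    all_series, sensor_order=SENSOR_NAMES, n_last: int = 4
) -> pd.DataFrame:
    """Assemble averaged responses into a wide samples-by-sensors table.

    Every (sample, sensor) pair must be present exactly once.  Rows follow
    first-appearance sample order; columns follow ``sensor_order``.
    """
    sensor_order = tuple(sensor_order)
    cells: dict = {}
    sample_ids: list = []
    for series in all_series:
        key = (series.sample_id, series.sensor_name)
        if key in cells:
            raise ValueError(f"duplicate replicate series for {key}")
        if series.sensor_name not in sensor_order:
            raise ValueError(f"unknown sensor {series.sensor_name!r}")
        cells[key] = average_replicates(series, n_last=n_last)
        if series.sample_id not in sample_ids:
            sample_ids.append(series.sample_id)
    missing = [
        (sid, s) for sid in sample_ids for s in sensor_order if (sid, s) not in cells
    ]
    if missing:
        raise ValueError(f"missing (sample, sensor) pairs: {missing}")
    data = {
        s: [cells[(sid, s)] for sid in sample_ids] for s in sensor_order
    }
    out = pd.DataFrame(data, columns=list(sensor_order))
    out.insert(0, "sample_id", sample_ids)
    return out


def read_replicates(path) -> list[ReplicateSeries]:
    """Read a long-format replicate CSV (sample_id, sensor, cycle, value)."""
    table = pd.read_csv(path)
    for col in ("sample_id", "sensor", "cycle", "value"):
        if col not in table.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for (sid, sensor), grp in table.groupby(
        ["sample_id", "sensor"], sort=False
    ):
        grp = grp.sort_values("cycle")
        out.append(ReplicateSeries(sid, sensor, grp["value"].to_numpy(float)))
    return out


def read_sensor_matrix(path, sensor_order=None) -> pd.DataFrame:
    """Read a wide sensor-matrix CSV (sample_id + one column per sensor)."""
    table = pd.read_csv(path)
    if "sample_id" not in table.columns:
        raise ValueError(f"{path}: missing column 'sample_id'")
    sensors = [c for c in table.columns if c != "sample_id"]
    if sensor_order is not None:
        missing = set(sensor_order) - set(sensors)
        if missing:
            raise ValueError(f"{path}: missing sensor columns {sorted(missing)}")
        table = table[["sample_id", *sensor_order]]
    bad = table.drop(columns="sample_id").apply(
        lambda c: ~pd.to_numeric(c, errors="coerce").notna()
    )
    if bad.to_numpy().any():
        rows, cols = np.nonzero(bad.to_numpy())
        loc = [(int(table["sample_id"].iloc[r]), bad.columns[c]) for r, c in zip(rows, cols)]
        raise ValueError(f"non-numeric sensor cells at {loc}")
    return table


def read_dataset(features_path, response_path) -> Dataset:
    """Join a wide sensor matrix with a per-sample response CSV by id.

    The response file needs columns ``sample_id`` and ``mean`` (or
    ``bitterness``).  Row order follows the features file.
    """
    feats = read_sensor_matrix(features_path)
    resp = pd.read_csv(response_path)
    ycol = "mean" if "mean" in resp.columns else "bitterness"
    if "sample_id" not in resp.columns or ycol not in resp.columns:
        raise ValueError(
            f"{response_path}: need columns 'sample_id' and 'mean'/'bitterness'"
        )
    merged = feats.merge(
        resp[["sample_id", ycol]], on="sample_id", how="left", validate="1:1"
    )
    unmatched = merged.loc[merged[ycol].isna(), "sample_id"].tolist()
    if unmatched:
        raise ValueError(f"no response for sample ids {unmatched}")
    sensors = [c for c in feats.columns if c != "sample_id"]
    return Dataset(
        merged[sensors].to_numpy(float),
        merged[ycol].to_numpy(float),
        ids=merged["sample_id"].to_numpy(),
        sensor_names=sensors,
    )
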