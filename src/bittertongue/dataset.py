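"""Samples-by-sensors calibration dataset container."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class Dataset:
    """An e-tongue calibration set: sensor responses ``X`` and panel means ``y``.

    Parameters
    ----------
    X : ndarray of shape (n, p)
        Averaged sensor responses, one row per decoction sample, one column
        per sensor.
    y : ndarray of shape (n,)
        Per-sample bitterness intensity (human-panel mean, 0.5-5.5 scale).
    ids : sequence of length n
        Sample identifiers; conventionally the 1-based sample numbers.
    sensor_names : sequence of length p
        Column labels, by default the seven bitterness sensors.
    """

    X: np.ndarray
    y: np.ndarray
    ids: np.ndarray = field(default=None)
    sensor_names: tuple = field(default=None)

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ValueError("X must be a 2-D samples-by-sensors matrix")
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError(
                f"X has {self.X.shape[0]} rows but y has {self.y.shape[0]} entries"
            )
        if not (np.isfinite(self.X).all() and np.isfinite(self.y).all()):
            raise ValueError("dataset contains missing or non-finite values")
        if self.ids is None:
            self.ids = np.arange(1, self.X.shape[0] + 1)
        self.ids = np.asarray(self.ids)
        if self.ids.shape[0] != self.X.shape[0]:
            raise ValueError("ids length does not match number of rows")
        if self.sensor_names is None:
            self.sensor_names = tuple(f"x{j + 1}" for j in range(self.X.shape[1]))
        self.sensor_names = tuple(self.sensor_names)
        if len(self.sensor_names) != self.X.shape[1]:
            raise ValueError("sensor_names length does not match number of columns")
        if self.n <= self.p:
            warnings.warn(
                "fewer samples than sensors + 1: classical full-rank fits are "
                "not identifiable",
                stacklevel=2,
            )

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def subset(self, mask_or_index) -> "Dataset":
        """Row subset preserving order (boolean mask or integer index array)."""
        idx = np.asarray(mask_or_index)
        return Dataset(
            self.X[idx], self.y[idx], self.ids[idx], self.sensor_names
        )

    def drop_ids(self, excluded) -> "Dataset":
        """Remove the samples whose id is in ``excluded``."""
        excluded = set(excluded)
        keep = np.array([i not in excluded for i in self.ids.tolist()])
        return self.subset(keep)
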