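"""Shared in-memory containers for epoched sensor data and decoding outputs."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

RING_STEP = 40.0
RING_VALUES = np.arange(9) * RING_STEP  # 0, 40, ..., 320
N_CHANNELS = 9


@dataclass
class EpochSet:
    """Epoched multi-sensor time series with per-trial feature labels.

    Attributes
    ----------
    data : ndarray, shape (n_trials, n_sensors, n_times)
    fs : float
        Sampling rate in Hz.
    times : ndarray, shape (n_times,)
        Seconds relative to epoch onset; strictly increasing, uniform at 1/fs.
    block_ids : ndarray, shape (n_trials,)
        Recording-block id per trial (cross-validation unit).
    labels : dict[str, ndarray]
        Per domain ("location", "color"): (n_trials, 3) ring values in
        degrees, one per serial position.
    """

    data: np.ndarray
    fs: float
    times: np.ndarray
    block_ids: np.ndarray
    labels: dict = field(default_factory=dict)
    sensor_names: list | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.block_ids = np.asarray(self.block_ids)
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.ndim != 3:
            raise ValueError("data must be (trials, sensors, times)")
        if self.times.shape != (self.data.shape[2],):
            raise ValueError("times length must match data time axis")
        dt = np.diff(self.times)
        if self.times.size > 1 and not np.allclose(dt, 1.0 / self.fs, rtol=1e-6):
            raise ValueError("times must be uniform at 1/fs and increasing")
        if self.block_ids.shape != (self.data.shape[0],):
            raise ValueError("block_ids length must match trial count")
        for dom, lab in self.labels.items():
            lab = np.asarray(lab, dtype=float)
            if lab.shape[0] != self.data.shape[0]:
                raise ValueError(f"labels[{dom!r}] trial count mismatch")
            self.labels[dom] = lab

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_sensors(self) -> int:
        return self.data.shape[1]

    @property
    def n_times(self) -> int:
        return self.data.shape[2]

    def select_trials(self, mask) -> "EpochSet":
        mask = np.asarray(mask)
        return EpochSet(
            data=self.data[mask],
            fs=self.fs,
            times=self.times.copy(),
            block_ids=self.block_ids[mask],
            labels={k: v[mask] for k, v in self.labels.items()},
            sensor_names=self.sensor_names,
        )


@dataclass
class DecodingTimecourse:
    """Per-subject time-resolved decoding score (slope of channel response)."""

    times: np.ndarray
    slope: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.slope = np.asarray(self.slope, dtype=float)
        if self.times.shape != self.slope.shape:
            raise ValueError("times and slope must be aligned")


@dataclass
class AccuracyTimecourse:
    """Time-resolved multi-class classification accuracy; chance = 1/8."""

    times: np.ndarray | None
    accuracy: np.ndarray
    chance: float = 0.125
    repeat_accuracies: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.accuracy = np.atleast_1d(np.asarray(self.accuracy, dtype=float))
        if np.any(self.accuracy < 0) or np.any(self.accuracy > 1):
            raise ValueError("accuracy must lie in [0, 1]")
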