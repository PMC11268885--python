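"""File formats and signal preprocessing.

Designs and behavioral reports travel as CSV (one row per trial); epoched
sensor data as HDF5 (datasets ``data``, ``times``, ``block_ids``,
``labels/<domain>``; attribute ``fs``). Preprocessing applies a zero-phase
band-pass, resampling to a target rate, baseline correction, and
variance-based trial rejection.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EpochSet
from .synth import BehavioralReport, TrialDesign

__all__ = [
    "designs_to_frame",
    "frame_to_designs",
    "reports_to_frame",
    "frame_to_reports",
    "save_epochs",
    "load_epochs",
    "preprocess",
]

_POS = ("1", "2", "3")


def designs_to_frame(designs) -> pd.DataFrame:
    rows = []
    for t, d in enumerate(designs):
        row = dict(trial=t, condition=d.condition, block=d.block_id)
        for p in range(3):
            row[f"loc{p+1}"] = d.locations[p]
            row[f"col{p+1}"] = d.colors[p]
            row[f"nom_loc{p+1}"] = d.nominal_locations[p]
            row[f"nom_col{p+1}"] = d.nominal_colors[p]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_designs(df: pd.DataFrame) -> list:
    designs = []
    for _, row in df.iterrows():
        designs.append(TrialDesign(
            condition=row["condition"],
            locations=np.array([row[f"loc{p}"] for p in _POS]),
            colors=np.array([row[f"col{p}"] for p in _POS]),
            nominal_locations=np.array([row[f"nom_loc{p}"] for p in _POS]),
            nominal_colors=np.array([row[f"nom_col{p}"] for p in _POS]),
            block_id=int(row["block"]),
        ))
    return designs


def reports_to_frame(reports) -> pd.DataFrame:
    rows = []
    for t, r in enumerate(reports):
        row = dict(trial=t)
        for p in range(3):
            row[f"rep_loc{p+1}"] = r.reported_locations[p]
            row[f"rep_col{p+1}"] = r.reported_colors[p]
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_reports(df: pd.DataFrame) -> list:
    return [
        BehavioralReport(
            reported_locations=np.array([row[f"rep_loc{p}"] for p in _POS]),
            reported_colors=np.array([row[f"rep_col{p}"] for p in _POS]),
        )
        for _, row in df.iterrows()
    ]


def save_epochs(path, epochs: EpochSet) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data)
        f.create_dataset("times", data=epochs.times)
        f.create_dataset("block_ids", data=np.asarray(epochs.block_ids, int))
        f.attrs["fs"] = epochs.fs
        g = f.create_group("labels")
        for dom, lab in epochs.labels.items():
            g.create_dataset(dom, data=lab)
        if epochs.sensor_names is not None:
            f.attrs["sensor_names"] = [str(s) for s in epochs.sensor_names]


def load_epochs(path) -> EpochSet:
    import h5py

    with h5py.File(path, "r") as f:
        labels = {dom: f["labels"][dom][()] for dom in f["labels"]}
        names = f.attrs.get("sensor_names", None)
        return EpochSet(
            data=f["data"][()],
            fs=float(f.attrs["fs"]),
            times=f["times"][()],
            block_ids=f["block_ids"][()],
            labels=labels,
            sensor_names=None if names is None else [str(s) for s in names],
        )


def preprocess(
    epochs: EpochSet,
    band=(2.0, 50.0),
    target_fs: float = 100.0,
    baseline=(-0.3, -0.1),
    reject_multiplier: float = 5.0,
):
    """Band-pass, downsample, baseline-correct, and reject noisy trials.

    Steps, in order: zero-phase FIR band-pass between ``band`` edges;
    resampling to ``target_fs``; per-trial per-sensor subtraction of the
    mean over the ``baseline`` window (pass None to skip); removal of
    trials whose total variance (over sensors and time) exceeds the median
    trial variance times ``reject_multiplier``.

    Returns ``(EpochSet, report)`` where ``report`` lists rejected trial
    indices and the parameters applied.
    """
    from mne.filter import filter_data, resample

    lo, hi = float(band[0]), float(band[1])
    if epochs.fs <= 2.0 * hi:
        raise ValueError("sampling rate must exceed twice the band's upper edge")
    n, m, T = epochs.data.shape
    flat = epochs.data.reshape(n * m, T)
    flat = filter_data(flat, sfreq=epochs.fs, l_freq=lo, h_freq=hi,
                       verbose="error")
    fs = epochs.fs
    if target_fs != fs:
        flat = resample(flat, up=float(target_fs), down=float(fs),
                        verbose="error")
        fs = float(target_fs)
    data = flat.reshape(n, m, -1)
    times = epochs.times[0] + np.arange(data.shape[2]) / fs

    if baseline is not None:
        b0, b1 = baseline
        if b0 < times[0] - 1e-9 or b1 > times[-1] + 1e-9 or b1 <= b0:
            raise ValueError(
                f"baseline window ({b0}, {b1}) outside epoch "
                f"({times[0]:.3f}, {times[-1]:.3f})"
            )
        win = (times >= b0) & (times <= b1)
        data = data - data[:, :, win].mean(axis=2, keepdims=True)

    var = data.var(axis=(1, 2))
    thresh = np.median(var) * reject_multiplier
    rejected = np.flatnonzero(var > thresh)
    keep = np.setdiff1d(np.arange(n), rejected)
    clean = EpochSet(
        data=data[keep], fs=fs, times=times,
        block_ids=epochs.block_ids[keep],
        labels={k: v[keep] for k, v in epochs.labels.items()},
        sensor_names=epochs.sensor_names,
    )
    report = dict(
        rejected_trials=rejected.tolist(),
        n_rejected=int(rejected.size),
        variance_threshold=float(thresh),
        band=[lo, hi], target_fs=fs,
        baseline=None if baseline is None else list(baseline),
        reject_multiplier=reject_multiplier,
    )
    return clean, report
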