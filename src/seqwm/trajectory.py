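"""Eight-way decoding of signed circular trajectory distances.

On a 9-point ring the signed circular distance between two distinct grid
values is one of +/-40, +/-80, +/-120, +/-160 degrees -- eight classes, so
chance accuracy is 1/8. A linear one-vs-rest support vector machine is
trained per time point with stratified k-fold cross-validation repeated
over fresh random partitions; the mean accuracy over folds and repeats is
the decoding score. Alpha-band (8-12 Hz) power features for the retention
period come from a 7-cycle Morlet wavelet transform.
"""

from __future__ import annotations

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import LinearSVC

from .circstats import circ_diff
from .core import AccuracyTimecourse, EpochSet

__all__ = [
    "TRAJECTORY_CLASSES",
    "trajectory_labels",
    "trajectory_label_array",
    "morlet_alpha_power",
    "decode_trajectory",
]

TRAJECTORY_CLASSES = (-160.0, -120.0, -80.0, -40.0, 40.0, 80.0, 120.0, 160.0)
_LEG_IDX = {"12": (0, 1), "23": (1, 2), "13": (0, 2)}


def trajectory_labels(design, domain: str = "location", leg: str = "12") -> float:
    """Signed circular distance of a leg's two nominal values, degrees.

    The result is a nonzero multiple of 40 with magnitude <= 160; a zero
    distance would violate the task's distinctness constraint and raises.
    """
    if leg not in _LEG_IDX:
        raise ValueError("leg must be one of '12', '23', '13'")
    vals = (design.nominal_locations if domain == "location"
            else design.nominal_colors)
    i, j = _LEG_IDX[leg]
    d = float(circ_diff(vals[j], vals[i]))
    if d == 0.0:
        raise ValueError("zero trajectory distance: items must be distinct")
    if d not in TRAJECTORY_CLASSES:
        raise ValueError(f"off-grid trajectory distance {d}")
    return d


def trajectory_label_array(designs, domain: str = "location",
                           leg: str = "12") -> np.ndarray:
    return np.array([trajectory_labels(d, domain, leg) for d in designs])


def morlet_alpha_power(epochs: EpochSet, band=(8.0, 12.0),
                       cycles: int = 7, log: bool = False) -> np.ndarray:
    """Morlet-wavelet band power (trials x sensors x times).

    Power is averaged over 1 Hz steps spanning ``band``. The sampling rate
    must satisfy Nyquist for the band's upper edge and the epoch must be
    at least as long as the widest wavelet (``cycles / band[0]`` seconds).
    Pass ``log=True`` to return log power, the recommended scale when the
    output feeds the linear trajectory classifier (power is heavily
    right-skewed; the log makes it closer to Gaussian per feature).
    """
    from mne.time_frequency import tfr_array_morlet

    lo, hi = float(band[0]), float(band[1])
    if epochs.fs < 2.0 * hi:
        raise ValueError("sampling rate below Nyquist for the band")
    if epochs.n_times / epochs.fs < cycles / lo:
        raise ValueError("epoch shorter than the widest wavelet")
    freqs = np.arange(lo, hi + 0.5, 1.0)
    power = tfr_array_morlet(epochs.data, sfreq=epochs.fs, freqs=freqs,
                             n_cycles=cycles, output="power", verbose="error")
    band_power = power.mean(axis=2)
    return np.log(band_power) if log else band_power


def _class_census(labels):
    vals, counts = np.unique(labels, return_counts=True)
    return dict(zip(vals.tolist(), counts.tolist()))


def decode_trajectory(
    features: np.ndarray,
    labels,
    n_folds: int = 5,
    n_repeats: int = 50,
    seed: int = 0,
    C: float = 1.0,
    times=None,
) -> AccuracyTimecourse:
    """Cross-validated 8-way trajectory-distance classification accuracy.

    ``features`` is (n_trials, n_features) for a single time point or
    (n_trials, n_features, n_times). Per time point, a standardized linear
    one-vs-rest SVM (regularization ``C``) is scored with stratified
    ``n_folds``-fold CV; the partition is redrawn ``n_repeats`` times and
    accuracies averaged over folds then repeats. All eight classes must be
    present with at least ``n_folds`` instances each.
    """
    X = np.asarray(features, float)
    y = np.asarray(labels, float)
    single = X.ndim == 2
    if single:
        X = X[:, :, None]
    if X.ndim != 3 or X.shape[0] != y.size:
        raise ValueError("features must be (trials, features[, times]) "
                         "aligned with labels")
    census = _class_census(y)
    missing = [c for c in TRAJECTORY_CLASSES if c not in census]
    if missing:
        raise ValueError(f"missing classes {missing}; census: {census}")
    if min(census.values()) < max(2, n_folds):
        raise ValueError(f"each class needs >= {max(2, n_folds)} instances; "
                         f"census: {census}")

    ss = np.random.SeedSequence(seed)
    repeat_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                    ss.spawn(n_repeats)]
    T = X.shape[2]
    per_repeat = np.empty((n_repeats, T))
    for rep, rs in enumerate(repeat_seeds):
        cv = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rs)
        folds = list(cv.split(X[:, :, 0], y))
        for t in range(T):
            Xt = X[:, :, t]
            accs = []
            for train, test in folds:
                clf = make_pipeline(
                    StandardScaler(),
                    LinearSVC(C=C, multi_class="ovr", dual="auto"),
                )
                clf.fit(Xt[train], y[train])
                accs.append(clf.score(Xt[test], y[test]))
            per_repeat[rep, t] = np.mean(accs)
    return AccuracyTimecourse(
        times=None if times is None else np.asarray(times, float),
        accuracy=per_repeat.mean(axis=0),
        chance=1.0 / len(TRAJECTORY_CLASSES),
        repeat_accuracies=per_repeat,
        metadata=dict(n_folds=n_folds, n_repeats=n_repeats, seed=seed, C=C,
                      census=census),
    )
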