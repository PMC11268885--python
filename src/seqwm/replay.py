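"""Sequential-replay detection from decoded item time courses.

Given one decoding time course per serial position, forward replay at lag
dt shows up as the first item's time course predicting the second at t+dt
and the second predicting the third at t+dt. The machinery here computes
lagged correlations for consecutive item pairs, subtracts the reverse
direction from the forward direction to cancel autocorrelation, locates
the peak of the averaged asymmetry profile (the consensus inter-item lag),
compares the full 3x3 lagged-correlation matrix against the theoretical
forward-transition pattern, and calibrates significance with a
label-shuffle permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LagProfile",
    "lagged_correlation",
    "direction_asymmetry",
    "find_peak_lag",
    "theoretical_matrix",
    "empirical_matrix",
    "matrix_similarity",
    "replay_permutation_null",
]


@dataclass
class LagProfile:
    """Forward/reverse lagged correlations and their asymmetry per item pair."""

    lags: np.ndarray  # seconds, >= 0
    fwd: dict  # pair ("12", "23") -> coefficients per lag
    rev: dict
    asym: dict  # fwd - rev, elementwise
    mean_asym: np.ndarray


def _pearson_at_lag(x, y, L):
    """corr(x(t), y(t+L)) over the overlapping window; NaN if degenerate."""
    n = x.size
    if L >= n - 1:
        return np.nan
    a = x[: n - L] if L > 0 else x
    b = y[L:] if L > 0 else y
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return np.nan
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def lagged_correlation(x, y, max_lag: float, fs: float):
    """Linear correlation of x(t) with y(t+L) for lags L = 0 .. max_lag.

    Returns ``(lags_seconds, coefficients)``. Zero-variance overlap windows
    yield NaN coefficients with a warning.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d time courses")
    max_samples = int(round(max_lag * fs))
    if max_samples >= x.size:
        raise ValueError("max_lag must be shorter than the window")
    lags = np.arange(max_samples + 1) / fs
    r = np.array([_pearson_at_lag(x, y, L) for L in range(max_samples + 1)])
    if np.any(np.isnan(r)):
        warnings.warn("zero-variance overlap: undefined coefficients set to NaN",
                      stacklevel=2)
    return lags, r


def direction_asymmetry(item_timecourses, max_lag: float, fs: float) -> LagProfile:
    """Forward-minus-reverse lagged correlations for pairs 1->2 and 2->3.

    asym_12(L) = corr(x1(t), x2(t+L)) - corr(x2(t), x1(t+L)), likewise for
    2->3; ``mean_asym`` averages the two profiles.
    """
    tcs = np.asarray(item_timecourses, float)
    if tcs.shape[0] != 3:
        raise ValueError("expected three aligned item time courses")
    pairs = {"12": (0, 1), "23": (1, 2)}
    fwd, rev, asym = {}, {}, {}
    lags = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, (i, j) in pairs.items():
            lags, f = lagged_correlation(tcs[i], tcs[j], max_lag, fs)
            _, r = lagged_correlation(tcs[j], tcs[i], max_lag, fs)
            fwd[name], rev[name] = f, r
            asym[name] = f - r
    mean_asym = 0.5 * (asym["12"] + asym["23"])
    return LagProfile(lags=lags, fwd=fwd, rev=rev, asym=asym, mean_asym=mean_asym)


def find_peak_lag(profile: LagProfile) -> float:
    """Lag (seconds) of the maximum mean asymmetry; ties -> smallest lag."""
    m = profile.mean_asym
    if m.size == 0 or np.all(np.isnan(m)):
        raise ValueError("asymmetry profile is empty or all-undefined")
    finite = m[np.isfinite(m)]
    if finite.max() == finite.min():
        warnings.warn("flat asymmetry profile: peak lag degenerate, "
                      "returning smallest lag", stacklevel=2)
    idx = int(np.nanargmax(m))  # argmax returns the first (smallest) lag on ties
    return float(profile.lags[idx])


def theoretical_matrix(n_items: int = 3) -> np.ndarray:
    """Ideal forward-transition pattern: 1 at (i, i+1), 0 elsewhere."""
    if n_items < 2:
        raise ValueError("n_items must be >= 2")
    return np.eye(n_items, k=1)


def empirical_matrix(item_timecourses, lag: float, fs: float) -> np.ndarray:
    """All-ordered-pairs lagged-correlation matrix at a fixed lag.

    M[i, j] = corr(x_i(t), x_j(t + lag)), including the diagonal
    (self-correlation; equals 1 at lag 0).
    """
    tcs = np.asarray(item_timecourses, float)
    n = tcs.shape[0]
    L = int(round(lag * fs))
    if L >= tcs.shape[1]:
        raise ValueError("lag must lie within the window")
    M = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            M[i, j] = _pearson_at_lag(tcs[i], tcs[j], L)
    if np.any(np.isnan(M)):
        warnings.warn("zero-variance time course: undefined matrix entries",
                      stacklevel=2)
    return M


def matrix_similarity(E: np.ndarray, T: np.ndarray,
                      include_diagonal: bool = True) -> float:
    """Linear correlation between two transition matrices over their cells."""
    E = np.asarray(E, float)
    T = np.asarray(T, float)
    if E.shape != T.shape:
        raise ValueError("matrices must share a shape")
    if include_diagonal:
        e, t = E.ravel(), T.ravel()
    else:
        mask = ~np.eye(E.shape[0], dtype=bool)
        e, t = E[mask], T[mask]
    if e.std() == 0.0 or t.std() == 0.0:
        warnings.warn("constant matrix: similarity undefined", stacklevel=2)
        return np.nan
    return float(np.corrcoef(e, t)[0, 1])


def replay_permutation_null(
    subject_timecourses,
    statistic,
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
):
    """Label-shuffle permutation null for a group replay statistic.

    ``subject_timecourses`` is (n_subjects, n_items, n_times). The observed
    statistic is computed on the grand-average item time courses. For each
    permutation the item-identity assignment is permuted independently
    within each subject before averaging, and the statistic recomputed.

    Returns a dict with the observed statistic, the permutation
    distribution, the (1 - alpha) threshold, and the permutation p-value
    ``(1 + #{null >= observed}) / (1 + n_perm)``.
    """
    tcs = np.asarray(subject_timecourses, float)
    if tcs.ndim != 3 or tcs.shape[0] < 2:
        raise ValueError("need (n_subjects >= 2, n_items, n_times)")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a coarse threshold", stacklevel=2)
    rng = np.random.default_rng(seed)
    n_subj, n_items, _ = tcs.shape
    observed = float(statistic(tcs.mean(axis=0)))
    null = np.empty(n_perm)
    for p in range(n_perm):
        shuffled = np.stack([tcs[s][rng.permutation(n_items)]
                             for s in range(n_subj)])
        null[p] = statistic(shuffled.mean(axis=0))
    threshold = float(np.nanquantile(null, 1.0 - alpha))
    p_value = float((1 + np.sum(null >= observed)) / (1 + n_perm))
    return dict(observed=observed, null=null, threshold=threshold,
                p_value=p_value, alpha=alpha)
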