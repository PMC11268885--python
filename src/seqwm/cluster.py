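"""Mass-univariate tests with cluster-based permutation correction.

Pointwise one-sample t-tests across subjects are corrected for multiple
comparisons over time by forming clusters of contiguous suprathreshold
samples (same effect sign), scoring each cluster by its size in samples
(or mass, the summed |t|), and comparing against the distribution of
maximal cluster scores under per-subject sign flips of the deviations from
the null value -- the standard one-sample cluster permutation, algebraically
equivalent to exchanging each subject's observed values with the null
constant. A bootstrap test for a difference between two groups of
per-subject scalars is also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "ClusterResult",
    "pointwise_test",
    "cluster_permutation",
    "bootstrap_group_diff",
]


@dataclass
class ClusterResult:
    """Clusters of contiguous suprathreshold samples with corrected p-values."""

    clusters: list  # dicts: start, stop (sample idx, half-open), size, sign, p
    t: np.ndarray
    p_pointwise: np.ndarray
    params: dict = field(default_factory=dict)


def pointwise_test(data: np.ndarray, null_value: float = 0.0):
    """One-sample t-test against ``null_value`` at every time sample.

    ``data`` is (n_subjects, n_times); returns (t, p) arrays with two-tailed
    p-values. Zero-variance samples give infinite t (suprathreshold, p=0)
    when the mean differs from the null, t=0 and p=1 when it equals it.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("data must be (n_subjects >= 3, n_times)")
    dev = data - null_value
    n = data.shape[0]
    mean = dev.mean(axis=0)
    sd = dev.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    zero_var = sd == 0.0
    if np.any(zero_var):
        warnings.warn("zero-variance samples: infinite t treated as "
                      "suprathreshold", stacklevel=2)
        t[zero_var & (mean != 0)] = np.sign(mean[zero_var & (mean != 0)]) * np.inf
        t[zero_var & (mean == 0)] = 0.0
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 1)
    return t, p


def _max_cluster_score(supra: np.ndarray, tvals: np.ndarray,
                       use_mass: bool) -> float:
    """Largest cluster score in a boolean suprathreshold vector."""
    best = 0.0
    run = 0
    mass = 0.0
    for i in range(supra.size):
        if supra[i]:
            run += 1
            mass += abs(tvals[i])
        else:
            best = max(best, mass if use_mass else run)
            run, mass = 0, 0.0
    return max(best, mass if use_mass else run)


def _clusters_from(supra: np.ndarray, sign: np.ndarray):
    """Maximal runs of suprathreshold samples sharing an effect sign."""
    out = []
    i = 0
    n = supra.size
    while i < n:
        if supra[i]:
            j = i
            while j + 1 < n and supra[j + 1] and sign[j + 1] == sign[i]:
                j += 1
            out.append((i, j + 1))
            i = j + 1
        else:
            i += 1
    return out


def cluster_permutation(
    data: np.ndarray,
    null_value: float = 0.0,
    cluster_alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "size",
) -> ClusterResult:
    """Cluster-size permutation test of subjects x time data against a null.

    Clusters are contiguous samples whose two-tailed pointwise p falls below
    ``cluster_alpha`` (same sign of effect); each cluster's statistic is its
    size in samples (``statistic="mass"`` uses summed |t| instead). The null
    distribution of the maximal cluster statistic is built from ``n_perm``
    per-subject sign flips of the deviations from ``null_value``. Corrected
    p-values use the (b + 1)/(n_perm + 1) convention.
    """
    data = np.asarray(data, float)
    if data.ndim != 2 or data.shape[0] < 3:
        raise ValueError("data must be (n_subjects >= 3, n_times)")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if statistic not in ("size", "mass"):
        raise ValueError("statistic must be 'size' or 'mass'")
    use_mass = statistic == "mass"
    n, T = data.shape
    dev = data - null_value
    t_obs, p_obs = pointwise_test(data, null_value)
    t_crit = stats.t.ppf(1.0 - cluster_alpha / 2.0, df=n - 1)
    supra_obs = np.abs(t_obs) > t_crit
    sign_obs = np.sign(t_obs)
    spans = _clusters_from(supra_obs, sign_obs)

    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    # sign-flipped t per permutation, vectorized:
    # mean_p = S @ dev / n; second moment of s_i*d_i is d_i^2, independent of s
    mean_p = signs @ dev / n
    msq = np.mean(dev**2, axis=0)  # (T,)
    var_p = (msq[None, :] - mean_p**2) * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t_perm = mean_p / np.sqrt(var_p / n)
    t_perm = np.nan_to_num(t_perm, nan=0.0, posinf=np.inf, neginf=-np.inf)
    supra_perm = np.abs(t_perm) > t_crit
    max_null = np.array([
        _max_cluster_score(supra_perm[p], t_perm[p], use_mass)
        for p in range(n_perm)
    ])

    clusters = []
    for (a, b) in spans:
        score = float(np.sum(np.abs(t_obs[a:b]))) if use_mass else float(b - a)
        p_corr = float((1 + np.sum(max_null >= score)) / (1 + n_perm))
        clusters.append(dict(start=a, stop=b, size=b - a, score=score,
                             sign=int(sign_obs[a]), p=p_corr))
    return ClusterResult(
        clusters=clusters,
        t=t_obs,
        p_pointwise=p_obs,
        params=dict(null_value=null_value, cluster_alpha=cluster_alpha,
                    n_perm=n_perm, seed=seed, statistic=statistic,
                    t_crit=float(t_crit)),
    )


def bootstrap_group_diff(groupA, groupB, n_boot: int = 10000,
                         seed: int = 0) -> float:
    """Two-sided bootstrap p-value for a difference in group means.

    Both groups are resampled with replacement ``n_boot`` times; the
    two-sided p is twice the smaller tail proportion of resampled mean
    differences falling on either side of zero (capped at 1).
    """
    a = np.asarray(groupA, float)
    b = np.asarray(groupB, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 subjects")
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    ma = a[rng.integers(0, a.size, size=(n_boot, a.size))].mean(axis=1)
    mb = b[rng.integers(0, b.size, size=(n_boot, b.size))].mean(axis=1)
    diffs = ma - mb
    lo = np.mean(diffs <= 0)
    hi = np.mean(diffs >= 0)
    return float(min(1.0, 2.0 * min(lo, hi)))
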