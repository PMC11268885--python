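"""Lagged correlations, direction asymmetry, transition matrices, permutation."""

import numpy as np
import pytest

from seqwm.replay import (direction_asymmetry, empirical_matrix, find_peak_lag,
                          lagged_correlation, matrix_similarity,
                          replay_permutation_null, theoretical_matrix)

FS = 100.0


def _shifted_noise(n=500, shift=13, seed=0):
    """x leads y by `shift` samples: y(t) = x(t - shift)."""
    rng = np.random.default_rng(seed)
    base = rng.normal(size=n + shift)
    return base[shift:shift + n], base[:n]


def test_shift_identity_peak():
    x, y = _shifted_noise(shift=13)
    lags, r = lagged_correlation(x, y, max_lag=0.3, fs=FS)
    assert lags[np.argmax(r)] == pytest.approx(0.13)
    assert r.max() > 0.9


def test_independent_noise_null_width():
    rng = np.random.default_rng(1)
    _, r = lagged_correlation(rng.normal(size=500), rng.normal(size=500),
                              max_lag=0.3, fs=FS)
    assert np.all(np.abs(r) < 0.15)


def test_noisy_shift_attenuation_matches_theory():
    """Peak height under additive noise follows 1/sqrt(1 + 1/snr2)."""
    rng = np.random.default_rng(2)
    n, shift = 20000, 10
    base = rng.normal(size=n + shift)
    snr2 = 1.0  # variance ratio
    x = base[shift:shift + n]
    y = base[:n] + rng.normal(0, 1.0 / np.sqrt(snr2), size=n)
    _, r = lagged_correlation(x, y, max_lag=0.2, fs=FS)
    expected = 1.0 / np.sqrt(1.0 + 1.0 / snr2)
    assert r[shift] == pytest.approx(expected, abs=0.03)


def test_zero_variance_flagged():
    with pytest.warns(UserWarning, match="zero-variance"):
        _, r = lagged_correlation(np.ones(50), np.arange(50.0),
                                  max_lag=0.1, fs=FS)
    assert np.all(np.isnan(r))


def test_asymmetry_contracts():
    rng = np.random.default_rng(3)
    x = rng.normal(size=300)
    # exchange-symmetric: identical first two items
    prof = direction_asymmetry([x, x, rng.normal(size=300)], 0.2, FS)
    assert np.allclose(prof.asym["12"], 0.0)
    # antisymmetry under swapping a pair
    a = rng.normal(size=300)
    b = rng.normal(size=300)
    c = rng.normal(size=300)
    p1 = direction_asymmetry([a, b, c], 0.2, FS)
    p2 = direction_asymmetry([b, a, c], 0.2, FS)
    assert np.allclose(p1.asym["12"], -p2.asym["12"])


def test_planted_chain_forward_and_reversed():
    rng = np.random.default_rng(4)
    shift = 10
    base = rng.normal(size=400)
    # forward chain: each item's time course is the previous one delayed
    x1 = base[2 * shift:300 + 2 * shift]
    x2 = base[shift:300 + shift]
    x3 = base[:300]
    prof = direction_asymmetry([x1, x2, x3], 0.25, FS)
    assert find_peak_lag(prof) == pytest.approx(shift / FS)
    rev = direction_asymmetry([x3, x2, x1], 0.25, FS)
    assert rev.mean_asym[shift] < 0


def test_peak_lag_tie_rule_and_degenerate():
    prof = direction_asymmetry(
        [np.ones(50), np.ones(50), np.ones(50)], 0.1, FS)
    with pytest.raises(ValueError):
        find_peak_lag(prof)  # all-NaN profile
    rng = np.random.default_rng(5)
    flat = direction_asymmetry([rng.normal(size=50)] * 3, 0.1, FS)
    with pytest.warns(UserWarning, match="flat"):
        assert find_peak_lag(flat) == 0.0


@pytest.mark.parametrize("n,expected", [
    (2, [[0, 1], [0, 0]]),
    (3, [[0, 1, 0], [0, 0, 1], [0, 0, 0]]),
    (4, None),
])
def test_theoretical_matrix(n, expected):
    T = theoretical_matrix(n)
    if expected is not None:
        assert np.array_equal(T, np.array(expected, float))
    else:
        assert np.array_equal(T, np.eye(4, k=1))


def test_empirical_matrix_lag_zero_diag_and_chain():
    rng = np.random.default_rng(6)
    tcs = rng.normal(size=(3, 200))
    M0 = empirical_matrix(tcs, lag=0.0, fs=FS)
    assert np.allclose(np.diag(M0), 1.0)
    assert np.all(np.abs(M0 - np.eye(3) * M0) < 0.2)  # off-diag near 0
    shift = 12
    base = rng.normal(size=500)
    chain = np.stack([base[(2 - i) * shift:300 + (2 - i) * shift]
                      for i in range(3)])
    M = empirical_matrix(chain, lag=shift / FS, fs=FS)
    planted = {(0, 1), (1, 2)}
    assert min(M[0, 1], M[1, 2]) > 0.9
    off = [M[i, j] for i in range(3) for j in range(3)
           if (i, j) not in planted and i != j]
    assert max(np.abs(off)) < 0.3


def test_matrix_similarity_contracts():
    T = theoretical_matrix(3)
    assert matrix_similarity(T, T) == pytest.approx(1.0)
    assert matrix_similarity(1.0 - T, T) == pytest.approx(-1.0)
    with pytest.warns(UserWarning, match="constant"):
        assert np.isnan(matrix_similarity(np.ones((3, 3)), T))
    off = matrix_similarity(T + 0.1, T, include_diagonal=False)
    assert np.isfinite(off)


def test_permutation_null_determinism_and_degenerate():
    rng = np.random.default_rng(7)
    tcs = rng.normal(size=(5, 3, 120))
    stat = lambda g: float(g.max())
    a = replay_permutation_null(tcs, stat, n_perm=200, seed=3)
    b = replay_permutation_null(tcs, stat, n_perm=200, seed=3)
    assert np.array_equal(a["null"], b["null"])
    # item-exchange-invariant statistic -> constant null equal to observed
    const_stat = lambda g: float(np.sum(g))
    c = replay_permutation_null(tcs, const_stat, n_perm=150, seed=4)
    assert np.allclose(c["null"], c["observed"])
    assert c["threshold"] == pytest.approx(c["observed"])
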