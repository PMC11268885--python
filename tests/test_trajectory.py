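"""Trajectory-distance labels, alpha power features, 8-way classification."""

import itertools

import numpy as np
import pytest

import seqwm
from seqwm.circstats import circ_diff
from seqwm.trajectory import (TRAJECTORY_CLASSES, decode_trajectory,
                              morlet_alpha_power, trajectory_labels)


def _design(locs, cols=None, cond="MAT"):
    cols = cols if cols is not None else [(v + 80) % 360 for v in locs]
    return seqwm.TrialDesign(condition=cond, locations=np.array(locs, float),
                             colors=np.array(cols, float),
                             nominal_locations=np.array(locs, float),
                             nominal_colors=np.array(cols, float))


def test_label_examples():
    d = _design([0, 40, 120])
    assert trajectory_labels(d, "location", "12") == 40.0
    d = _design([0, 40, 320])
    assert trajectory_labels(d, "location", "23") == -80.0
    d = _design([0, 200, 240])
    assert trajectory_labels(d, "location", "12") == -160.0  # wraps


def test_exhaustive_enumeration_gives_eight_classes():
    grid = seqwm.RING_VALUES
    dists = {float(circ_diff(b, a))
             for a, b in itertools.permutations(grid, 2)}
    assert dists == set(TRAJECTORY_CLASSES)
    assert len(dists) == 8


def test_label_census_over_generated_designs():
    designs = seqwm.generate_design(n_trials=648, seed=1)
    labels = seqwm.trajectory_label_array(designs, "location", "12")
    vals, counts = np.unique(labels, return_counts=True)
    assert set(vals.tolist()) == set(TRAJECTORY_CLASSES)
    assert counts.min() > 648 / 8 * 0.5  # uniform-ish census


class TestAlphaPower:
    def _epochs(self, freq, fs=200.0, n_trials=4, amp=1.0, seed=0):
        t = np.arange(int(2.0 * fs)) / fs
        rng = np.random.default_rng(seed)
        data = amp * np.sin(2 * np.pi * freq * t)[None, None, :] * np.ones(
            (n_trials, 3, 1)) + rng.normal(0, 1e-6, (n_trials, 3, t.size))
        return seqwm.EpochSet(data=data, fs=fs, times=t,
                              block_ids=np.zeros(n_trials, int))

    def test_band_selectivity(self):
        p10 = morlet_alpha_power(self._epochs(10.0)).mean()
        p30 = morlet_alpha_power(self._epochs(30.0)).mean()
        assert p10 / p30 > 10

    def test_quadratic_amplitude_scaling(self):
        p1 = morlet_alpha_power(self._epochs(10.0, amp=1.0)).mean()
        p2 = morlet_alpha_power(self._epochs(10.0, amp=2.0)).mean()
        assert p2 / p1 == pytest.approx(4.0, rel=0.01)

    def test_white_noise_power_matches_filter_gain(self):
        """E[band power of white noise] = sigma^2 x filter energy.

        The filter energy sum_t |psi(t)|^2 (averaged over band
        frequencies) is measured independently from the transform's
        impulse response, using linearity; stationary white noise of
        variance sigma^2 must then carry sigma^2 times that gain, away
        from the epoch edges.
        """
        fs, T = 200.0, 800
        t = np.arange(T) / fs
        impulse = np.zeros((1, 1, T))
        impulse[0, 0, T // 2] = 1.0
        ep_imp = seqwm.EpochSet(data=impulse, fs=fs, times=t,
                                block_ids=np.zeros(1, int))
        gain = morlet_alpha_power(ep_imp).sum()
        rng = np.random.default_rng(9)
        sigma = 1.7
        noise = rng.normal(0, sigma, size=(40, 2, T))
        ep_noise = seqwm.EpochSet(data=noise, fs=fs, times=t,
                                  block_ids=np.zeros(40, int))
        p = morlet_alpha_power(ep_noise)[:, :, T // 4: 3 * T // 4]
        assert p.mean() == pytest.approx(sigma**2 * gain, rel=0.05)

    def test_log_scale_option(self):
        p = morlet_alpha_power(self._epochs(10.0))
        lp = morlet_alpha_power(self._epochs(10.0), log=True)
        assert np.allclose(lp, np.log(p))

    def test_preconditions(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_alpha_power(self._epochs(10.0, fs=20.0))
        short = self._epochs(10.0)
        short = seqwm.EpochSet(data=short.data[:, :, :80], fs=200.0,
                               times=short.times[:80],
                               block_ids=short.block_ids)
        with pytest.raises(ValueError, match="shorter"):
            morlet_alpha_power(short)


class TestDecode:
    def _separable(self, n_per_class=12, noise=0.01, seed=0):
        rng = np.random.default_rng(seed)
        X, y = [], []
        for i, c in enumerate(TRAJECTORY_CLASSES):
            mu = np.zeros(8)
            mu[i] = 10.0
            X.append(mu + rng.normal(0, noise, size=(n_per_class, 8)))
            y += [c] * n_per_class
        return np.vstack(X), np.array(y)

    def test_separable_features_near_perfect(self):
        X, y = self._separable()
        acc = decode_trajectory(X, y, n_repeats=3, seed=1)
        assert acc.accuracy[0] > 0.99

    def test_scaling_invariance(self):
        X, y = self._separable(noise=0.5)
        a1 = decode_trajectory(X, y, n_repeats=3, seed=2)
        a2 = decode_trajectory(X * 50.0, y, n_repeats=3, seed=2)
        assert abs(a1.accuracy[0] - a2.accuracy[0]) < 0.05

    def test_missing_class_rejected_with_census(self):
        X, y = self._separable()
        y2 = y.copy()
        y2[y2 == 40.0] = 80.0
        with pytest.raises(ValueError, match="census"):
            decode_trajectory(X, y2, n_repeats=2, seed=0)

    def test_shuffled_labels_at_chance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(240, 10))
        y = np.repeat(TRAJECTORY_CLASSES, 30)
        rng.shuffle(y)
        acc = decode_trajectory(X, y, n_repeats=10, seed=4)
        # 3 binomial SEs around chance
        se = np.sqrt(0.125 * 0.875 / 240)
        assert abs(acc.accuracy[0] - 0.125) < 3 * se + 0.02

    def test_repeat_variance_shrinks_with_more_repeats(self):
        X, y = self._separable(noise=3.0, seed=5)
        many = decode_trajectory(X, y, n_repeats=20, seed=6)
        few = decode_trajectory(X, y, n_repeats=4, seed=6)
        sem_many = many.repeat_accuracies.std() / np.sqrt(20)
        sem_few = few.repeat_accuracies.std() / np.sqrt(4)
        assert sem_many < sem_few
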