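"""Inverted encoding model: basis, training, inversion, slope, decoding."""

import numpy as np
import pytest

import seqwm
from seqwm.iem import (gaussian_smooth, invert_weights, make_basis,
                       recenter_average, response_slope, train_weights)


class TestBasis:
    def test_values_at_landmarks(self):
        b = make_basis()
        r = b.evaluate(80.0)
        assert r[2] == pytest.approx(1.0)          # own center
        assert b.evaluate(90.0)[0] == pytest.approx(0.0, abs=1e-12)  # 90 off
        # 40 deg off-center: cos(40 deg)^8
        assert b.evaluate(40.0)[0] == pytest.approx(np.cos(np.deg2rad(40)) ** 8)
        assert b.evaluate(40.0)[0] == pytest.approx(0.1186, abs=2e-4)
        assert np.all(r >= 0)

    def test_rotational_symmetry(self):
        b = make_basis()
        shifted = seqwm.BasisSet((b.centers + 25.0) % 360, 8)
        assert np.allclose(b.evaluate(100.0), shifted.evaluate(125.0))

    def test_duplicate_centers_rejected(self):
        with pytest.raises(ValueError):
            seqwm.BasisSet([0, 40, 40], 8)


class TestTrainInvert:
    def test_exact_recovery_and_round_trip(self):
        rng = np.random.default_rng(0)
        W0 = rng.normal(size=(16, 9))
        C = rng.uniform(0, 1, size=(9, 40))
        B = W0 @ C
        W_hat = train_weights(B, C)
        assert np.allclose(W_hat, W0, atol=1e-9)
        assert np.allclose(invert_weights(W_hat, B), C, atol=1e-9)
        assert np.allclose(invert_weights(W_hat, np.zeros_like(B)), 0.0)

    def test_residual_orthogonal_to_channel_responses(self):
        rng = np.random.default_rng(1)
        C = rng.uniform(0, 1, size=(9, 60))
        B = rng.normal(size=(16, 9)) @ C + rng.normal(0, 0.5, size=(16, 60))
        W_hat = train_weights(B, C)
        # normal equations; cross-check against numpy's lstsq solution
        resid = B - W_hat @ C
        assert np.allclose(resid @ C.T, 0.0, atol=1e-8)
        W_ref = np.linalg.lstsq(C.T, B.T, rcond=None)[0].T
        assert np.allclose(W_hat, W_ref, atol=1e-8)

    def test_rank_preconditions(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            train_weights(rng.normal(size=(16, 5)), rng.uniform(size=(9, 5)))
        C_bad = np.ones((9, 30))
        with pytest.raises(np.linalg.LinAlgError):
            train_weights(rng.normal(size=(16, 30)), C_bad)
        with pytest.raises(np.linalg.LinAlgError):
            invert_weights(np.ones((16, 9)), rng.normal(size=(16, 4)))

    def test_inversion_unbiased_under_sensor_noise(self):
        rng = np.random.default_rng(3)
        W = rng.normal(size=(16, 9))
        C = rng.uniform(0, 1, size=(9, 1))
        est = np.mean([
            invert_weights(W, W @ C + rng.normal(0, 1, size=(16, 1)))
            for _ in range(1000)
        ], axis=0)
        assert np.allclose(est, C, atol=0.15)


class TestRecenterSlope:
    def test_delta_alignment_identity(self):
        feats = seqwm.RING_VALUES.copy()
        C2 = np.stack([np.roll(np.eye(9)[0], int(f / 40)) for f in feats])
        avg = recenter_average(C2, feats)
        assert np.allclose(avg, np.eye(9)[0])

    def test_flat_input_flat_output_and_offgrid_reject(self):
        avg = recenter_average(np.ones((5, 9)), [0, 40, 80, 120, 160])
        assert np.allclose(avg, 1.0)
        with pytest.raises(ValueError, match="off"):
            recenter_average(np.ones((2, 9)), [0.0, 20.0])

    def test_basis_shaped_responses_recentre_to_basis(self):
        b = make_basis()
        rng = np.random.default_rng(4)
        feats = rng.choice(seqwm.RING_VALUES, size=60)
        C2 = b.evaluate(feats).T
        avg = recenter_average(C2, feats)
        assert np.allclose(avg, b.evaluate(0.0), atol=1e-12)

    def test_slope_contracts(self):
        b = make_basis()
        ideal = b.evaluate(0.0)
        s = response_slope(ideal)
        assert s > 0
        assert response_slope(-ideal) == pytest.approx(-s)
        assert response_slope(np.ones(9)) == pytest.approx(0.0, abs=1e-12)
        # independent least-squares oracle on the folded curve
        d = np.array([0, 40, 80, 120, 160], float)
        folded = np.array([ideal[0]] + [(ideal[j] + ideal[9 - j]) / 2
                                        for j in range(1, 5)])
        x = -d / 160.0
        oracle = np.polyfit(x, folded, 1)[0]
        assert s == pytest.approx(oracle)

    def test_rotation_equivariance_of_recentering(self):
        rng = np.random.default_rng(5)
        b = make_basis()
        feats = rng.choice(seqwm.RING_VALUES, size=40)
        C2 = b.evaluate(feats).T + rng.normal(0, 0.1, size=(40, 9))
        avg = recenter_average(C2, feats)
        # rotate features AND channel profiles by one grid step
        C2_rot = np.stack([np.roll(row, 1) for row in C2])
        avg_rot = recenter_average(C2_rot, (feats + 40.0) % 360)
        assert np.allclose(avg, avg_rot)


class TestSmoothing:
    def test_impulse_response_is_gaussian_40ms(self):
        fs = 100.0
        sd = 0.040 * fs
        x = np.zeros(201)
        x[100] = 1.0
        y = gaussian_smooth(x, sd)
        t = np.arange(201) - 100
        ref = np.where(np.abs(t) <= np.ceil(4 * sd),
                       np.exp(-0.5 * (t / sd) ** 2), 0.0)
        ref /= ref.sum()  # kernel truncated at 4 sd, renormalized
        assert np.allclose(y, ref, atol=1e-12)
        # second moment of the impulse response equals (40 ms * fs)^2
        assert np.sqrt(np.sum(y * t**2)) == pytest.approx(sd, rel=1e-3)

    def test_edge_renormalization_preserves_constants(self):
        y = gaussian_smooth(np.ones(50), 4.0)
        assert np.allclose(y, 1.0)


class TestDecodeTimecourse:
    def test_noiseless_activation_window(self, noiseless_epochs):
        epochs, truth = noiseless_epochs
        tc = seqwm.decode_timecourse(epochs, epochs.labels["location"][:, 0])
        active = (tc.times > 0.2) & (tc.times < 0.8)
        late = tc.times > 4.2
        assert np.all(tc.slope[active] > 0.2)
        assert np.allclose(tc.slope[late], 0.0, atol=1e-6)

    def test_permuted_labels_near_zero(self, noiseless_epochs):
        epochs, _ = noiseless_epochs
        rng = np.random.default_rng(6)
        labels = epochs.labels["location"][:, 0].copy()
        rng.shuffle(labels)
        ep_noisy, _ = seqwm.simulate_eeg(
            seqwm.generate_design(n_trials=144, seed=31), snr=1.0, seed=32)
        tc = seqwm.decode_timecourse(ep_noisy, labels[: ep_noisy.n_trials])
        assert abs(tc.slope.mean()) < 0.1

    def test_single_block_rejected(self, designs_small):
        epochs, _ = seqwm.simulate_eeg(designs_small, seed=33)
        epochs.block_ids = np.zeros(epochs.n_trials, dtype=int)
        with pytest.raises(ValueError, match="block"):
            seqwm.decode_timecourse(epochs, epochs.labels["location"][:, 0])

    def test_slope_increases_with_snr(self):
        designs = seqwm.generate_design(n_trials=72, seed=41)
        means = []
        for snr in (0.2, 1.0, 5.0):
            reps = []
            for r in range(10):
                ep, _ = seqwm.simulate_eeg(designs, snr=snr, seed=50 + r,
                                           epoch_duration=1.5,
                                           item_latencies=(0.2,) * 3,
                                           envelope_width=1.0)
                tc = seqwm.decode_timecourse(ep, ep.labels["location"][:, 0])
                reps.append(tc.slope[(tc.times > 0.4) & (tc.times < 1.4)].mean())
            means.append(np.mean(reps))
        assert means[0] < means[1] < means[2]
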