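# seqwm

Analysis toolkit for multi-sequence working-memory EEG experiments, for
researchers studying how relational structure shared between memoranda
(here: a common spatial trajectory linking a location sequence and a
color sequence on their respective rings) shapes behavior and neural
reactivation. The package bundles:

- **Circular behavioral statistics** — response errors, memory precision
  1/σ (σ = sqrt(−2 ln R), the circular SD of report errors), trajectory
  errors per leg, Fisher–Lee within-subject circular correlations, and
  the group-level binned trajectory-error correlation.
- **Time-resolved inverted encoding model (IEM)** — nine half-wave
  rectified cosine⁸ tuning channels f_k(θ) = max(0, cos(θ − φ_k))⁸ at
  φ_k = 0°, 40°, …, 320°; least-squares training Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹,
  inversion Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂ per time sample, leave-one-block-out CV,
  circular recentering, and a fold-and-regress slope score smoothed with
  a 40 ms Gaussian kernel.
- **Sequential-replay detection** — forward-minus-reverse lagged
  cross-correlation asymmetry between item time courses, peak-lag
  estimation, 3×3 transition-matrix similarity against the theoretical
  forward pattern, and a label-shuffle permutation null.
- **Trajectory-distance decoding** — an 8-way (±40°…±160°, chance 1/8)
  linear one-vs-rest SVM with stratified 5-fold × 50-repeat CV, plus
  7-cycle Morlet alpha-power (8–12 Hz) features.
- **Cluster-based permutation inference** — one-sample t maps corrected
  by maximal-cluster-size sign-flip permutation, and a bootstrap
  group-difference test.
- **A seeded forward-model simulator** (`seqwm.synth`) generating task
  designs (9-point ring, aligned/misaligned trajectory conditions),
  von Mises behavioral reports with controllable cross-domain coupling,
  and sensor data with item-locked envelopes and optional planted replay
  — so every stage is testable against known ground truth.

See `docs/methods.md` for the full model descriptions, parameter
defaults, and known limitations.

## Worked example

Simulate a small cohort with coupled aligned-condition reports, then a
subject with planted forward replay at 130 ms during recall:

```python
import numpy as np, seqwm

# behavior: 8 subjects, 648 trials each, AT-only trajectory coupling
at_tables, mat_tables = [], []
for s in range(8):
    designs = seqwm.generate_design(n_trials=648, seed=100 + s)
    reports = seqwm.simulate_behavior(designs, coupling_sd=10.0, seed=200 + s)
    tab = seqwm.trajectory_error_table(designs, reports)
    at_tables.append(tab[tab.condition == "AT"])
    mat_tables.append(tab[tab.condition == "MAT"])
r_at, p_at, pts = seqwm.group_binned_correlation(at_tables, "12", n_bins=4)
r_mat, p_mat, _ = seqwm.group_binned_correlation(mat_tables, "12", n_bins=4)
print(f"group binned correlation, AT : r = {r_at:.3f}, p = {p_at:.2g}")
print(f"group binned correlation, MAT: r = {r_mat:.3f}, p = {p_mat:.2g}")

# replay: decode the three items' recall time courses, estimate the lag
designs = seqwm.generate_design(n_trials=144, seed=7)
epochs, truth = seqwm.simulate_eeg(designs, snr=1.0, envelope_width=0.1,
                                   replay_lag=0.13, seed=9)
slopes = np.array([
    seqwm.decode_timecourse(epochs, epochs.labels["location"][:, pos]).slope
    for pos in range(3)
])
profile = seqwm.direction_asymmetry(slopes, max_lag=0.35, fs=100.0)
peak = seqwm.find_peak_lag(profile)
E = seqwm.empirical_matrix(slopes, lag=peak, fs=100.0)
sim = seqwm.matrix_similarity(E, seqwm.theoretical_matrix(3))
print(f"recovered replay lag: {peak*1000:.0f} ms (planted 130 ms)")
print(f"transition-matrix similarity: r = {sim:.3f}")
```

Output:

```
group binned correlation, AT : r = 0.584, p = 0.00045
group binned correlation, MAT: r = -0.253, p = 0.16
recovered replay lag: 120 ms (planted 130 ms)
transition-matrix similarity: r = 0.947
```

The aligned condition — and only the aligned condition — shows the
planted location–color trajectory-error correlation (32 = 8 subjects × 4
bins pooled points). The single-subject replay estimate lands within one
sample (10 ms) of the planted 130 ms lag, and the empirical lagged-
correlation matrix strongly resembles the theoretical forward-transition
pattern (ones on the super-diagonal); group-level significance against
the item-shuffle permutation null is provided by
`seqwm.replay_permutation_null`.

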