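# Methods

`seqwm` implements the analysis chain for a multi-sequence working-memory
EEG experiment in which three colored disks appear sequentially at ring
positions and both the location sequence and the color sequence must be
reproduced. Every stage is exercisable on a bundled forward-model
simulator with known ground truth, so the statistical machinery can be
calibrated and the recovery of planted effects demonstrated without any
recorded data.

## Task design and the synthetic generator

Locations and colors are drawn from a 9-point ring, 0°–320° in 40° steps,
with per-value jitter of random sign and magnitude uniform in [1°, 3°]
applied after constraint checking on the nominal centers. Constraints:
the three values of each domain are pairwise distinct (hence ≥ 40° apart
at the grid), and an item's color value never equals its location value.
In the aligned-trajectory condition (AT) the color triple is a random
nonzero rigid rotation of the location triple, which enforces equality of
both consecutive signed inter-item distances across domains; in the
misaligned condition (MAT) colors are resampled until the full-trajectory
predicate fails (a single matching leg is allowed). Conditions are
interleaved in random order. The default configuration produces 648
trials (two sessions), assigned to 8 equal recording blocks.

The instruction that each of the nine values "occur equally often" is
arithmetically ambiguous for 648 trials × 3 serial positions; the
generator balances the *first* serial position exactly via shuffled
balanced decks (one per condition) and draws later positions uniformly
under the constraints, which leaves them balanced only in expectation.

**Behavioral reports.** Per-item report errors are independent von Mises
draws (circular analogue of Gaussian noise; concentration
`kappa_location = 8`, `kappa_color = 4` by default, chosen so that
location precision exceeds color precision as real observers show, with
circular SDs of ≈ 21° and ≈ 31°). The closed form
σ = sqrt(−2 ln(I₁(κ)/I₀(κ))) serves as the calibration oracle. When
`coupling_sd > 0` (default 10°), AT trials receive shared leg
perturbations s₁₂, s₂₃ ~ N(0, coupling_sd): s₁₂ is added to both domains'
second-item errors and s₁₂ + s₂₃ to both third-item errors, so the
location and color trajectory errors of consecutive legs share a common
component. MAT trials never receive coupling. Note the coupling *adds*
report noise, so it produces the AT trajectory correlation but not the
AT precision advantage; the generator emulates the correlational
structure, not every behavioral effect.

**Sensor data.** The forward model is exactly the linear model the
inverted encoding model assumes: nine feature-tuned channels with
idealized tuning curves (below), mixed into `n_sensors = 16` sensors by a
random Gaussian weight matrix (full column rank almost surely, checked),
with each item's channel response gated by a raised-cosine (Hann)
envelope. Encoding epochs default to 4.5 s at 100 Hz with item onsets at
0, 1.5, 3.0 s and 1 s envelopes (mirroring 1 s presentations with 0.5 s
gaps); recall epochs default to 1.0 s with the three items reactivating
at onsets 0.1 + i·lag for a configurable replay lag and a 0.1 s envelope.
Additive Gaussian sensor noise is scaled to `RMS(signal)/snr`; the
default snr = 1 is deliberately modest — single-trial EEG decoding
operates far below the noiseless regime, and (see "IEM cross-talk"
below) noiseless data are actually *less* favorable for replay timing.
The simulator returns its ground truth (weight matrix, latencies, channel
responses) for oracle tests. It makes no attempt at volume conduction,
1/f background, eye movements, or artifacts; passing tests demonstrate
correctness of the analysis chain under its own generative assumptions,
not robustness to real-EEG nuisance structure.

## Behavioral statistics

Signed circular differences live in (−180°, 180°]; the antipodal case
maps to +180° by convention (tested). Circular SD is σ = sqrt(−2 ln R)
in radians (R the mean resultant length) and memory precision is 1/σ.
A leg's trajectory error is the wrapped difference of the two item errors
(later minus earlier), so a shared report rotation cancels. Per-subject
location–color trajectory association uses the Fisher–Lee circular
correlation (implemented here; the estimator choice is a documented
convention, with the usual ±1 and rotation-invariance contracts tested).
The group-level procedure sorts each subject's trials by location
trajectory error, splits them into 4 equal-count bins (remainder spread
over leading bins), averages both domains per bin, pools subjects × bins
points, and reports a linear Pearson correlation with a two-sided p —
linear rather than circular because binned mean errors are small-angle
quantities presented as a scatter with a best linear fit.

## Inverted encoding model

Channel tuning curves are half-wave rectified cosines raised to the 8th
power, centered on the nine grid values: f_k(θ) = max(0, cos(θ − φ_k))⁸,
so f_k(φ_k) = 1. Training solves Ŵ = B₁C₁ᵀ(C₁C₁ᵀ)⁻¹ by least squares
(sensors × channels); inversion reconstructs Ĉ₂ = (ŴᵀŴ)⁻¹ŴᵀB₂ per time
sample, implemented with the pseudoinverse (identical at full column
rank, graceful at signal-free samples). Training labels are nominal grid
centers — stimulus jitter is sub-grid and ignored — so recentering each
trial's reconstruction on its own feature is an exact whole-channel
circular shift. Cross-validation is leave-one-block-out on the recording
blocks; recentered reconstructions from all held-out trials are pooled
and averaged. The decoding score is the slope of the folded curve:
offsets ±d are averaged onto d ∈ {0°, 40°, …, 160°} (center included by
default) and the folded response is regressed on proximity −d/160, so a
center-peaked reconstruction scores positive. Slope time courses are
smoothed with a 40 ms (s.d.) Gaussian kernel renormalized over its valid
support at the epoch edges; smoothing follows fold pooling. A config
argument restricts the fit to a named sensor subset (e.g. posterior
electrodes); the default uses all sensors.

**IEM cross-talk.** Because the three features of a trial are mutually
constrained (pairwise distinct), the trained weights at one item's active
time are a structured mixture when decoding another item's label, and the
per-time pseudoinverse amplifies this structure as noise vanishes: each
position's decoded time course shows systematic secondary bumps at the
*other* items' times. Sensor noise implicitly regularizes the inversion
and suppresses the artifact. This is intrinsic to the method on this
design, and it is why the replay-recovery study below is run at the
simulator's default snr = 1 rather than in a near-noiseless regime.

## Replay detection

Forward replay at lag Δt makes item i's decoded time course predict item
i+1's at t + Δt. For pairs 1→2 and 2→3 we compute lagged Pearson
correlations over the overlapping window for lags 0 … 0.5 s (at the
epoch rate), subtract the reverse direction from the forward direction to
cancel autocorrelation, and average the two asymmetry profiles. The
consensus lag is the profile's argmax (ties broken to the smallest lag,
flat profiles flagged). The theoretical forward-transition pattern is the
3×3 super-diagonal indicator; the empirical pattern is the full
9-ordered-pair lagged-correlation matrix at the chosen lag (diagonal
included by default; a flag drops it). Similarity is the Pearson
correlation over cells. Group inference shuffles the item-identity
assignment of decoded time courses independently within each subject
(1000 permutations), recomputes the statistic on the grand average, and
takes the 95th percentile as the threshold; p-values use
(1 + b)/(1 + n_perm). The group statistic operates on grand-average time
courses; per-subject profiles are also available.

## Cluster-based permutation inference

Pointwise one-sample t-tests against a null constant (0 for IEM slopes,
0.125 for classifier accuracy) are corrected by forming clusters of
contiguous suprathreshold samples sharing an effect sign at a
cluster-defining threshold (two-tailed p < 0.05 default; 0.001 is
first-class for encoding-period analyses), scoring clusters by size in
samples (mass = Σ|t| behind a flag), and comparing against the maximal
cluster score under 1000 per-subject sign flips of the deviations from
the null — algebraically identical to exchanging a subject's values with
the null constant. Corrected p-values use (1 + b)/(1 + n_perm). Two
numerical notes, both verified by simulation: (i) on temporally white
null data the size statistic is so discrete that the test is
conservative (FWER ≈ 1% at nominal 5% for 20 × 100 inputs); on data with
the 40 ms autocorrelation that actual slope time courses carry, FWER
calibrates to ≈ 3%, and the bundled calibration study therefore uses
smoothed null time courses. (ii) With very large homogeneous effects the
sign-flip null itself thickens, so corrected p-values saturate rather
than decrease indefinitely. The bootstrap group test resamples both
groups' means (10,000 draws default) and doubles the smaller tail
proportion of the resampled difference about zero.

## Trajectory-distance decoding

The signed circular distance between two distinct grid values is one of
±40°, ±80°, ±120°, ±160° — eight classes, chance 1/8. The decoder is a
standardized linear one-vs-rest SVM (regularization C = 1, a documented
default; accuracy contracts are written against chance and separability,
not a particular margin), scored with stratified 5-fold cross-validation
repeated 50 times with fresh partitions. Stratification prevents
empty-class folds at these trial counts. Retention-period features are
alpha-band (8–12 Hz, 1 Hz steps) power from 7-cycle Morlet wavelets.

## Calibration and recovery studies (`seqwm.studies`)

Problem sizes were chosen to give each check adequate power at desk
scale. Chance calibration: 400 noise trials, class-balanced labels
re-shuffled on each of 50 repeats (the permutation estimate of chance;
a single fixed assignment would carry ~0.016 SD of dataset-level chance
clustering), yielding 0.125 ± 0.002. IEM null: 20 subjects × 200 trials
with within-subject label shuffles; the 95% CI of the grand-mean slope
covers 0. Replay recovery: 100 cohorts of 8 subjects × 90 trials at
snr = 1, planted lags 80/130/200 ms; recovered peak lags match within
one sample (10 ms) and planted-lag matrix similarity exceeds the
1000-permutation threshold in well over the required fractions. Cluster
FWER: 200 null replicates as above. Behavioral coupling: 100 replicates
of 8 subjects × 648 trials; AT binned correlation exceeds MAT in ≈ 100%
of coupled replicates, and with zero coupling the group correlation is
null-distributed.

## Known limitations

- The forward model shares its linear-mixture assumption with the IEM, so
  IEM recovery on this simulator is a best case by construction.
- The behavioral coupling model produces trajectory-error correlation at
  the cost of item precision; it does not reproduce the AT precision
  benefit.
- Replay-lag estimation inherits the cross-talk bias described above;
  at very high SNR the recovered lag can be systematically off by one to
  two samples at long lags.
- Cluster correction here is temporal only (no sensor adjacency, no
  TFCE), and the replay machinery is lagged-correlation-based (no TDLM
  sequenceness or HMM state models).
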