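"""Synthetic task designs, behavioral reports, and forward-model sensor data.

The generators emulate a multi-sequence working-memory experiment in which
three colored disks appear sequentially at ring positions. Both the three
locations and the three colors are drawn from a 9-point ring (0-320 deg in
40-deg steps, small +/-1-3 deg jitter). In the aligned-trajectory (AT)
condition the color sequence is a rigid rotation of the location sequence,
so consecutive inter-item distances match across domains; in the misaligned
(MAT) condition the full trajectory differs (a single leg may still
coincide). Sensor data follow the same linear forward model the inverted
encoding model assumes: idealized tuning-channel responses, mixed into
sensors by a ground-truth weight matrix, with item-locked temporal
envelopes and additive Gaussian noise. Everything is seeded and returns its
ground truth so downstream stages can be tested against known answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circstats import circ_diff
from .core import EpochSet, N_CHANNELS, RING_STEP, RING_VALUES

__all__ = [
    "TrialDesign",
    "BehavioralReport",
    "GroundTruth",
    "generate_design",
    "verify_designs",
    "simulate_behavior",
    "simulate_eeg",
    "PAPER_N_TRIALS",
]

PAPER_N_TRIALS = 648  # two-session default of the emulated design


@dataclass
class TrialDesign:
    """One trial: condition, jittered feature values, and nominal centers."""

    condition: str  # "AT" or "MAT"
    locations: np.ndarray  # (3,) jittered degrees
    colors: np.ndarray  # (3,) jittered degrees
    nominal_locations: np.ndarray  # (3,) on the 40-deg grid
    nominal_colors: np.ndarray  # (3,) on the 40-deg grid
    block_id: int = 0

    def __post_init__(self):
        if self.condition not in ("AT", "MAT"):
            raise ValueError("condition must be 'AT' or 'MAT'")
        for name in ("locations", "colors", "nominal_locations", "nominal_colors"):
            v = np.asarray(getattr(self, name), dtype=float) % 360.0
            if v.shape != (3,):
                raise ValueError(f"{name} must hold 3 ring values")
            setattr(self, name, v)


@dataclass
class BehavioralReport:
    """Reported locations and colors (degrees) for one trial."""

    reported_locations: np.ndarray
    reported_colors: np.ndarray

    def __post_init__(self):
        self.reported_locations = np.asarray(self.reported_locations, float) % 360.0
        self.reported_colors = np.asarray(self.reported_colors, float) % 360.0


@dataclass
class GroundTruth:
    """Simulation ground truth returned alongside an EpochSet."""

    weight_matrix: np.ndarray  # (n_sensors, n_channels)
    item_latencies: np.ndarray  # (3,) seconds (item onsets actually used)
    replay_lag: float | None
    snr: float
    seed: int
    channel_responses: np.ndarray | None = None  # (trials, channels, times)
    domain: str = "location"


def _is_aligned(locs, cols) -> bool:
    """Full-trajectory predicate: both consecutive legs match across domains."""
    d12 = circ_diff(locs[1], locs[0]) == circ_diff(cols[1], cols[0])
    d23 = circ_diff(locs[2], locs[1]) == circ_diff(cols[2], cols[1])
    return bool(d12 and d23)


def _sample_triple(rng, first=None):
    """Three pairwise-distinct grid values; optional fixed first value."""
    if first is None:
        first = rng.choice(RING_VALUES)
    rest = RING_VALUES[RING_VALUES != first]
    pick = rng.choice(rest.size, size=2, replace=False)
    return np.array([first, rest[pick[0]], rest[pick[1]]])


def generate_design(
    n_trials: int = PAPER_N_TRIALS,
    at_fraction: float = 0.5,
    jitter_range: tuple = (1.0, 3.0),
    seed: int = 0,
    n_blocks: int = 8,
) -> list:
    """Generate trial designs for the 9-point ring task.

    AT trials set the color sequence to a random nonzero rigid rotation of
    the location sequence (which enforces matching consecutive trajectory
    distances and color != location at every serial position). MAT trials
    resample colors until the full-trajectory predicate fails. Jitter of
    uniformly random magnitude within ``jitter_range`` and random sign is
    added to every value after constraint checking on the nominal centers.
    Conditions are interleaved in random order; first-position values are
    drawn from shuffled balanced decks per condition so each nominal value
    occurs approximately equally often.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= at_fraction <= 1.0:
        raise ValueError("at_fraction must lie in [0, 1]")
    lo, hi = float(jitter_range[0]), float(jitter_range[1])
    if not (0.0 <= lo <= hi < 20.0):
        raise ValueError(
            "infeasible jitter range: need 0 <= lo <= hi < 20 deg so that "
            "jittered values cannot collide across the 40-deg grid spacing"
        )
    if n_blocks < 1 or n_blocks > n_trials:
        raise ValueError("n_blocks must lie in [1, n_trials]")

    rng = np.random.default_rng(seed)
    n_at = int(round(n_trials * at_fraction))
    conditions = np.array(["AT"] * n_at + ["MAT"] * (n_trials - n_at))
    rng.shuffle(conditions)

    # balanced first-position decks, one per condition x domain
    def deck(n):
        reps = int(np.ceil(n / RING_VALUES.size))
        d = np.tile(RING_VALUES, reps)[:n]
        rng.shuffle(d)
        return list(d)

    loc_decks = {"AT": deck(n_at), "MAT": deck(n_trials - n_at)}

    designs = []
    block_size = int(np.ceil(n_trials / n_blocks))
    for i, cond in enumerate(conditions):
        locs = _sample_triple(rng, first=loc_decks[cond].pop())
        if cond == "AT":
            step = rng.integers(1, 9)  # nonzero rotation in grid steps
            cols = (locs + step * RING_STEP) % 360.0
        else:
            while True:
                cols = _sample_triple(rng)
                if np.any(cols == locs):  # same-position color==location ban
                    continue
                if not _is_aligned(locs, cols):
                    break
        jit = lambda: rng.uniform(lo, hi, size=3) * rng.choice([-1.0, 1.0], size=3)
        designs.append(
            TrialDesign(
                condition=str(cond),
                locations=(locs + jit()) % 360.0,
                colors=(cols + jit()) % 360.0,
                nominal_locations=locs,
                nominal_colors=cols,
                block_id=i // block_size,
            )
        )
    return designs


def verify_designs(designs) -> dict:
    """Count constraint violations over a list of designs (all should be 0).

    Checks: pairwise distinctness (>= 40 deg at nominal grid) within each
    domain, color != location at every serial position, the AT
    full-trajectory equality, and the MAT full-trajectory inequality.
    """
    counts = dict(distinctness=0, spacing=0, color_eq_location=0,
                  at_predicate=0, mat_predicate=0)
    for d in designs:
        for vals in (d.nominal_locations, d.nominal_colors):
            if len(set(vals.tolist())) != 3:
                counts["distinctness"] += 1
            sep = [abs(circ_diff(vals[i], vals[j]))
                   for i in range(3) for j in range(i + 1, 3)]
            if min(sep) < RING_STEP:
                counts["spacing"] += 1
        if np.any(d.nominal_locations == d.nominal_colors):
            counts["color_eq_location"] += 1
        aligned = _is_aligned(d.nominal_locations, d.nominal_colors)
        if d.condition == "AT" and not aligned:
            counts["at_predicate"] += 1
        if d.condition == "MAT" and aligned:
            counts["mat_predicate"] += 1
    counts["total"] = sum(counts.values())
    return counts


def simulate_behavior(
    designs,
    kappa_location: float = 8.0,
    kappa_color: float = 4.0,
    coupling_sd: float = 10.0,
    seed: int = 0,
) -> list:
    """Simulate behavioral reports with von Mises errors and AT coupling.

    Per-item report errors are independent von Mises draws (concentration
    kappa per domain). When ``coupling_sd`` > 0, each AT trial additionally
    receives shared leg perturbations s12, s23 ~ N(0, coupling_sd deg):
    s12 is added to both domains' second-item errors and s12 + s23 to both
    third-item errors, so the location and color trajectory errors of
    consecutive legs share a common component. MAT trials never receive
    coupling, mirroring the structure the aligned condition is meant to
    elicit in real reports.
    """
    if kappa_location <= 0 or kappa_color <= 0:
        raise ValueError("concentrations must be positive")
    if coupling_sd < 0:
        raise ValueError("coupling_sd must be >= 0")
    rng = np.random.default_rng(seed)
    reports = []
    for d in designs:
        loc_err = np.rad2deg(rng.vonmises(0.0, kappa_location, size=3))
        col_err = np.rad2deg(rng.vonmises(0.0, kappa_color, size=3))
        if d.condition == "AT" and coupling_sd > 0:
            s12, s23 = rng.normal(0.0, coupling_sd, size=2)
            shared = np.array([0.0, s12, s12 + s23])
            loc_err = loc_err + shared
            col_err = col_err + shared
        reports.append(
            BehavioralReport(
                reported_locations=(d.locations + loc_err) % 360.0,
                reported_colors=(d.colors + col_err) % 360.0,
            )
        )
    return reports


def _raised_cosine(times, onset, width, fs):
    """Hann envelope of the given width starting at onset; bounds-checked."""
    if onset < times[0] - 0.5 / fs or onset + width > times[-1] + 0.5 / fs + 1e-9:
        raise ValueError(
            f"envelope [{onset:.3f}, {onset + width:.3f}] s extends past "
            f"epoch bounds [{times[0]:.3f}, {times[-1]:.3f}] s"
        )
    t = times - onset
    env = np.zeros_like(times)
    inside = (t >= 0) & (t <= width)
    env[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * t[inside] / width))
    return env


def simulate_eeg(
    designs,
    n_sensors: int = 16,
    snr: float = 1.0,
    item_latencies=(0.0, 1.5, 3.0),
    envelope_width: float = 1.0,
    replay_lag: float | None = None,
    seed: int = 0,
    fs: float = 100.0,
    epoch_duration: float | None = None,
    tmin: float = 0.0,
    domain: str = "location",
    replay_onset: float = 0.1,
    basis=None,
):
    """Forward-model sensor data for an encoding or a recall epoch.

    Encoding epoch (``replay_lag=None``, default 4.5 s): each serial
    position's item drives the idealized tuning channels at its nominal
    feature value, gated by a raised-cosine envelope starting at the item's
    latency (defaults mirror 1 s presentations with 0.5 s gaps).

    Recall epoch (``replay_lag`` set, default 1.0 s): the three items
    reactivate sequentially at onsets ``replay_onset + i * replay_lag``
    with the same envelope shape, planting forward replay at a known lag.

    Sensor data = W_true @ channel responses + Gaussian noise with
    sigma = RMS(signal)/snr (``snr=inf`` for noiseless data).

    Returns ``(EpochSet, GroundTruth)``; labels carry the nominal grid
    values for both domains.
    """
    from .iem import make_basis  # local import avoids a cycle

    if n_sensors < N_CHANNELS:
        raise ValueError(f"n_sensors must be >= {N_CHANNELS}")
    if not (snr > 0):
        raise ValueError("snr must be positive (np.inf for noiseless)")
    basis = basis if basis is not None else make_basis()
    if replay_lag is not None:
        duration = 1.0 if epoch_duration is None else epoch_duration
        latencies = replay_onset + replay_lag * np.arange(3)
    else:
        duration = 4.5 if epoch_duration is None else epoch_duration
        latencies = np.asarray(item_latencies, dtype=float)

    n_times = int(round(duration * fs))
    times = tmin + np.arange(n_times) / fs
    envs = np.stack([_raised_cosine(times, lat, envelope_width, fs)
                     for lat in latencies])  # (3, T)

    n = len(designs)
    feats = np.stack([
        d.nominal_locations if domain == "location" else d.nominal_colors
        for d in designs
    ])  # (n, 3)

    rng = np.random.default_rng(seed)
    W = rng.normal(size=(n_sensors, N_CHANNELS)) / np.sqrt(N_CHANNELS)
    if np.linalg.matrix_rank(W) < N_CHANNELS:  # pragma: no cover
        raise RuntimeError("ground-truth weight matrix is rank deficient")

    # channel responses: (n, k, T) = sum over items of tuning x envelope
    tuning = basis.evaluate(feats.ravel()).T.reshape(n, 3, N_CHANNELS)
    C = np.einsum("nik,it->nkt", tuning, envs)
    signal = np.einsum("mk,nkt->nmt", W, C)
    if np.isfinite(snr):
        sigma = signal.std() / snr
        data = signal + rng.normal(scale=sigma, size=signal.shape)
    else:
        data = signal

    epochs = EpochSet(
        data=data,
        fs=fs,
        times=times,
        block_ids=np.array([d.block_id for d in designs]),
        labels={
            "location": np.stack([d.nominal_locations for d in designs]),
            "color": np.stack([d.nominal_colors for d in designs]),
        },
    )
    truth = GroundTruth(
        weight_matrix=W,
        item_latencies=latencies,
        replay_lag=replay_lag,
        snr=snr,
        seed=seed,
        channel_responses=C,
        domain=domain,
    )
    return epochs, truth
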