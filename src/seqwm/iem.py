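"""Time-resolved inverted encoding model (IEM) for ring-valued features.

The IEM treats each sensor's signal as a linear mixture of k idealized
feature-tuned channels. Training estimates the sensor-by-channel weight
matrix W by least squares from trials with known feature values; inversion
applies the pseudoinverse of W to held-out data to reconstruct channel
response profiles. Reconstructed profiles are circularly recentered on each
trial's feature, averaged, folded about the center, and summarized by the
slope of response versus proximity to the center: a center-peaked
reconstruction yields a positive slope, chance yields zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import DecodingTimecourse, EpochSet, N_CHANNELS, RING_STEP, RING_VALUES

__all__ = [
    "BasisSet",
    "make_basis",
    "train_weights",
    "invert_weights",
    "recenter_average",
    "response_slope",
    "gaussian_smooth",
    "decode_timecourse",
]


@dataclass
class BasisSet:
    """Idealized tuning curves: half-wave rectified cosines to a power.

    Channel k responds to feature angle theta as
    ``max(0, cos(theta - center_k)) ** exponent`` with a 360-deg period,
    so the response at a channel's own center is exactly 1.
    """

    centers: np.ndarray
    exponent: int

    def __post_init__(self):
        self.centers = np.asarray(self.centers, dtype=float) % 360.0
        if len(set(self.centers.tolist())) != self.centers.size:
            raise ValueError("basis centers must be distinct")
        if self.exponent < 1:
            raise ValueError("exponent must be >= 1")

    @property
    def n_channels(self) -> int:
        return self.centers.size

    def evaluate(self, theta) -> np.ndarray:
        """Channel responses for angle(s) theta: shape (k,) or (k, n)."""
        th = np.atleast_1d(np.asarray(theta, dtype=float))
        diff = np.deg2rad(th[None, :] - self.centers[:, None])
        resp = np.clip(np.cos(diff), 0.0, None) ** self.exponent
        return resp[:, 0] if np.isscalar(theta) or np.ndim(theta) == 0 else resp


def make_basis(centers=None, exponent: int = 8) -> BasisSet:
    """Default basis: nine channels at 0, 40, ..., 320 deg, eighth power."""
    return BasisSet(RING_VALUES.copy() if centers is None else centers, exponent)


def train_weights(B1: np.ndarray, C1: np.ndarray) -> np.ndarray:
    """Least-squares weight estimate W = B1 C1' (C1 C1')^-1.

    Parameters
    ----------
    B1 : (m sensors, n trials) observed sensor responses
    C1 : (k channels, n trials) predicted channel responses

    The residual B1 - W C1 is orthogonal to the rows of C1 (normal
    equations). Requires n >= k and full-rank C1 C1'.
    """
    B1 = np.asarray(B1, float)
    C1 = np.asarray(C1, float)
    k, n = C1.shape
    if B1.shape[1] != n:
        raise ValueError("B1 and C1 must share the trial axis")
    if n < k:
        raise ValueError(f"need at least as many trials ({n}) as channels ({k})")
    G = C1 @ C1.T
    rank = np.linalg.matrix_rank(G)
    if rank < k:
        raise np.linalg.LinAlgError(
            f"C1 C1' is singular (rank {rank} < {k} channels); "
            "training labels do not span the channel space"
        )
    # W' solves G W' = C1 B1'
    return np.linalg.solve(G, C1 @ B1.T).T


def invert_weights(W: np.ndarray, B2: np.ndarray) -> np.ndarray:
    """Reconstruct channel responses C2 = (W'W)^-1 W' B2.

    ``B2`` may be (m, n) for one time sample or (m, n, T); the
    pseudoinverse is applied per time sample. Requires full column rank W.
    """
    W = np.asarray(W, float)
    B2 = np.asarray(B2, float)
    m, k = W.shape
    if np.linalg.matrix_rank(W) < k:
        raise np.linalg.LinAlgError("weight matrix is rank deficient")
    WtW = W.T @ W
    if B2.ndim == 2:
        return np.linalg.solve(WtW, W.T @ B2)
    if B2.ndim == 3:
        # (T, k, n) batch solve, then back to (k, n, T)
        rhs = np.einsum("mk,mnt->tkn", W, B2)
        C2 = np.linalg.solve(WtW[None, :, :], rhs)
        return np.moveaxis(C2, 0, -1)
    raise ValueError("B2 must be 2-d or 3-d")


def _grid_shifts(features, n_channels: int, tol_deg: float = 5.0) -> np.ndarray:
    step = 360.0 / n_channels
    f = np.asarray(features, float) % 360.0
    steps = f / step
    shifts = np.round(steps).astype(int) % n_channels
    off = np.abs(f - shifts * step)
    off = np.minimum(off, 360.0 - off)
    if np.any(off > tol_deg):
        bad = f[off > tol_deg]
        raise ValueError(
            f"features off the {step:.0f}-deg grid beyond {tol_deg} deg "
            f"jitter snap: {bad[:5]}"
        )
    return shifts


def recenter_average(C2: np.ndarray, trial_features, tol_deg: float = 5.0) -> np.ndarray:
    """Rotate each trial's channel profile so its feature sits at 0 deg; average.

    ``C2`` is (trials, channels) or (trials, channels, times); features must
    lie on the channel grid (within ``tol_deg`` to absorb stimulus jitter)
    so recentering is an exact whole-channel circular shift.
    """
    C2 = np.asarray(C2, float)
    squeeze = C2.ndim == 2
    if squeeze:
        C2 = C2[:, :, None]
    n, k, T = C2.shape
    feats = np.atleast_1d(np.asarray(trial_features, float))
    if feats.size != n:
        raise ValueError("one feature per trial required")
    shifts = _grid_shifts(feats, k, tol_deg)
    out = np.empty_like(C2)
    for i in range(n):
        out[i] = np.roll(C2[i], -shifts[i], axis=0)
    avg = out.mean(axis=0)
    return avg[:, 0] if squeeze else avg


def _fold(centered: np.ndarray):
    """Fold a 0-centered channel profile: offsets +/-d averaged onto d.

    Input (..., k) with odd k ordered by center 0, 360/k, ...; returns
    (distances_deg, folded (..., h+1)).
    """
    k = centered.shape[-1]
    if k % 2 == 0:
        raise ValueError("folding requires an odd channel count")
    h = (k - 1) // 2
    step = 360.0 / k
    parts = [centered[..., :1]]
    for j in range(1, h + 1):
        parts.append(0.5 * (centered[..., j:j + 1] + centered[..., k - j:k - j + 1]))
    folded = np.concatenate(parts, axis=-1)
    return step * np.arange(h + 1), folded


def response_slope(centered: np.ndarray, include_center: bool = True) -> np.ndarray:
    """Slope score of a recentered channel profile.

    Folds offsets +/-d together, then regresses the folded response on a
    proximity axis (negated distance, normalized by the maximum offset) so
    that a center-peaked profile yields a POSITIVE slope. Accepts (..., k)
    and returns the slope per leading index; a flat profile scores 0.
    """
    centered = np.asarray(centered, float)
    d, folded = _fold(centered)
    if not include_center:
        d, folded = d[1:], folded[..., 1:]
    x = -d / d.max()  # proximity axis in [-1, 0]
    xc = x - x.mean()
    return (folded @ xc) / (xc @ xc)


def gaussian_smooth(y: np.ndarray, sd_samples: float, axis: int = -1) -> np.ndarray:
    """Gaussian smoothing with the kernel renormalized over valid support.

    Near the edges the kernel mass falling outside the series is dropped
    and the remaining weights rescaled to sum to 1 (no padding assumption).
    """
    if sd_samples <= 0:
        return np.asarray(y, float)
    y = np.asarray(y, float)
    radius = int(np.ceil(4 * sd_samples))
    t = np.arange(-radius, radius + 1)
    kern = np.exp(-0.5 * (t / sd_samples) ** 2)

    def smooth_1d(v):
        num = np.convolve(v, kern, mode="same")
        den = np.convolve(np.ones_like(v), kern, mode="same")
        return num / den

    return np.apply_along_axis(smooth_1d, axis, y)


def decode_timecourse(
    epochs: EpochSet,
    labels,
    smoothing_sd: float = 0.040,
    basis: BasisSet | None = None,
    sensors=None,
    include_center: bool = True,
) -> DecodingTimecourse:
    """Leave-one-block-out IEM decoding time course for one feature.

    For each held-out block: train W per time sample on the remaining
    blocks (channel responses predicted by the basis at each trial's
    label), invert on the held-out trials, and circularly recenter each
    trial's reconstruction on its own label. Recentered profiles from all
    held-out trials are pooled, averaged, scored by :func:`response_slope`
    per time sample, and the slope time course smoothed with a Gaussian
    kernel (``smoothing_sd`` seconds, 40 ms default).

    Parameters
    ----------
    epochs : EpochSet
    labels : (n_trials,) feature value per trial, degrees on the channel grid
    sensors : optional index array or list of sensor names restricting the fit
        (e.g. a posterior subset); default uses all sensors.
    """
    basis = basis if basis is not None else make_basis()
    labels = np.asarray(labels, float)
    if labels.shape != (epochs.n_trials,):
        raise ValueError("one label per trial required")
    X = epochs.data
    if sensors is not None:
        if epochs.sensor_names is not None and len(sensors) and isinstance(
            sensors[0], str
        ):
            idx = [epochs.sensor_names.index(s) for s in sensors]
        else:
            idx = list(sensors)
        X = X[:, idx, :]
    blocks = np.unique(epochs.block_ids)
    if blocks.size < 2:
        raise ValueError("leave-one-block-out CV requires >= 2 blocks")
    k = basis.n_channels
    C_all = basis.evaluate(labels)  # (k, n)
    for b in blocks:
        for lab in np.unique(labels):
            if not np.any(labels[epochs.block_ids == b] == lab):
                warnings.warn(
                    f"block {b!r} lacks label {lab:g}; folds may be unbalanced",
                    stacklevel=2,
                )
                break

    T = epochs.n_times
    pooled_sum = np.zeros((k, T))
    n_pooled = 0
    for b in blocks:
        test = epochs.block_ids == b
        train = ~test
        C1 = C_all[:, train]
        n_tr = int(train.sum())
        if n_tr < k:
            raise ValueError(
                f"fold holding out block {b!r} leaves {n_tr} training trials "
                f"for {k} channels"
            )
        G = C1 @ C1.T
        if np.linalg.matrix_rank(G) < k:
            # a fold whose training labels miss a grid value leaves one
            # channel unconstrained; fall back to the minimum-norm solution
            warnings.warn(
                f"training labels in fold holding out block {b!r} do not "
                "span all channels; using pseudoinverse weights",
                stacklevel=2,
            )
            A = (np.linalg.pinv(G) @ C1).T
        else:
            A = np.linalg.solve(G, C1).T  # (n_tr, k): C1'(C1 C1')^-1
        # W per time: (T, m, k)
        W_t = np.einsum("mnt,nk->tmk", X[train].transpose(1, 0, 2), A)
        # pseudoinverse per time sample: equals (W'W)^-1 W' for full column
        # rank, and degrades gracefully at signal-free samples where the
        # trained weights are rank deficient (reconstruction -> 0)
        W_pinv = np.linalg.pinv(W_t)
        C2 = np.einsum("tkm,mnt->tkn", W_pinv, X[test].transpose(1, 0, 2))
        shifts = _grid_shifts(labels[test], k)
        for j, s in enumerate(shifts):
            pooled_sum += np.roll(C2[:, :, j].T, -s, axis=0)
        n_pooled += int(test.sum())

    mean_resp = pooled_sum / n_pooled  # (k, T)
    slope = response_slope(mean_resp.T, include_center=include_center)
    slope = gaussian_smooth(slope, smoothing_sd * epochs.fs)
    return DecodingTimecourse(
        times=epochs.times,
        slope=slope,
        metadata=dict(
            scheme="leave-one-block-out",
            n_blocks=int(blocks.size),
            smoothing_sd=smoothing_sd,
            exponent=basis.exponent,
            include_center=include_center,
            n_sensors=int(X.shape[1]),
        ),
    )
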