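"""Circular (directional) statistics on angles in degrees.

All public functions take angles in degrees on a 360-degree ring. Signed
circular differences live in the half-open interval (-180, 180]; the
boundary case of exactly opposite angles maps to +180 by convention.
Dispersion measures (circular SD) are returned in radians so that their
reciprocal -- the memory-precision measure 1/sigma -- is scale-consistent.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import special

__all__ = [
    "wrap_signed",
    "circ_diff",
    "circular_sd",
    "memory_precision",
    "vonmises_circular_sd",
    "fisher_lee_correlation",
]


def wrap_signed(angles):
    """Wrap angles (degrees) to the interval (-180, 180].

    ``180 - (180 - x) % 360`` maps both +180 and -180 to +180, which fixes
    the otherwise ambiguous antipodal case.
    """
    return 180.0 - (180.0 - np.asarray(angles, dtype=float)) % 360.0


def circ_diff(a, b):
    """Signed circular difference a - b in degrees, wrapped to (-180, 180]."""
    return wrap_signed(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circular_sd(errors_deg) -> float:
    """Circular standard deviation sigma = sqrt(-2 ln R), in radians.

    R is the mean resultant length of the sample of angles. A tightly
    clustered sample has R near 1 and sigma near 0; a sample spread
    uniformly over the ring has R near 0 and a large sigma.

    Parameters
    ----------
    errors_deg : array-like
        At least two finite angles in degrees.
    """
    x = np.asarray(errors_deg, dtype=float)
    if x.size < 2:
        raise ValueError("circular_sd requires at least 2 angles")
    if not np.all(np.isfinite(x)):
        raise ValueError("circular_sd requires finite angles")
    rad = np.deg2rad(x)
    R = np.abs(np.mean(np.exp(1j * rad)))
    # R == 1 exactly (all angles identical) gives sigma = 0
    R = min(R, 1.0)
    if R <= 0.0:
        return np.inf
    return float(np.sqrt(-2.0 * np.log(R)))


def memory_precision(errors_deg, *, cap: float | None = None) -> float:
    """Memory precision 1/sigma, sigma the circular SD of response errors.

    If all errors are identical sigma is 0 and the precision diverges;
    pass ``cap`` to return a flagged finite value instead of raising.
    """
    sigma = circular_sd(errors_deg)
    if sigma == 0.0:
        if cap is None:
            raise ValueError(
                "all errors identical: sigma = 0, precision undefined "
                "(pass cap= to return a capped value)"
            )
        warnings.warn("sigma = 0; returning capped precision", stacklevel=2)
        return float(cap)
    return 1.0 / sigma


def vonmises_circular_sd(kappa: float) -> float:
    """Closed-form circular SD (radians) of a von Mises distribution.

    For concentration kappa the mean resultant length is
    R = I1(kappa)/I0(kappa), hence sigma = sqrt(-2 ln(I1/I0)).
    Used as the independent calibration oracle for the simulator's noise.
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    R = special.i1e(kappa) / special.i0e(kappa)
    return float(np.sqrt(-2.0 * np.log(R)))


def fisher_lee_correlation(a_deg, b_deg) -> float:
    """Fisher-Lee circular-circular correlation coefficient.

    r = sum_{i<j} sin(a_i - a_j) sin(b_i - b_j)
        / sqrt( sum_{i<j} sin^2(a_i - a_j) * sum_{i<j} sin^2(b_i - b_j) )

    Lies in [-1, 1]; equals +1 when b is a rotation of a and -1 when b is
    a rotation of -a, and is invariant to adding a constant angle to either
    variable. Returns NaN (with a warning) on zero-variance input.
    """
    a = np.deg2rad(np.asarray(a_deg, dtype=float))
    b = np.deg2rad(np.asarray(b_deg, dtype=float))
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("inputs must be paired 1-d angle lists")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    sa = np.sin(a[:, None] - a[None, :])
    sb = np.sin(b[:, None] - b[None, :])
    iu = np.triu_indices(a.size, k=1)
    num = float(np.sum(sa[iu] * sb[iu]))
    den = float(np.sqrt(np.sum(sa[iu] ** 2) * np.sum(sb[iu] ** 2)))
    if den == 0.0:
        warnings.warn("degenerate (zero-variance) input; correlation undefined",
                      stacklevel=2)
        return np.nan
    return num / den
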