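"""Circular behavioral statistics for sequence report data.

Response error is the signed circular difference between a reported and a
true ring value. Memory precision is 1/sigma with sigma the circular SD of
response errors (radians). A trajectory error for a leg (1->2, 2->3, 1->3)
is the circular difference between the two item errors spanning that leg:
a shared error common to both items cancels, so trajectory error isolates
how well the *relation* between items was reproduced. Within-subject
association of location and color trajectory errors uses the Fisher-Lee
circular correlation; the group-level procedure bins trials by location
trajectory error, averages both domains per bin, pools subjects x bins
points, and fits a linear correlation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .circstats import (circ_diff, circular_sd, fisher_lee_correlation,
                        memory_precision)

__all__ = [
    "response_errors",
    "error_table",
    "trajectory_error",
    "trajectory_error_table",
    "precision_summary",
    "subject_trajectory_correlation",
    "group_binned_correlation",
]

LEGS = ("12", "23", "13")
_LEG_IDX = {"12": (0, 1), "23": (1, 2), "13": (0, 2)}


def response_errors(reported, true) -> np.ndarray:
    """Signed circular errors (reported - true), wrapped to (-180, 180]."""
    return circ_diff(reported, true)


def error_table(designs, reports) -> pd.DataFrame:
    """Tidy per-trial error table: trial, condition, domain, position, error."""
    if len(designs) != len(reports):
        raise ValueError("designs and reports must be aligned")
    rows = []
    for t, (d, r) in enumerate(zip(designs, reports)):
        for dom, rep, true in (
            ("location", r.reported_locations, d.locations),
            ("color", r.reported_colors, d.colors),
        ):
            err = response_errors(rep, true)
            for pos in range(3):
                rows.append(dict(trial=t, condition=d.condition, domain=dom,
                                 position=pos + 1, error=err[pos]))
    return pd.DataFrame(rows)


def trajectory_error(item_errors, leg: str) -> float:
    """Trajectory error for a leg: later item's error minus earlier's, wrapped.

    ``item_errors`` holds the three serial positions' signed errors. Equal
    item errors (a common report rotation) yield 0.
    """
    if leg not in _LEG_IDX:
        raise ValueError(f"leg must be one of {LEGS}")
    i, j = _LEG_IDX[leg]
    e = np.asarray(item_errors, float)
    return float(circ_diff(e[j], e[i]))


def trajectory_error_table(designs, reports) -> pd.DataFrame:
    """Per-trial trajectory errors for both domains and all three legs."""
    if len(designs) != len(reports):
        raise ValueError("designs and reports must be aligned")
    rows = []
    for t, (d, r) in enumerate(zip(designs, reports)):
        errs = {
            "location": response_errors(r.reported_locations, d.locations),
            "color": response_errors(r.reported_colors, d.colors),
        }
        row = dict(trial=t, condition=d.condition)
        for dom in ("location", "color"):
            for leg in LEGS:
                row[f"{dom}_{leg}"] = trajectory_error(errs[dom], leg)
        rows.append(row)
    return pd.DataFrame(rows)


def precision_summary(designs, reports, by_position: bool = False) -> pd.DataFrame:
    """Memory precision 1/sigma per domain x condition (x serial position)."""
    tab = error_table(designs, reports)
    keys = ["domain", "condition"] + (["position"] if by_position else [])
    rows = []
    for key, grp in tab.groupby(keys):
        rec = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        rec["sigma"] = circular_sd(grp["error"].to_numpy())
        rec["precision"] = 1.0 / rec["sigma"] if rec["sigma"] > 0 else np.inf
        rec["n_trials"] = len(grp)
        rows.append(rec)
    return pd.DataFrame(rows)


def subject_trajectory_correlation(loc_errors, col_errors) -> float:
    """Fisher-Lee circular correlation of paired trajectory errors (degrees)."""
    loc = np.asarray(loc_errors, float)
    col = np.asarray(col_errors, float)
    if loc.size != col.size:
        raise ValueError("paired lists required")
    if loc.size < 8:
        raise ValueError("need at least 8 paired trials")
    return fisher_lee_correlation(loc, col)


def group_binned_correlation(subject_tables, leg: str = "12",
                             n_bins: int = 4):
    """Group-level binned trajectory-error correlation.

    Each element of ``subject_tables`` is a DataFrame with columns
    ``location_<leg>`` and ``color_<leg>`` (one row per trial; see
    :func:`trajectory_error_table`). Per subject, trials are sorted by
    location trajectory error and split into ``n_bins`` equal-count bins
    (any remainder spread over the leading bins); per-bin means of both
    domains are pooled across subjects and a linear (Pearson) correlation
    with a two-sided p-value is returned, along with the pooled points.

    Subjects with fewer than ``n_bins`` trials are excluded with a warning.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    loc_col = f"location_{leg}"
    col_col = f"color_{leg}"
    xs, ys = [], []
    for s, tab in enumerate(subject_tables):
        if len(tab) < n_bins:
            warnings.warn(f"subject {s} has {len(tab)} < {n_bins} trials; "
                          "excluded", stacklevel=2)
            continue
        loc = tab[loc_col].to_numpy()
        col = tab[col_col].to_numpy()
        order = np.argsort(loc, kind="stable")
        # equal-count bins; remainder goes to the leading bins
        sizes = np.full(n_bins, len(loc) // n_bins)
        sizes[: len(loc) % n_bins] += 1
        start = 0
        for sz in sizes:
            idx = order[start:start + sz]
            xs.append(loc[idx].mean())
            ys.append(col[idx].mean())
            start += sz
    if len(xs) < 3:
        raise ValueError("too few pooled points for a correlation")
    x = np.array(xs)
    y = np.array(ys)
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), np.column_stack([x, y])
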