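"""Diel (24-hour) variation of stem CO2 efflux.

Each tree's EA series is z-scored to remove between-tree level and scale
differences, then regressed on a periodic harmonic basis of hour-of-day,

    ea_norm(h) = sum_k a_k sin(2 pi k h / 24) + b_k cos(2 pi k h / 24),

fit per tree by least squares (K = 2 harmonics by default).  The per-tree
predicted curve is evaluated at each integer hour and a one-sample Wilcoxon
signed-rank test across trees asks, per hour, whether the cohort departs
from the daily mean (0 on the normalized scale).  Hours with no significant
departure form the recommended measurement window: a single reading taken
then is representative of the tree's daily mean flux.

Harmonic regression is a deliberate, fully specified approximation of
penalized cyclic-spline smoothing: the inferential target (a smooth periodic
hour effect per tree) is the same, and testing at the tree level (one
predicted value per tree per hour) sidesteps within-series autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

PERIOD_H = 24.0


def normalize_per_tree(obs: pd.DataFrame, ea_col: str = "ea",
                       group_col: str = "tree_tag") -> pd.DataFrame:
    """Add an ``ea_norm`` column: per-tree z-score (mean 0, sample SD 1)."""
    out = obs.copy()

    def _z(x: pd.Series) -> pd.Series:
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(
                f"constant EA series for a tree (sd = 0); cannot normalize")
        return (x - x.mean()) / sd

    out["ea_norm"] = out.groupby(group_col)[ea_col].transform(_z)
    return out


def harmonic_design(hour: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Design matrix of sin/cos pairs at harmonics 1..K of the diel period."""
    hour = np.asarray(hour, dtype=float)
    cols = []
    for k in range(1, n_harmonics + 1):
        w = 2.0 * np.pi * k * hour / PERIOD_H
        cols.extend([np.sin(w), np.cos(w)])
    return np.column_stack(cols)


@dataclass
class CyclicFit:
    """Per-tree harmonic fits and their hourly predictions.

    hourly_pred : DataFrame, index hour 0..23, one column per tree.
    pooled : Series, mean prediction across trees per hour.
    """

    n_harmonics: int
    coefficients: dict[str, np.ndarray]
    hourly_pred: pd.DataFrame
    pooled: pd.Series


def fit_cyclic_model(obs: pd.DataFrame, n_harmonics: int = 2,
                     per_tree: bool = True,
                     group_col: str = "tree_tag") -> CyclicFit:
    """Least-squares harmonic regression of ``ea_norm`` on hour-of-day.

    With ``per_tree=True`` (default) each tree gets its own coefficients —
    the analogue of a tree-specific smooth; otherwise one pooled curve is
    fit to all observations.  The basis has no intercept: the data are
    zero-mean by construction and the harmonics integrate to zero over a
    full cycle, so predictions are daily departures.
    """
    if "ea_norm" not in obs.columns:
        raise ValueError("run normalize_per_tree first (ea_norm missing)")
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    hours_grid = np.arange(24.0)
    grid_design = harmonic_design(hours_grid, n_harmonics)
    coefs: dict[str, np.ndarray] = {}
    preds: dict[str, np.ndarray] = {}
    groups = obs.groupby(group_col) if per_tree else [("pooled", obs)]
    for tag, grp in groups:
        x = harmonic_design(grp["hour"].to_numpy(float), n_harmonics)
        y = grp["ea_norm"].to_numpy(float)
        if np.linalg.matrix_rank(x) < x.shape[1]:
            raise ValueError(
                f"rank-deficient harmonic design for {tag!r}: "
                f"{len(grp)} observations cannot support {n_harmonics} harmonics")
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        coefs[str(tag)] = beta
        preds[str(tag)] = grid_design @ beta
    hourly = pd.DataFrame(preds, index=pd.Index(hours_grid.astype(int), name="hour"))
    return CyclicFit(n_harmonics=n_harmonics, coefficients=coefs,
                     hourly_pred=hourly, pooled=hourly.mean(axis=1))


def hourly_departure_test(fit: CyclicFit, alpha: float = 0.05,
                          correction: str | None = None) -> pd.DataFrame:
    """Wilcoxon signed-rank test of per-tree hourly predictions against 0.

    Returns a 24-row table (hour, median_pred, p_value, significant).  With
    fewer than 5 trees the test is underpowered and a warning is issued.
    ``correction="holm"`` applies a Holm step-down across the 24 hours
    (off by default).
    """
    n_trees = fit.hourly_pred.shape[1]
    if n_trees < 5:
        warnings.warn(f"only {n_trees} trees: signed-rank test is underpowered",
                      stacklevel=2)
    rows = []
    for hour in fit.hourly_pred.index:
        vals = fit.hourly_pred.loc[hour].to_numpy(float)
        if np.allclose(vals, 0.0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(vals).pvalue)
        rows.append({"hour": int(hour), "median_pred": float(np.median(vals)),
                     "p_value": p})
    out = pd.DataFrame(rows)
    if correction == "holm":
        out["p_value"] = multipletests(out["p_value"], method="holm")[1]
    elif correction is not None:
        raise ValueError(f"unknown correction {correction!r}")
    out["significant"] = out["p_value"] < alpha
    return out


def recommend_window(tests: pd.DataFrame) -> list[tuple[int, int]]:
    """Contiguous windows of hours whose cohort flux matches the daily mean.

    Takes the table from :func:`hourly_departure_test` (24 rows) and returns
    the non-significant hours merged into (start, end) inclusive windows,
    wrapping across midnight, ordered by start hour.  An empty list means no
    hour is representative; [(0, 23)] means any hour is.
    """
    if len(tests) != 24:
        raise ValueError("expected one test per hour (24 rows)")
    good = sorted(tests.loc[~tests["significant"], "hour"].astype(int))
    if not good:
        return []
    if len(good) == 24:
        return [(0, 23)]
    good_set = set(good)
    windows = []
    for h in good:
        if (h - 1) % 24 in good_set:
            continue  # not a window start
        end = h
        while (end + 1) % 24 in good_set:
            end = (end + 1) % 24
        windows.append((h, end))
    return sorted(windows)


def window_hours(windows: Sequence[tuple[int, int]]) -> set[int]:
    """Expand (start, end) inclusive wrap-around windows to a set of hours."""
    hours: set[int] = set()
    for start, end in windows:
        h = start
        hours.add(h)
        while h != end:
            h = (h + 1) % 24
            hours.add(h)
    return hours


def analyze_diel(obs: pd.DataFrame, n_harmonics: int = 2, alpha: float = 0.05,
                 correction: str | None = None):
    """Normalize, fit, test and recommend in one call.

    ``obs`` columns: tree_tag, hour (or datetime, from which hour is taken)
    and ea.  Returns (CyclicFit, tests DataFrame, windows list).
    """
    obs = obs.copy()
    if "hour" not in obs.columns:
        dt = pd.to_datetime(obs["datetime"])
        obs["hour"] = dt.dt.hour + dt.dt.minute / 60.0
    obs = normalize_per_tree(obs)
    fit = fit_cyclic_model(obs, n_harmonics=n_harmonics, per_tree=True)
    tests = hourly_departure_test(fit, alpha=alpha, correction=correction)
    return fit, tests, recommend_window(tests)
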