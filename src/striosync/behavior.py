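"""Behavioral metrics and learning-stage identification.

Reaction time is the latency from judgment-zone entry to arrival at the
reward port; the judgment point is the earliest normalized distance at which
left- and right-choice trajectories differ under the permutation-band test;
learning stages (early/middle/late) are found by Ward hierarchical
clustering of (success rate, reaction time) over consecutive session sets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.ndimage import gaussian_filter1d

from .resampling import CurveFamily, band_permutation_test, first_divergence

N_BINS = 50  #: normalized-distance grid: 50 half-open bins on [0, 1]
STAGES = ("early", "middle", "late")


def distance_bin_centers(n_bins: int = N_BINS) -> np.ndarray:
    return (np.arange(n_bins) + 0.5) / n_bins


def distance_bin_index(d, n_bins: int = N_BINS) -> np.ndarray:
    """Bin of a normalized distance; bins [i/n, (i+1)/n), last bin closed."""
    idx = np.floor(np.asarray(d, float) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def trial_metrics(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-trial reaction time; rows with missing timestamps are dropped.

    ``reaction_time = t_choice - t_entry``.
    """
    required = ["t_entry", "t_choice"]
    missing = trials[required].isna().any(axis=1)
    if missing.any():
        warnings.warn(f"excluding {int(missing.sum())} trial(s) with missing "
                      "timestamps", stacklevel=2)
    out = trials.loc[~missing].copy()
    out["reaction_time"] = out["t_choice"] - out["t_entry"]
    return out


def success_rate(trials: pd.DataFrame) -> float:
    return float(np.mean(trials["correct"].astype(bool)))


def session_metrics(trials: pd.DataFrame) -> dict:
    """Session-level summary: success rate, mean/median reaction time."""
    per_trial = trial_metrics(trials)
    rt = per_trial["reaction_time"].to_numpy()
    return {
        "n_trials": len(per_trial),
        "success_rate": success_rate(per_trial),
        "reaction_time_mean": float(np.mean(rt)),
        "reaction_time_median": float(np.median(rt)),
    }


def running_speed(t, x, y, sigma: float = 2.0):
    """Instantaneous running speed, Gaussian-smoothed.

    Speed is per-step travel distance over the time step, assigned to the
    midpoint time of each step, then smoothed with a Gaussian kernel of
    ``sigma`` samples (``sigma=0`` returns the raw finite difference).
    """
    t = np.asarray(t, float)
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if t.size < 3:
        raise ValueError("need at least 3 tracking samples")
    dt = np.diff(t)
    if (dt <= 0).any():
        raise ValueError("timestamps must be strictly increasing")
    step = np.hypot(np.diff(x), np.diff(y))
    speed = step / dt
    if sigma > 0:
        speed = gaussian_filter1d(speed, sigma, mode="nearest")
    return (t[:-1] + t[1:]) / 2.0, speed


def track_speed(tracking: pd.DataFrame, sigma: float = 2.0,
                max_gap: float | None = None):
    """Speed over a whole tracking table, splitting at acquisition gaps.

    Returns (t_mid, speed) concatenated over contiguous blocks; smoothing
    never crosses a gap larger than ``max_gap`` (default 3x the median dt).
    """
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    y = tracking["y"].to_numpy()
    dt = np.diff(t)
    if max_gap is None:
        max_gap = 3.0 * float(np.median(dt))
    breaks = np.flatnonzero(dt > max_gap) + 1
    ts, vs = [], []
    for block in np.split(np.arange(t.size), breaks):
        if block.size < 3:
            continue
        tm, v = running_speed(t[block], x[block], y[block], sigma=sigma)
        ts.append(tm)
        vs.append(v)
    if not ts:
        raise ValueError("no tracking block long enough for speed estimation")
    return np.concatenate(ts), np.concatenate(vs)


def trajectory_family(trials: pd.DataFrame, tracking: pd.DataFrame,
                      zone_length: float, n_bins: int = N_BINS,
                      label_col: str = "choice") -> CurveFamily:
    """Per-trial lateral-position curves on the normalized-distance grid.

    Each trial's judgment-zone samples are interpolated onto bin centers;
    the condition label defaults to the chosen arm.
    """
    centers = distance_bin_centers(n_bins)
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    y = tracking["y"].to_numpy()
    curves, labels = [], []
    for row in trials.itertuples():
        sel = (t >= row.t_entry) & (t < row.t_exit)
        if sel.sum() < 2:
            continue
        d = np.clip(x[sel] / zone_length, 0.0, 1.0)
        d = np.maximum.accumulate(d)  # guard against tracking jitter
        curves.append(np.interp(centers, d, y[sel]))
        labels.append(getattr(row, label_col))
    return CurveFamily(np.array(curves), np.array(labels), positions=centers)


def judgment_metrics(trials: pd.DataFrame, tracking: pd.DataFrame,
                     zone_length: float, n_bins: int = N_BINS,
                     n_perm: int = 5000, alpha: float = 0.05,
                     run_length: int = 3, seed=None):
    """Judgment distance and judgment time of one session.

    The judgment distance is the first normalized distance at which left-
    and right-choice lateral trajectories diverge under the globally
    corrected permutation band; the judgment time is the median latency from
    zone entry to the first crossing of that distance.  Both are ``None``
    when no divergence is found.
    """
    family = trajectory_family(trials, tracking, zone_length, n_bins)
    result = band_permutation_test(family, n_perm=n_perm, alpha=alpha,
                                   seed=seed)
    d_star = first_divergence(result, run_length=run_length)
    if d_star is None:
        return None, None, result
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    latencies = []
    for row in trials.itertuples():
        sel = (t >= row.t_entry) & (t < row.t_exit)
        if sel.sum() < 2:
            continue
        d = np.maximum.accumulate(np.clip(x[sel] / zone_length, 0.0, 1.0))
        if d[-1] < d_star:
            continue
        latencies.append(float(np.interp(d_star, d, t[sel]) - row.t_entry))
    judgment_time = float(np.median(latencies)) if latencies else None
    return d_star, judgment_time, result


def session_sets(metrics: pd.DataFrame, size: int = 3,
                 sliding: bool = False) -> pd.DataFrame:
    """Aggregate per-session metrics over consecutive session sets.

    Disjoint triplets by default; ``sliding=True`` uses every window.
    Sessions must be ordered; incomplete trailing sets are dropped.
    """
    n = len(metrics)
    starts = range(0, n - size + 1) if sliding else range(0, n - size + 1, size)
    rows = []
    for s in starts:
        chunk = metrics.iloc[s:s + size]
        rows.append({
            "set_id": len(rows),
            "first_session": int(chunk.index[0]),
            "success_rate": float(chunk["success_rate"].mean()),
            "reaction_time": float(chunk["reaction_time_median"].mean()),
        })
    return pd.DataFrame(rows)


def cluster_stages(features: pd.DataFrame, k: int = 3,
                   standardize: bool = True) -> pd.DataFrame:
    """Ward clustering of session-set features into ordered learning stages.

    Features (success rate, reaction time) are z-scored by default (they are
    incommensurate), clustered with Ward linkage on Euclidean distance, and
    the tree is cut at ``k``.  Clusters are ordered into stages by
    *behavior*, descending mean reaction time: early = slowest, late =
    fastest (dendrogram leaf order is arbitrary).
    """
    cols = ["success_rate", "reaction_time"]
    X = features[cols].to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(X) < k:
        raise ValueError(f"need >= {k} session sets, got {len(X)}")
    Z = X.copy()
    if standardize:
        sd = Z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0)) / sd
    labels = fcluster(linkage(Z, method="ward"), t=k, criterion="maxclust")
    order = (
        pd.DataFrame({"cluster": labels, "rt": X[:, 1]})
        .groupby("cluster")["rt"].mean().sort_values(ascending=False)
    )
    if k == 3:
        names = dict(zip(order.index, STAGES))
    else:
        names = {c: f"stage_{i}" for i, c in enumerate(order.index)}
    out = features.copy()
    out["cluster"] = labels
    out["stage"] = [names[c] for c in labels]
    return out


def sample_skewness(values) -> float:
    """Moment skewness g1 = m3 / m2^(3/2) (no bias correction)."""
    values = np.asarray(values, float)
    if values.size < 3:
        raise ValueError("need n >= 3")
    if np.var(values) == 0:
        raise ValueError("skewness undefined for zero-variance sample")
    return float(stats.skew(values, bias=True))


def skewness_test(values):
    """D'Agostino's skewness test: (statistic, two-sided p)."""
    stat, p = stats.skewtest(np.asarray(values, float))
    return float(stat), float(p)
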