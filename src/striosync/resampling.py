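"""Permutation-band inference for families of curves.

The core inferential engine of the pipeline: given per-trial curves on a
common position grid and a two-level condition label (left/right choice,
Stim 1/Stim 2, early/late stage), test where the two condition means differ.

The test permutes condition labels over trials, recomputes the difference of
means each time, and derives

* a **pointwise band**: per-position empirical (alpha/2, 1 - alpha/2)
  quantiles of the null differences, and
* a **global band**: the pointwise band re-computed at the largest level
  ``alpha' <= alpha`` such that no more than a fraction ``alpha`` of null
  datasets exits that band *anywhere* — a familywise correction obtained by
  widening the band rather than adjusting p-values.

Conventions chosen for exactness under exchangeability:

* the observed (identity) assignment is a member of the null set, so
  pointwise p-values are rational counts ``2k/N`` and never 0;
* ties between null differences are counted into both tails, which can only
  widen bands (conservative);
* significance is declared at ``p <= alpha`` (the exact-level convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

DEFAULT_N_PERM = 5000
DEFAULT_ALPHA = 0.05
EXHAUSTIVE_LIMIT = 10**6


@dataclass
class CurveFamily:
    """Trials x positions matrix with a two-level condition label per trial."""

    curves: np.ndarray
    labels: np.ndarray
    positions: np.ndarray | None = None

    def __post_init__(self):
        self.curves = np.asarray(self.curves, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.curves.ndim != 2:
            raise ValueError("curves must be a 2-D (trials x positions) array")
        if self.labels.shape[0] != self.curves.shape[0]:
            raise ValueError("one label per trial required")
        if self.positions is None:
            self.positions = np.arange(self.curves.shape[1], dtype=float)
        else:
            self.positions = np.asarray(self.positions, dtype=float)
        if not np.all(np.isfinite(self.curves)):
            raise ValueError("curves contain non-finite values")

    @property
    def levels(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class BandPermResult:
    positions: np.ndarray
    observed_diff: np.ndarray
    pointwise_band: np.ndarray  # (2, P): low, high
    global_band: np.ndarray  # (2, P)
    pointwise_p: np.ndarray
    pointwise_sig: np.ndarray
    global_sig: np.ndarray
    n_perm: int
    alpha: float
    global_alpha_achieved: float
    levels: tuple = ("A", "B")

    def to_frame(self) -> pd.DataFrame:
        """Tabular export (CSV-friendly)."""
        return pd.DataFrame(
            {
                "position": self.positions,
                "observed_diff": self.observed_diff,
                "pointwise_low": self.pointwise_band[0],
                "pointwise_high": self.pointwise_band[1],
                "global_low": self.global_band[0],
                "global_high": self.global_band[1],
                "pointwise_p": self.pointwise_p,
                "pointwise_sig": self.pointwise_sig,
                "global_sig": self.global_sig,
            }
        )


def _check_family(family: CurveFamily):
    levels = family.levels
    if levels.size != 2:
        raise ValueError(f"exactly two label levels required, got {levels.size}")
    idx_a = np.flatnonzero(family.labels == levels[0])
    idx_b = np.flatnonzero(family.labels == levels[1])
    if idx_a.size < 2 or idx_b.size < 2:
        raise ValueError("each level needs >= 2 trials")
    return levels, idx_a, idx_b


def _null_diffs_from_masks(curves: np.ndarray, masks: np.ndarray,
                           n_a: int) -> np.ndarray:
    """Mean(level A) - mean(level B) for every boolean assignment row."""
    n = curves.shape[0]
    n_b = n - n_a
    sums_a = masks.astype(float) @ curves
    total = curves.sum(axis=0, keepdims=True)
    return sums_a / n_a - (total - sums_a) / n_b


def exhaustive_null(family: CurveFamily) -> np.ndarray:
    """Difference-of-means under *every* label assignment (identity first).

    Enumeration is over the ``C(n, n_a)`` ways of assigning ``n_a`` trials to
    level A; the Monte-Carlo engine converges to the quantiles of this set as
    ``n_perm`` grows.
    """
    levels, idx_a, idx_b = _check_family(family)
    n = family.curves.shape[0]
    n_a = idx_a.size
    n_assign = comb(n, n_a)
    if n_assign > EXHAUSTIVE_LIMIT:
        raise ValueError(
            f"{n_assign} assignments exceed the exhaustive limit "
            f"({EXHAUSTIVE_LIMIT}); use the Monte-Carlo engine"
        )
    masks = np.zeros((n_assign, n), dtype=bool)
    rows = [tuple(idx_a)]
    rows += [c for c in combinations(range(n), n_a) if c != tuple(idx_a)]
    for i, c in enumerate(rows):
        masks[i, list(c)] = True
    return _null_diffs_from_masks(family.curves, masks, n_a)


def _pointwise_p_matrix(diffs: np.ndarray) -> np.ndarray:
    """Two-sided rank p-value of every null difference within its column.

    Ties are counted into both tails (conservative).  ``p[j, i] = 2 *
    min(#{D <= d}, #{D >= d}) / N`` capped at 1.
    """
    n_set, n_pos = diffs.shape
    p = np.empty_like(diffs)
    for i in range(n_pos):
        col = diffs[:, i]
        order = np.sort(col)
        le = np.searchsorted(order, col, side="right")
        ge = n_set - np.searchsorted(order, col, side="left")
        p[:, i] = np.minimum(le, ge)
    return np.minimum(2.0 * p / n_set, 1.0)


def _band_edges(diffs_sorted: np.ndarray, level: float) -> np.ndarray:
    """Band at pointwise level ``level`` from per-column sorted null diffs.

    A value is outside the band iff its two-sided rank p is <= level; with
    ``cut = floor(level * N / 2)`` the band is [S[cut], S[N-1-cut]] and
    "outside" means strictly beyond these edges.
    """
    n_set = diffs_sorted.shape[0]
    cut = int(np.floor(level * n_set / 2.0))
    cut = min(cut, (n_set - 1) // 2)
    return np.vstack([diffs_sorted[cut], diffs_sorted[n_set - 1 - cut]])


def band_permutation_test(
    family: CurveFamily,
    n_perm: int = DEFAULT_N_PERM,
    alpha: float = DEFAULT_ALPHA,
    seed=None,
    exhaustive: bool = False,
) -> BandPermResult:
    """Two-sided permutation test with pointwise and global bands.

    Parameters
    ----------
    family
        Per-trial curves and two-level labels.
    n_perm
        Number of label permutations (Monte-Carlo mode); the observed
        assignment is added, so the null set has ``n_perm + 1`` members.
    alpha
        Two-sided pointwise level; also the familywise target of the global
        band.  The achieved familywise level is reported in
        ``global_alpha_achieved`` (the discrete grid of attainable levels
        rarely hits ``alpha`` exactly).
    exhaustive
        Enumerate all assignments instead of sampling (small families only).
    """
    levels, idx_a, idx_b = _check_family(family)
    curves = family.curves
    n = curves.shape[0]
    n_a = idx_a.size
    if exhaustive:
        diffs = exhaustive_null(family)
    else:
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = np.random.default_rng(seed)
        masks = np.zeros((n_perm + 1, n), dtype=bool)
        masks[0, idx_a] = True
        for j in range(1, n_perm + 1):
            masks[j, rng.permutation(n)[:n_a]] = True
        diffs = _null_diffs_from_masks(curves, masks, n_a)
    n_set = diffs.shape[0]

    if np.ptp(diffs) == 0.0:
        warnings.warn("all null differences identical (zero variance); "
                      "nothing can be significant", stacklevel=2)

    p_all = _pointwise_p_matrix(diffs)
    p_obs = p_all[0]
    observed = diffs[0]

    # Familywise calibration on the min-p statistic over positions.
    min_p = p_all.min(axis=1)
    candidates = np.unique(min_p)
    candidates = candidates[candidates <= alpha]
    t_star = 0.0
    for t in candidates[::-1]:
        if np.mean(min_p <= t) <= alpha:
            t_star = float(t)
            break
    achieved = float(np.mean(min_p <= t_star)) if t_star > 0 else 0.0

    diffs_sorted = np.sort(diffs, axis=0)
    pointwise_band = _band_edges(diffs_sorted, alpha)
    global_band = _band_edges(diffs_sorted, t_star)

    return BandPermResult(
        positions=family.positions,
        observed_diff=observed,
        pointwise_band=pointwise_band,
        global_band=global_band,
        pointwise_p=p_obs,
        pointwise_sig=p_obs <= alpha,
        global_sig=p_obs <= t_star if t_star > 0 else np.zeros_like(p_obs, bool),
        n_perm=n_set - 1 if not exhaustive else n_set,
        alpha=alpha,
        global_alpha_achieved=achieved,
        levels=tuple(levels),
    )


def first_divergence(result: BandPermResult, run_length: int = 3,
                     which: str = "global"):
    """Earliest position opening a significant run of >= ``run_length`` bins.

    Returns the grid position of the first bin of the run, or ``None`` when
    no such run exists.  ``which`` selects the globally corrected mask
    (default) or the pointwise one.
    """
    sig = result.global_sig if which == "global" else result.pointwise_sig
    sig = np.asarray(sig, bool)
    if run_length < 1:
        raise ValueError("run_length must be >= 1")
    run = 0
    for i, flag in enumerate(sig):
        run = run + 1 if flag else 0
        if run >= run_length:
            return float(result.positions[i - run_length + 1])
    return None
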