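"""Spike-LFP phase locking.

Per-spike instantaneous phase sampling against a band-limited oscillation,
the Rayleigh uniformity test (Z = R^2 / n), preferred phases, and
population summaries: fractions of locked units with exact Clopper-Pearson
intervals, log Z distributions compared across stages by the two-sample
Kolmogorov-Smirnov test, and circular preferred-phase histograms.

Phases are degrees in [0, 360), cosine-referenced (0 at the oscillation
peak, 180 at the trough) — see :mod:`striosync.lfp`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lfp import BandSignal

DEFAULT_MIN_SPIKES = 50


@dataclass
class PhaseLockResult:
    n: int
    R: float  # resultant length |sum exp(i theta)|
    Rbar: float  # R / n
    Z: float  # Rayleigh statistic R^2 / n
    logZ: float
    p: float
    preferred_phase: float  # degrees
    reliable: bool = True
    reference: str = ""
    band: tuple = ()


def spike_phases(spike_times, band_signal: BandSignal, epochs=None,
                 t0: float = 0.0) -> np.ndarray:
    """Instantaneous phase of each spike by nearest-sample lookup.

    ``epochs`` is an optional list of [start, stop) intervals (e.g. the
    judgment-zone period of every trial); spikes outside them are dropped.
    """
    st = np.asarray(spike_times, float)
    if epochs is not None:
        keep = np.zeros(st.size, dtype=bool)
        for e0, e1 in epochs:
            keep |= (st >= e0) & (st < e1)
        st = st[keep]
    if st.size == 0:
        return np.empty(0)
    idx = np.round((st - t0) * band_signal.fs).astype(int)
    idx = np.clip(idx, 0, band_signal.phase.size - 1)
    return band_signal.phase[idx]


def rayleigh_test(phases_deg, min_spikes: int = DEFAULT_MIN_SPIKES,
                  reference: str = "", band=()) -> PhaseLockResult:
    """Rayleigh test of circular uniformity.

    ``R`` is the magnitude of the resultant vector, ``Z = R^2 / n``, and the
    p-value uses the standard approximation
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))``.
    The preferred phase is the direction of the resultant.  Results with
    fewer than ``min_spikes`` phases are marked unreliable (still computed).
    """
    theta = np.radians(np.asarray(phases_deg, float))
    n = theta.size
    if n == 0:
        raise ValueError("empty phase sample")
    resultant = np.exp(1j * theta).sum()
    R = float(np.abs(resultant))
    Z = R**2 / n
    p = float(np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - R**2))
                     - (1.0 + 2.0 * n)))
    p = min(max(p, np.finfo(float).tiny), 1.0)
    preferred = float(np.degrees(np.angle(resultant)) % 360.0)
    return PhaseLockResult(
        n=n, R=R, Rbar=R / n, Z=float(Z),
        logZ=float(np.log(Z)) if Z > 0 else -np.inf,
        p=p, preferred_phase=preferred, reliable=n >= min_spikes,
        reference=reference, band=tuple(band),
    )


def clopper_pearson(k: int, n: int, conf: float = 0.95):
    """Exact (Clopper-Pearson) binomial confidence interval for k/n."""
    if not 0 <= k <= n or n == 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def population_phaselock(results: pd.DataFrame, alpha: float = 0.05,
                         conf: float = 0.95):
    """Population summary of per-unit phase-locking results by stage.

    ``results`` needs columns ``stage``, ``p``, ``logZ``,
    ``preferred_phase`` (one row per unit).  Returns

    * ``proportions``: per stage, the fraction of units with ``p < alpha``
      and its exact Clopper-Pearson interval;
    * ``ks``: pairwise two-sample KS tests on the log Z distributions;
    * ``phases``: preferred phases of significantly locked units per stage.
    """
    if len(results) == 0:
        raise ValueError("no units")
    prop_rows, ks_rows, phases = [], [], {}
    stages = list(dict.fromkeys(results["stage"]))
    for stage in stages:
        sub = results[results["stage"] == stage]
        if len(sub) == 0:
            raise ValueError(f"empty stage '{stage}'")
        k = int((sub["p"] < alpha).sum())
        n = len(sub)
        lo, hi = clopper_pearson(k, n, conf)
        prop_rows.append({"stage": stage, "n": n, "k": k,
                          "fraction": k / n, "ci_low": lo, "ci_high": hi})
        phases[stage] = sub.loc[sub["p"] < alpha, "preferred_phase"].to_numpy()
    for i, s1 in enumerate(stages):
        for s2 in stages[i + 1:]:
            a = results.loc[results["stage"] == s1, "logZ"].to_numpy()
            b = results.loc[results["stage"] == s2, "logZ"].to_numpy()
            ks = stats.ks_2samp(a, b)
            ks_rows.append({"stage_a": s1, "stage_b": s2,
                            "D": float(ks.statistic), "p": float(ks.pvalue)})
    return pd.DataFrame(prop_rows), pd.DataFrame(ks_rows), phases


def phase_histogram(phases_deg, bins: int = 18, normalization: str = "max"):
    """Circular histogram of phases on [0, 360).

    Returns (bin edges, normalized heights).  ``normalization``: 'max'
    (per-unit maximum = 1, the display convention), 'mean' (mean = 1), or
    None (raw counts).  Bin 0 is adjacent to the last bin.
    """
    phases = np.asarray(phases_deg, float) % 360.0
    edges = np.linspace(0.0, 360.0, bins + 1)
    counts, _ = np.histogram(phases, bins=edges)
    heights = counts.astype(float)
    if normalization == "max":
        if heights.max() > 0:
            heights = heights / heights.max()
    elif normalization == "mean":
        if heights.mean() > 0:
            heights = heights / heights.mean()
    elif normalization is not None:
        raise ValueError(f"unknown normalization '{normalization}'")
    return edges, heights
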