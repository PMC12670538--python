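"""Single-unit characterization.

Waveform width and firing-rate based RS/FS classification, occupancy-
normalized rate maps on normalized distance, stimulus-selectivity
permutation tests, Skaggs spatial information (bits/spike), and stage-wise
population averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .behavior import N_BINS, distance_bin_centers, distance_bin_index
from .resampling import CurveFamily, band_permutation_test

#: Default classification thresholds (config-exposed; the boundary values
#: are free parameters calibrated on the synthetic population).
DEFAULT_WIDTH_MS = 0.55  # FS below, RS at or above
DEFAULT_RATE_HZ = 2.0  # FS requires at least this mean rate
DEFAULT_PROP_ISI = 0.05  # TAN below (tonically active: few long gaps)


@dataclass
class UnitFeatures:
    unit_id: str
    region: str
    spike_width: float  # ms
    mean_rate: float  # Hz
    prop_long_isi: float
    label: str = ""


def spike_width(waveform, fs: float) -> float:
    """Spike width in ms: time the waveform spends below one third of the
    trough-to-peak amplitude.

    Baseline is the pre-trough median; the level is
    ``baseline - (peak - trough) / 3`` with the peak taken after the trough
    (or the baseline itself if the waveform never rebounds above it).  The
    crossings around the trough are located by linear interpolation, so the
    width is not quantized to the sample period.
    """
    v = np.asarray(waveform, float)
    if v.size < 3 or np.ptp(v) == 0:
        raise ValueError("flat or degenerate waveform")
    i_tr = int(np.argmin(v))
    if i_tr == 0 or i_tr == v.size - 1:
        raise ValueError("trough at waveform edge")
    baseline = float(np.median(v[:i_tr]))
    peak = float(max(np.max(v[i_tr:]), baseline))
    trough = float(v[i_tr])
    level = baseline - (peak - trough) / 3.0
    if trough >= level:
        raise ValueError("trough does not reach the one-third level")

    # Walk outward from the trough to the interpolated level crossings.
    i = i_tr
    while i > 0 and v[i - 1] < level:
        i -= 1
    if i == 0:
        t_left = 0.0
    else:
        t_left = i - (level - v[i]) / (v[i - 1] - v[i])
    j = i_tr
    while j < v.size - 1 and v[j + 1] < level:
        j += 1
    if j == v.size - 1:
        t_right = float(v.size - 1)
    else:
        t_right = j + (level - v[j]) / (v[j + 1] - v[j])
    return (t_right - t_left) * 1000.0 / fs


def prop_long_isi(spike_times, total_time: float, threshold: float = 2.0) -> float:
    """Fraction of the recording occupied by inter-spike intervals > threshold."""
    st = np.asarray(spike_times, float)
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    if st.size < 2:
        warnings.warn("fewer than 2 spikes: PROP(ISI>thr) set to 1.0 "
                      "(whole record is one long gap)", stacklevel=2)
        return 1.0
    isi = np.diff(st)
    return float(isi[isi > threshold].sum() / total_time)


def classify_unit(spike_width_ms: float, mean_rate: float,
                  prop_isi: float | None = None,
                  width_thr: float = DEFAULT_WIDTH_MS,
                  rate_thr: float = DEFAULT_RATE_HZ,
                  prop_thr: float = DEFAULT_PROP_ISI,
                  merge_tan: bool = True) -> str:
    """Rule-based RS/FS/TAN label.

    FS: narrow spike and high rate.  TAN: broad spike with few long ISI
    gaps (tonically active); grouped into FS by default, matching the
    treatment of the small cholinergic population.  Everything else is RS
    (putative medium spiny neuron).
    """
    if spike_width_ms < width_thr and mean_rate >= rate_thr:
        return "FS"
    if prop_isi is not None and prop_isi < prop_thr and spike_width_ms >= width_thr:
        return "FS" if merge_tan else "TAN"
    return "RS"


def unit_features(unit, total_time: float, **thresholds) -> UnitFeatures:
    """Width, whole-session mean rate, PROP(ISI>2s), and label for one unit."""
    width = spike_width(unit.mean_waveform, unit.fs_wave)
    rate = len(unit.spike_times) / total_time
    prop = prop_long_isi(unit.spike_times, total_time)
    label = classify_unit(width, rate, prop, **thresholds)
    return UnitFeatures(unit_id=unit.unit_id, region=unit.region,
                        spike_width=width, mean_rate=rate,
                        prop_long_isi=prop, label=label)


@dataclass
class RateMap:
    """Occupancy-normalized firing rate per normalized-distance bin.

    ``rate * occupancy == count`` holds exactly per bin; zero-occupancy
    bins are NaN-rated and masked.
    """

    bin_centers: np.ndarray
    rate: dict = field(default_factory=dict)  # condition -> Hz per bin
    occupancy: dict = field(default_factory=dict)  # condition -> s per bin
    count: dict = field(default_factory=dict)  # condition -> spikes per bin

    def valid(self, condition: str = "pooled") -> np.ndarray:
        return self.occupancy[condition] > 0


def _bin_trial(spikes, t, x, zone_length, t_entry, t_exit, n_bins):
    """(occupancy s, spike count) per bin for one judgment-zone traversal."""
    sel = np.flatnonzero((t >= t_entry) & (t < t_exit))
    occ = np.zeros(n_bins)
    cnt = np.zeros(n_bins)
    if sel.size < 2:
        return occ, cnt
    ts = t[sel]
    d = np.clip(x[sel] / zone_length, 0.0, 1.0)
    bins = distance_bin_index(d, n_bins)
    dt = np.empty(sel.size)
    dt[:-1] = np.diff(ts)
    dt[-1] = t_exit - ts[-1]
    np.add.at(occ, bins, dt)
    in_zone = spikes[(spikes >= t_entry) & (spikes < t_exit)]
    if in_zone.size:
        # spike -> bin of the nearest tracking sample at spike time
        idx = np.searchsorted(ts, in_zone)
        idx = np.clip(idx, 1, ts.size - 1)
        nearer_left = (in_zone - ts[idx - 1]) < (ts[idx] - in_zone)
        idx = np.where(nearer_left, idx - 1, idx)
        np.add.at(cnt, bins[idx], 1)
    return occ, cnt


def rate_map(spike_times, trials: pd.DataFrame, tracking: pd.DataFrame,
             zone_length: float, n_bins: int = N_BINS,
             split: str | None = "stimulus") -> RateMap:
    """Judgment-zone rate map, optionally split by a trial column.

    Rates are spike counts divided by the time spent in each bin, summed
    over traversals.  A 'pooled' condition is always included.
    """
    spikes = np.asarray(spike_times, float)
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    conditions = ["pooled"]
    if split is not None:
        conditions += sorted(trials[split].unique())
    occ = {c: np.zeros(n_bins) for c in conditions}
    cnt = {c: np.zeros(n_bins) for c in conditions}
    for row in trials.itertuples():
        o, c = _bin_trial(spikes, t, x, zone_length, row.t_entry, row.t_exit,
                          n_bins)
        occ["pooled"] += o
        cnt["pooled"] += c
        if split is not None:
            cond = getattr(row, split)
            occ[cond] += o
            cnt[cond] += c
    rate = {}
    for c in conditions:
        with np.errstate(invalid="ignore", divide="ignore"):
            rate[c] = np.where(occ[c] > 0, cnt[c] / np.where(occ[c] > 0, occ[c], 1),
                               np.nan)
    return RateMap(bin_centers=distance_bin_centers(n_bins), rate=rate,
                   occupancy=occ, count=cnt)


def trial_rate_curves(spike_times, trials: pd.DataFrame,
                      tracking: pd.DataFrame, zone_length: float,
                      n_bins: int = N_BINS,
                      label_col: str = "stimulus") -> CurveFamily:
    """Per-trial rate curves (Hz per bin) labeled by a trial column.

    Bins a trial never occupied are rated 0 for that trial (the permutation
    engine requires complete curves).
    """
    spikes = np.asarray(spike_times, float)
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    curves, labels = [], []
    for row in trials.itertuples():
        occ, cnt = _bin_trial(spikes, t, x, zone_length, row.t_entry,
                              row.t_exit, n_bins)
        rate = np.where(occ > 0, cnt / np.where(occ > 0, occ, 1.0), 0.0)
        curves.append(rate)
        labels.append(getattr(row, label_col))
    return CurveFamily(np.array(curves), np.array(labels),
                       positions=distance_bin_centers(n_bins))


def stimulus_selectivity(spike_times, trials, tracking, zone_length,
                         n_bins: int = N_BINS, n_perm: int = 5000,
                         alpha: float = 0.05, seed=None):
    """Stim 1 vs Stim 2 permutation-band test on per-trial rate curves.

    Returns (BandPermResult, selective flag); a unit is selective when any
    position is significant under the globally corrected band.
    """
    family = trial_rate_curves(spike_times, trials, tracking, zone_length,
                               n_bins, label_col="stimulus")
    result = band_permutation_test(family, n_perm=n_perm, alpha=alpha,
                                   seed=seed)
    return result, bool(result.global_sig.any())


@dataclass
class SpatialInfo:
    information: float  # bits/spike
    mean_rate: float  # Hz (occupancy-weighted)
    occupancy_p: np.ndarray
    rates: np.ndarray


def spatial_information(rates, occupancy) -> SpatialInfo:
    """Skaggs per-spike spatial information of a pooled rate map.

    ``I = sum_i p_i (lam_i / lam) log2(lam_i / lam)`` over occupied bins,
    with ``p_i`` the occupancy probability and ``lam`` the occupancy-
    weighted mean rate.  Zero for a flat map; invariant to uniform rate
    rescaling.
    """
    rates = np.asarray(rates, float)
    occupancy = np.asarray(occupancy, float)
    occ_mask = occupancy > 0
    if not occ_mask.any():
        raise ValueError("no occupied bins")
    p = occupancy[occ_mask] / occupancy[occ_mask].sum()
    lam = rates[occ_mask]
    lam_bar = float(np.sum(p * lam))
    if lam_bar <= 0:
        raise ValueError("mean rate is zero; bits/spike undefined")
    pos = lam > 0
    ratio = lam[pos] / lam_bar
    info = float(np.sum(p[pos] * ratio * np.log2(ratio)))
    return SpatialInfo(information=max(info, 0.0), mean_rate=lam_bar,
                       occupancy_p=p, rates=lam)


def population_stage_average(curves_by_stage: dict, n_perm: int = 5000,
                             alpha: float = 0.05, seed=None):
    """Per-stage population mean +/- SEM and an early-vs-late band test.

    ``curves_by_stage`` maps stage name -> (units x bins) rate curves;
    units are treated as exchangeable observations in the comparison.
    """
    summary = {}
    for stage, curves in curves_by_stage.items():
        curves = np.asarray(curves, float)
        if curves.shape[0] < 2:
            raise ValueError(f"stage '{stage}' needs >= 2 units")
        summary[stage] = {
            "mean": curves.mean(axis=0),
            "sem": curves.std(axis=0, ddof=1) / np.sqrt(curves.shape[0]),
            "n": curves.shape[0],
        }
    result = None
    if "early" in curves_by_stage and "late" in curves_by_stage:
        early = np.asarray(curves_by_stage["early"], float)
        late = np.asarray(curves_by_stage["late"], float)
        family = CurveFamily(
            np.vstack([early, late]),
            np.array(["early"] * early.shape[0] + ["late"] * late.shape[0]),
            positions=distance_bin_centers(early.shape[1]),
        )
        result = band_permutation_test(family, n_perm=n_perm, alpha=alpha,
                                       seed=seed)
    return summary, result
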