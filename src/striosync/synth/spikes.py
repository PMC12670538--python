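"""Synthetic spike trains and mean waveforms.

Each unit is an inhomogeneous Poisson process simulated exactly by
thinning of a dominating homogeneous process, with intensity

``lambda(t) = r0 * tuning(pos(t)) * stim_gain(trial)
            * exp(kappa * cos(phi_ref(t) - phi_pref)) / I0(kappa)``

where ``tuning`` is a normalized Gaussian bump on normalized distance
(mean 1 over the zone, so ``r0`` stays the baseline rate), the stimulus
gain applies during Stim 1 judgment-zone epochs, and ``phi_ref`` is the
instantaneous phase of the reference region's band-limited oscillation.
Mean waveforms get a class-dependent triangular trough whose
width-at-one-third is set analytically, so the downstream width classifier
can recover the class.
"""

from __future__ import annotations

import numpy as np
from scipy.special import i0

from ..lfp import bandpass
from ..session import Unit
from .config import SynthConfig, UnitSpec

FS_WAVE = 20000.0
#: realized spike-width targets (ms) per class: mean and jitter SD
WIDTH_TARGETS = {"RS": (0.90, 0.08), "FS": (0.30, 0.04), "TAN": (0.95, 0.08)}
WIDTH_CLIPS = {"RS": (0.65, 1.30), "FS": (0.18, 0.45), "TAN": (0.70, 1.30)}
# fraction of a triangular trough spent below the one-third level:
# with after-peak 0.3x the trough depth, level = 0.433 * depth, so the
# time below it is (1 - 0.433) of the full trough duration
_TRI_FRACTION = 1.0 - (1.0 + 0.3) / 3.0


def make_waveform(unit_class: str, rng, n_samples: int = 64,
                  fs: float = FS_WAVE) -> np.ndarray:
    """Mean waveform (µV) with a class-dependent trough width."""
    mean_w, sd_w = WIDTH_TARGETS[unit_class]
    lo, hi = WIDTH_CLIPS[unit_class]
    target_ms = float(np.clip(rng.normal(mean_w, sd_w), lo, hi))
    tri_ms = target_ms / _TRI_FRACTION
    dt_ms = 1000.0 / fs
    t = np.arange(n_samples) * dt_ms
    center = t[n_samples // 2]
    depth = 100.0  # µV
    v = np.zeros(n_samples)
    half = tri_ms / 2.0
    tri = 1.0 - np.abs(t - center) / half
    v -= depth * np.clip(tri, 0.0, None)
    # after-hyperpolarization bump, 0.3x the trough depth
    bump_c = center + half + 0.6 * half
    bump_w = 1.2 * half
    bump = np.cos(np.clip((t - bump_c) / bump_w, -1, 1) * np.pi / 2) ** 2
    bump[np.abs(t - bump_c) > bump_w] = 0.0
    v += 0.3 * depth * bump
    v += rng.normal(0.0, 0.5, n_samples)  # measurement noise, µV
    return v


def _tuning_factor(spec: UnitSpec, d: np.ndarray) -> np.ndarray:
    """Position gain, normalized to mean 1 over the zone."""
    if spec.tuning_center is None or spec.tuning_gain == 0:
        return np.ones_like(d)
    grid = np.linspace(0.0, 1.0, 501)
    bump = np.exp(-((grid - spec.tuning_center) ** 2)
                  / (2 * spec.tuning_width**2))
    norm = 1.0 + spec.tuning_gain * bump.mean()
    gain = 1.0 + spec.tuning_gain * np.exp(
        -((d - spec.tuning_center) ** 2) / (2 * spec.tuning_width**2))
    return gain / norm


def gen_spikes(cfg: SynthConfig, lfp_traces: dict, tracking, trials,
               duration: float, rng) -> dict:
    """Simulate all configured units; returns ``{unit_id: Unit}``.

    ``lfp_traces`` must contain every reference region; tracking and trials
    must cover the trial epochs.
    """
    cfg.validate()
    fs = cfg.lfp_fs
    n = int(round(duration * fs))
    tt = np.arange(n) / fs

    track_t = tracking["t"].to_numpy()
    track_x = tracking["x"].to_numpy()
    d_of_t = np.interp(tt, track_t, track_x, left=np.nan, right=np.nan)
    d_of_t = d_of_t / cfg.zone_length
    in_zone = (d_of_t >= 0.0) & (d_of_t <= 1.0)
    in_zone &= np.isfinite(d_of_t)

    zone_mask = np.zeros(n, dtype=bool)
    stim1_mask = np.zeros(n, dtype=bool)
    for row in trials.itertuples():
        i0_, i1_ = int(row.t_entry * fs), int(row.t_exit * fs)
        zone_mask[i0_:i1_] = True
        if row.stimulus == "Stim1":
            stim1_mask[i0_:i1_] = True
    in_zone &= zone_mask

    phase_by_ref = {}
    units = {}
    for k, spec in enumerate(cfg.unit_specs):
        key = (spec.ref_region, tuple(spec.ref_band))
        if spec.phase_kappa > 0 and key not in phase_by_ref:
            sig = bandpass(lfp_traces[spec.ref_region], fs, spec.ref_band)
            phase_by_ref[key] = np.radians(sig.phase)

        rate = np.full(n, float(spec.mean_rate))
        if spec.tuning_center is not None and spec.tuning_gain != 0:
            gain = np.ones(n)
            gain[in_zone] = _tuning_factor(spec, d_of_t[in_zone])
            rate *= gain
        if spec.stim_gain != 1.0:
            rate[stim1_mask] *= spec.stim_gain
        if spec.phase_kappa > 0:
            phi = phase_by_ref[key]
            kappa = spec.phase_kappa
            rate *= np.exp(kappa * np.cos(phi - np.radians(spec.preferred_phase)))
            rate /= i0(kappa)
        lam_max = rate.max()
        if lam_max > cfg.rate_ceiling:
            raise ValueError(
                f"unit {k}: peak intensity {lam_max:.1f} Hz exceeds the "
                f"{cfg.rate_ceiling:.0f} Hz ceiling (mis-set gains?)"
            )
        # thinning of a dominating homogeneous process
        n_cand = rng.poisson(lam_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, n_cand))
        idx = np.minimum((cand * fs).astype(int), n - 1)
        keep = rng.uniform(0.0, lam_max, n_cand) < rate[idx]
        spikes = np.unique(cand[keep])  # strictly increasing
        unit_id = f"u{k:03d}_{spec.region}"
        units[unit_id] = Unit(
            unit_id=unit_id, region=spec.region, spike_times=spikes,
            mean_waveform=make_waveform(spec.unit_class, rng),
            fs_wave=FS_WAVE,
        )
    return units
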