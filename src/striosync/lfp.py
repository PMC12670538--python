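"""LFP spectral analysis.

Band filtering with analytic phase/amplitude, Morlet wavelet power,
inter-regional wavelet coherence, position alignment of time-resolved
quantities, and amplitude-speed rank correlation.

Phase convention (used everywhere downstream): phases are cosine-referenced
degrees in [0, 360) — 0 deg at the oscillation peak, 180 deg at the trough.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pywt
from scipy import signal, stats
from scipy.ndimage import gaussian_filter1d, uniform_filter1d

from .behavior import N_BINS, distance_bin_centers, distance_bin_index

BAND_4HZ = (2.0, 5.0)
BAND_THETA = (6.0, 10.0)
MORLET_W0 = 6.0  #: Morlet center-frequency parameter omega0


@dataclass
class BandSignal:
    band: tuple
    filtered: np.ndarray  # µV
    phase: np.ndarray  # degrees in [0, 360)
    amplitude: np.ndarray  # µV envelope
    fs: float

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.filtered.size) / self.fs


def bandpass(samples, fs: float, band, order: int = 3) -> BandSignal:
    """Zero-phase Butterworth band-pass with analytic phase and envelope.

    The filter is applied forward-backward (order ``order`` per pass);
    instantaneous phase and amplitude come from the Hilbert analytic signal.
    """
    lo, hi = band
    if not 0 < lo < hi < fs / 2:
        raise ValueError(f"band {band} outside (0, fs/2) = (0, {fs / 2})")
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    filtered = signal.sosfiltfilt(sos, np.asarray(samples, float))
    analytic = signal.hilbert(filtered)
    phase = np.degrees(np.angle(analytic)) % 360.0
    return BandSignal(band=tuple(band), filtered=filtered, phase=phase,
                      amplitude=np.abs(analytic), fs=fs)


def _cmor_name(w0: float) -> str:
    # psi(t) = (pi B)^(-1/2) exp(2i pi C t) exp(-t^2/B): B=2, C=w0/2pi
    return f"cmor2.0-{w0 / (2 * np.pi):.8f}"


def morlet_cwt(samples, fs: float, freqs, w0: float = MORLET_W0) -> np.ndarray:
    """Complex Morlet CWT, rows ordered as ``freqs``.

    PyWavelets' cmor implementation is L2-normalized across scale (white
    noise has flat expected power over frequency), which is the convention
    all downstream power/coherence code assumes.
    """
    freqs = np.asarray(freqs, float)
    if np.any(freqs <= 0) or np.any(freqs >= fs / 2):
        raise ValueError("frequency grid must lie inside (0, fs/2)")
    wav = _cmor_name(w0)
    scales = pywt.frequency2scale(wav, freqs / fs)
    coefs, _ = pywt.cwt(np.asarray(samples, float), scales, wav,
                        sampling_period=1.0 / fs, method="fft")
    return coefs


def coi_mask(n_samples: int, fs: float, freqs, w0: float = MORLET_W0) -> np.ndarray:
    """True where a (freq, time) cell is *outside* the cone of influence.

    Edge effects extend one e-folding time ``sqrt(2) * s`` (Morlet scale
    ``s = w0 / (2 pi f)`` seconds) into the data from each end.
    """
    freqs = np.asarray(freqs, float)
    t = np.arange(n_samples) / fs
    tau = np.sqrt(2.0) * w0 / (2 * np.pi * freqs)  # s, per frequency
    edge = np.minimum(t, t[::-1])[None, :]
    return edge >= tau[:, None]


@dataclass
class PowerMap:
    freqs: np.ndarray
    t: np.ndarray
    values: np.ndarray  # power, µV²
    valid: np.ndarray  # outside the cone of influence


@dataclass
class CoherenceMap:
    freqs: np.ndarray
    t: np.ndarray
    values: np.ndarray  # magnitude-squared coherence in [0, 1]
    valid: np.ndarray


def wavelet_power(samples, fs: float, freqs, w0: float = MORLET_W0) -> PowerMap:
    """Morlet wavelet power (squared modulus), edge cone flagged."""
    coefs = morlet_cwt(samples, fs, freqs, w0)
    n = coefs.shape[1]
    return PowerMap(freqs=np.asarray(freqs, float), t=np.arange(n) / fs,
                    values=np.abs(coefs) ** 2,
                    valid=coi_mask(n, fs, freqs, w0))


def wavelet_coherence(samples_a, samples_b, fs: float, freqs,
                      w0: float = MORLET_W0, time_smooth_cycles: float = 6.0,
                      scale_smooth_bins: int = 3) -> CoherenceMap:
    """Magnitude-squared wavelet coherence between two equal-length traces.

    ``|S(Wa conj(Wb))|^2 / (S(|Wa|^2) S(|Wb|^2))`` with smoothing S a
    Gaussian over time whose sigma is ``time_smooth_cycles`` oscillation
    cycles at each frequency (scale-proportional), followed by a boxcar over
    ``scale_smooth_bins`` adjacent scales.  Values are clipped to [0, 1];
    zero-power cells are masked.
    """
    a = np.asarray(samples_a, float)
    b = np.asarray(samples_b, float)
    if a.shape != b.shape:
        raise ValueError("traces must have equal length")
    freqs = np.asarray(freqs, float)
    wa = morlet_cwt(a, fs, freqs, w0)
    wb = morlet_cwt(b, fs, freqs, w0)
    sxy = wa * np.conj(wb)
    sxx = np.abs(wa) ** 2
    syy = np.abs(wb) ** 2
    for i, f in enumerate(freqs):
        sig = max(time_smooth_cycles * fs / f, 1.0)  # samples
        sxy[i] = gaussian_filter1d(sxy.real[i], sig, mode="nearest") \
            + 1j * gaussian_filter1d(sxy.imag[i], sig, mode="nearest")
        sxx[i] = gaussian_filter1d(sxx[i], sig, mode="nearest")
        syy[i] = gaussian_filter1d(syy[i], sig, mode="nearest")
    if scale_smooth_bins > 1 and freqs.size > 1:
        size = min(scale_smooth_bins, freqs.size)
        sxy = uniform_filter1d(sxy.real, size, axis=0, mode="nearest") \
            + 1j * uniform_filter1d(sxy.imag, size, axis=0, mode="nearest")
        sxx = uniform_filter1d(sxx, size, axis=0, mode="nearest")
        syy = uniform_filter1d(syy, size, axis=0, mode="nearest")
    denom = sxx * syy
    power_ok = denom > 0
    coh = np.zeros_like(sxx)
    coh[power_ok] = np.abs(sxy[power_ok]) ** 2 / denom[power_ok]
    np.clip(coh, 0.0, 1.0, out=coh)
    n = a.size
    return CoherenceMap(freqs=freqs, t=np.arange(n) / fs, values=coh,
                        valid=coi_mask(n, fs, freqs, w0) & power_ok)


def band_mean(spectral_map, band, time_mask=None,
              exclude_coi: bool = True) -> float:
    """Mean map value over a frequency band and an epoch mask.

    ``time_mask`` is boolean over samples (e.g. in-judgment-zone); the
    wavelet edge cone is excluded by default.
    """
    freqs = spectral_map.freqs
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        raise ValueError(f"band {band} outside the frequency grid")
    sel = np.ones_like(spectral_map.values, dtype=bool)
    sel &= in_band[:, None]
    if exclude_coi:
        sel &= spectral_map.valid
    if time_mask is not None:
        time_mask = np.asarray(time_mask, bool)
        sel &= time_mask[None, :]
    if not sel.any():
        raise ValueError("empty selection (mask/band/cone leave no samples)")
    return float(spectral_map.values[sel].mean())


def epoch_mask(t, intervals) -> np.ndarray:
    """Boolean mask over sample times for a list of [t0, t1) intervals."""
    t = np.asarray(t, float)
    mask = np.zeros(t.size, dtype=bool)
    for t0, t1 in intervals:
        mask |= (t >= t0) & (t < t1)
    return mask


def position_align(values, t_values, trials: pd.DataFrame,
                   tracking: pd.DataFrame, zone_length: float,
                   n_bins: int = N_BINS):
    """Occupancy-time-weighted per-bin mean of a time series over traversals.

    The quantity is interpolated at tracking sample times; each sample
    contributes its dwell time to its normalized-distance bin, so the
    profile is invariant to running speed.  Zero-occupancy bins are NaN.
    """
    values = np.asarray(values, float)
    t_values = np.asarray(t_values, float)
    t = tracking["t"].to_numpy()
    x = tracking["x"].to_numpy()
    acc = np.zeros(n_bins)
    occ = np.zeros(n_bins)
    for row in trials.itertuples():
        sel = np.flatnonzero((t >= row.t_entry) & (t < row.t_exit))
        if sel.size < 2:
            continue
        ts = t[sel]
        d = np.clip(x[sel] / zone_length, 0.0, 1.0)
        bins = distance_bin_index(d, n_bins)
        dt = np.empty(sel.size)
        dt[:-1] = np.diff(ts)
        dt[-1] = row.t_exit - ts[-1]
        v = np.interp(ts, t_values, values)
        np.add.at(acc, bins, v * dt)
        np.add.at(occ, bins, dt)
    profile = np.full(n_bins, np.nan)
    ok = occ > 0
    profile[ok] = acc[ok] / occ[ok]
    return distance_bin_centers(n_bins), profile


def amplitude_speed_kendall(amplitude, t_amplitude, speed, t_speed,
                            rate: float = 10.0):
    """Kendall tau-b between band amplitude and running speed.

    Both series are resampled to a common ``rate`` (Hz) grid over their
    overlapping support before correlating.
    """
    t0 = max(t_amplitude[0], t_speed[0])
    t1 = min(t_amplitude[-1], t_speed[-1])
    if t1 <= t0:
        raise ValueError("series do not overlap in time")
    grid = np.arange(t0, t1 + 0.5 / rate, 1.0 / rate)
    a = np.interp(grid, t_amplitude, amplitude)
    v = np.interp(grid, t_speed, speed)
    if np.ptp(a) == 0 or np.ptp(v) == 0:
        raise ValueError("tau undefined for a constant series")
    res = stats.kendalltau(a, v)
    return float(res.statistic), float(res.pvalue)
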