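"""Synthetic LFP: coupled 4 Hz oscillators, speed-modulated theta, noise.

Each region's trace is

``scale * (a_r * s4 + b_r * p4_r + A_theta * theta_r * (1 + g * speed(t))
+ sigma_n * white)``

where ``s4`` is a narrowband 2-5 Hz process shared by all regions, ``p4_r``
and ``theta_r`` are private narrowband processes, and the mixing weights
``a_r`` are solved so the asymptotic magnitude-squared coherence of every
region pair inside 2-5 Hz equals its target.  Narrowband processes are
white noise band-pass filtered (order-3 Butterworth, forward-backward), so
coherence and phase estimates are nondegenerate.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from ..session import REGIONS
from .config import REGION_PAIRS, SynthConfig


def narrowband(rng, n: int, fs: float, band) -> np.ndarray:
    """Unit-variance narrowband noise in ``band`` (zero-phase Butterworth)."""
    sos = signal.butter(3, list(band), btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def solve_mixing_weights(targets: dict, inband_noise_ratio: float = 0.0) -> dict:
    """Shared-component weights ``a_r`` from pairwise coherence targets.

    With unit-variance band components ``a_r * s + b_r * p_r``
    (``a^2 + b^2 = 1``) and relative in-band noise ``nu``, the asymptotic
    coherence of a pair is ``(a_r a_s)^2 / (1 + nu)^2``; solving the three
    pairwise products gives ``a_r``.  Raises when the targets violate the
    positive-semidefiniteness of the implied 3x3 coherency structure.
    """
    corr = (1.0 + inband_noise_ratio)
    g = {}
    for pair in REGION_PAIRS:
        c = targets.get(pair, targets.get((pair[1], pair[0]), 0.0))
        g[pair] = min(c * corr**2, 1.0)
    g12 = g[("pStr", "dLGN")]
    g13 = g[("pStr", "VC")]
    g23 = g[("dLGN", "VC")]
    zeros = [pair for pair, v in g.items() if v == 0.0]
    if len(zeros) == 3:
        return {r: 0.0 for r in REGIONS}
    if len(zeros) == 2:
        # one coherent pair, the third region uncoupled
        (pair_nz,) = [p for p, v in g.items() if v > 0.0]
        a = g[pair_nz] ** 0.25
        out = {r: 0.0 for r in REGIONS}
        out[pair_nz[0]] = out[pair_nz[1]] = a
        return out
    if len(zeros) == 1:
        raise ValueError(
            "coherence targets unsolvable with a single shared 4 Hz process: "
            f"exactly one zero pair {zeros[0]} while both other pairs are "
            "coherent violates the implied coherency structure"
        )
    a_sq = {
        "pStr": np.sqrt(g12 * g13 / g23),
        "dLGN": np.sqrt(g12 * g23 / g13),
        "VC": np.sqrt(g13 * g23 / g12),
    }
    for region, v in a_sq.items():
        if v > 1.0 + 1e-9:
            raise ValueError(
                f"coherence targets infeasible: implied shared power "
                f"{v:.3f} > 1 for {region} (coherency matrix not PSD)"
            )
    return {r: float(np.sqrt(min(v, 1.0))) for r, v in a_sq.items()}


def gen_lfp(cfg: SynthConfig, duration: float, rng, speed_t=None,
            speed_v=None, coherence: dict | None = None) -> dict:
    """LFP traces (µV) per region for one session of ``duration`` seconds.

    ``speed_t`` / ``speed_v`` give the running-speed series for the
    theta-amplitude coupling (zero speed outside its support).
    ``coherence`` overrides the config's 4 Hz pairwise targets.
    """
    cfg.validate()
    fs = cfg.lfp_fs
    n = int(round(duration * fs))
    targets = coherence if coherence is not None else cfg.coherence_4hz
    bw = cfg.band_4hz[1] - cfg.band_4hz[0]
    nu = cfg.noise_sd**2 * bw / (fs / 2.0)  # in-band white-noise variance
    weights = solve_mixing_weights(targets, nu)

    t = np.arange(n) / fs
    if speed_t is None or len(speed_t) == 0:
        speed = np.zeros(n)
    else:
        speed = np.interp(t, speed_t, speed_v, left=0.0, right=0.0)
    theta_gain = np.maximum(1.0 + cfg.theta_speed_gain * speed, 0.0)

    shared = narrowband(rng, n, fs, cfg.band_4hz)
    traces = {}
    for region in REGIONS:
        a = weights[region]
        b = np.sqrt(max(1.0 - a**2, 0.0))
        band4 = a * shared + b * narrowband(rng, n, fs, cfg.band_4hz)
        theta = cfg.theta_amplitude * narrowband(rng, n, fs, cfg.band_theta)
        white = cfg.noise_sd * rng.standard_normal(n)
        traces[region] = cfg.lfp_scale * (band4 + theta * theta_gain + white)
    return traces
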