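"""Synthetic behavior: trials and head tracking for one session.

Each trial is a judgment-zone traversal: the along-track coordinate follows
the (relative) speed profile scaled to a log-normal traversal duration
(CV matching the ~18% inter-traversal variability of real runs), and the
lateral coordinate is identical in expectation for left and right choices
before the programmed bifurcation distance, diverging linearly after it,
plus i.i.d. Gaussian tracking noise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ..session import CORRECT_ARM
from .config import SynthConfig


def _lognormal(rng, mean: float, cv: float, size=None):
    sigma2 = np.log(1.0 + cv**2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size)


def _distance_vs_time(cfg: SynthConfig, t_rel: np.ndarray,
                      duration: float) -> np.ndarray:
    """Normalized distance at times ``t_rel`` in [0, duration]."""
    profile = cfg.speed_profile
    if profile is None:
        return np.clip(t_rel / duration, 0.0, 1.0)
    profile = np.asarray(profile, float)
    if np.any(profile <= 0):
        raise ValueError("speed profile must be positive")
    n = profile.size
    # time to cross each bin ~ width / speed, rescaled to the duration
    bin_times = (1.0 / n) / profile
    edges_t = np.concatenate([[0.0], np.cumsum(bin_times)])
    edges_t *= duration / edges_t[-1]
    edges_d = np.linspace(0.0, 1.0, n + 1)
    return np.interp(t_rel, edges_t, edges_d)


def lateral_offset(cfg: SynthConfig, d: np.ndarray) -> np.ndarray:
    """Unsigned lateral offset (maze units) at normalized distance ``d``.

    Zero before the bifurcation distance, then linear, reaching
    ``arm_offset`` at the zone end.
    """
    b = cfg.bifurcation_distance
    slope = cfg.arm_offset / (1.0 - b)
    return slope * np.maximum(0.0, np.asarray(d, float) - b)


def gen_behavior(cfg: SynthConfig, session_index: int, rng):
    """Generate (trials, tracking) tables for one session.

    Stimuli are equiprobable; the choice matches the stimulus-defined
    correct arm with the session's programmed success probability.
    Timestamps: ``t_entry`` (zone entry), ``t_exit`` (zone exit),
    ``t_choice`` (reward-port arrival); reaction time = t_choice - t_entry.
    """
    cfg.validate()
    p_success = float(cfg.success_prob[session_index])
    rt_mean = float(cfg.reaction_time[session_index])
    dt = 1.0 / cfg.fs_track
    rows = []
    frames = []
    clock = cfg.iti
    for _ in range(cfg.trials_per_session):
        stimulus = "Stim1" if rng.random() < 0.5 else "Stim2"
        correct = rng.random() < p_success
        arm = CORRECT_ARM[stimulus]
        choice = arm if correct else ("right" if arm == "left" else "left")
        sign = 1.0 if choice == "right" else -1.0

        rt = float(_lognormal(rng, rt_mean, cfg.timing_cv))
        t_zone = rt * (1.0 - cfg.approach_fraction)
        t_entry = clock
        t_exit = t_entry + t_zone
        t_choice = t_entry + rt
        clock = t_choice + cfg.iti

        t = np.arange(t_entry, t_choice, dt)
        t_rel = t - t_entry
        in_zone = t_rel < t_zone
        d = np.empty(t.size)
        d[in_zone] = _distance_vs_time(cfg, t_rel[in_zone], t_zone)
        # approach segment: straight run from zone exit to the reward port
        frac = (t_rel[~in_zone] - t_zone) / max(rt - t_zone, dt)
        d[~in_zone] = 1.0 + frac * 0.2
        x = d * cfg.zone_length
        y = np.where(
            d <= 1.0,
            sign * lateral_offset(cfg, np.minimum(d, 1.0)),
            sign * (cfg.arm_offset + (d - 1.0) / 0.2 * cfg.arm_offset),
        )
        y = y + rng.normal(0.0, cfg.trajectory_noise_sd, t.size)
        frames.append(pd.DataFrame({"t": t, "x": x, "y": y}))
        rows.append({
            "stimulus": stimulus, "choice": choice, "correct": correct,
            "t_entry": t_entry, "t_exit": t_exit, "t_choice": t_choice,
        })
    trials = pd.DataFrame(rows)
    tracking = pd.concat(frames, ignore_index=True)
    return trials, tracking
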