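"""Configuration and ground truth for the synthetic-session generator.

The defaults describe the study conditions the analyses assume: ~29
training sessions over which the success probability rises from chance
toward ~0.95 while the reaction time falls from ~4 s to ~1.5 s, left/right
trajectories bifurcating halfway through a 100-unit judgment zone, LFPs at
1.25 kHz carrying a shared 4 Hz (2-5 Hz) rhythm with programmable pairwise
coherence plus an independent theta (6-10 Hz) rhythm whose amplitude grows
with running speed, and RS/FS units with programmable tuning, stimulus
selectivity and von Mises phase modulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from ..session import REGIONS

REGION_PAIRS = (("pStr", "dLGN"), ("pStr", "VC"), ("dLGN", "VC"))


def default_learning_curve(n_sessions: int):
    """(success probability, mean reaction time s) per session.

    Saturating-exponential learning: success 0.5 -> ~0.95, reaction time
    4 s -> ~1.5 s, time constant 8 sessions.
    """
    i = np.arange(n_sessions)
    ramp = 1.0 - np.exp(-i / 8.0)
    return 0.5 + 0.45 * ramp, 4.0 - 2.5 * ramp


@dataclass
class UnitSpec:
    """Ground-truth parameters of one synthetic unit."""

    unit_class: str = "RS"  # RS or FS
    region: str = "pStr"
    mean_rate: float = 5.0  # Hz, baseline r0
    tuning_center: float | None = None  # normalized distance; None = flat
    tuning_width: float = 0.1  # normalized distance (Gaussian sigma)
    tuning_gain: float = 3.0  # bump amplitude over baseline
    stim_gain: float = 1.0  # rate multiplier on Stim1 trials (>= 0)
    phase_kappa: float = 0.0  # von Mises concentration (>= 0)
    preferred_phase: float = 0.0  # degrees
    ref_region: str = "dLGN"  # oscillation the unit locks to
    ref_band: tuple = (2.0, 5.0)


@dataclass
class SynthConfig:
    n_sessions: int = 29
    trials_per_session: int = 40
    success_prob: np.ndarray | None = None  # per session, in [0.5, 1]
    reaction_time: np.ndarray | None = None  # per session mean, s
    zone_length: float = 100.0  # maze units
    arm_offset: float = 15.0  # lateral half-separation at zone end
    bifurcation_distance: float = 0.5  # normalized distance in (0, 1)
    trajectory_noise_sd: float = 0.5  # maze units, per tracking sample
    speed_profile: np.ndarray | None = None  # relative speed per distance bin
    timing_cv: float = 0.18  # log-normal CV of traversal durations
    approach_fraction: float = 0.2  # of reaction time, after zone exit
    iti: float = 10.0  # s between trials
    fs_track: float = 50.0  # Hz
    lfp_fs: float = 1250.0  # Hz
    band_4hz: tuple = (2.0, 5.0)
    band_theta: tuple = (6.0, 10.0)
    coherence_4hz: dict = field(
        default_factory=lambda: {pair: 0.3 for pair in REGION_PAIRS}
    )
    theta_amplitude: float = 1.0  # relative to the 4 Hz component
    theta_speed_gain: float = 0.01  # amplitude gain per (maze unit/s)
    noise_sd: float = 0.3  # white-noise floor, relative units
    lfp_scale: float = 200.0  # µV per relative unit
    rate_ceiling: float = 500.0  # Hz, hard intensity cap
    unit_specs: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self):
        if self.success_prob is None or self.reaction_time is None:
            sp, rt = default_learning_curve(self.n_sessions)
            if self.success_prob is None:
                self.success_prob = sp
            if self.reaction_time is None:
                self.reaction_time = rt
        self.success_prob = np.asarray(self.success_prob, float)
        self.reaction_time = np.asarray(self.reaction_time, float)
        self.validate()

    def validate(self):
        issues = []
        if self.success_prob.shape[0] != self.n_sessions:
            issues.append("success_prob must have one entry per session")
        if np.any(self.success_prob < 0) or np.any(self.success_prob > 1):
            issues.append("success probabilities must lie in [0, 1]")
        if np.any(self.reaction_time <= 0):
            issues.append("reaction times must be positive")
        if not 0.0 < self.bifurcation_distance < 1.0:
            issues.append(
                f"bifurcation_distance {self.bifurcation_distance} outside (0, 1)"
            )
        if self.trajectory_noise_sd < 0:
            issues.append("trajectory_noise_sd must be >= 0")
        for band in (self.band_4hz, self.band_theta):
            lo, hi = band
            if not 0 < lo < hi < self.lfp_fs / 2:
                issues.append(f"band {band} outside (0, fs/2)")
        if self.band_4hz[1] > self.band_theta[0]:
            issues.append("4 Hz and theta bands must not overlap")
        for pair, c in self.coherence_4hz.items():
            if not 0.0 <= c <= 1.0:
                issues.append(f"coherence target {c} for {pair} outside [0, 1]")
        for spec in self.unit_specs:
            if spec.mean_rate < 0 or spec.stim_gain < 0 or spec.phase_kappa < 0:
                issues.append(f"negative rate/gain/kappa in unit spec {spec}")
            if spec.region not in REGIONS or spec.ref_region not in REGIONS:
                issues.append(f"unknown region in unit spec {spec}")
        if issues:
            raise ValueError("invalid SynthConfig:\n  " + "\n  ".join(issues))

    def with_(self, **kwargs) -> "SynthConfig":
        return replace(self, **kwargs)


@dataclass
class GroundTruth:
    """What the generator actually programmed (for recovery tests)."""

    bifurcation_distance: float
    success_prob: float
    mean_reaction_time: float
    stage: str  # early/middle/late by learning-curve terciles
    coherence_4hz: dict = field(default_factory=dict)
    units: list = field(default_factory=list)  # UnitSpec per generated unit

    def as_dict(self) -> dict:
        return {
            "bifurcation_distance": self.bifurcation_distance,
            "success_prob": self.success_prob,
            "mean_reaction_time": self.mean_reaction_time,
            "stage": self.stage,
            "coherence_4hz": {"-".join(k): float(v)
                              for k, v in self.coherence_4hz.items()},
            "units": [vars(u).copy() for u in self.units],
        }


def session_stage(session_index: int, n_sessions: int) -> str:
    """Programmed stage label: terciles of the session sequence."""
    frac = session_index / max(n_sessions - 1, 1)
    if frac < 1 / 3:
        return "early"
    if frac < 2 / 3:
        return "middle"
    return "late"
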