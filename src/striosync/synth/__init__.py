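"""Synthetic session generator with known ground truth.

Every downstream estimator in the package has a matched generator setting
here, so parameter recovery can be tested end to end.  Fixing the seed
fixes every generated byte.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import yaml

from ..behavior import track_speed
from ..session import Session, write_session
from .config import GroundTruth, SynthConfig, UnitSpec, session_stage
from .behavior import gen_behavior, lateral_offset
from .lfp import gen_lfp, narrowband, solve_mixing_weights
from .spikes import FS_WAVE, gen_spikes, make_waveform

__all__ = [
    "SynthConfig", "UnitSpec", "GroundTruth", "session_stage",
    "gen_behavior", "gen_lfp", "gen_spikes", "gen_session",
    "default_unit_specs", "write_session_with_truth", "lateral_offset",
    "narrowband", "solve_mixing_weights", "make_waveform", "FS_WAVE",
]


def default_unit_specs(n_rs: int = 8, n_fs: int = 4, region: str = "pStr",
                       kappa: float = 2.0, preferred_phase: float = 180.0,
                       ref_region: str = "dLGN",
                       stim_gain: float = 1.0) -> list[UnitSpec]:
    """A small mixed population with spread-out tuning centers."""
    specs = []
    # RS rates are kept sparse (putative MSNs pause often, so their
    # PROP(ISI>2s) stays well above the tonically-active range)
    for i in range(n_rs):
        specs.append(UnitSpec(
            unit_class="RS", region=region,
            mean_rate=0.5 + 0.5 * (i % 4),
            tuning_center=(i + 0.5) / n_rs, tuning_width=0.12,
            tuning_gain=3.0, stim_gain=stim_gain, phase_kappa=kappa,
            preferred_phase=preferred_phase, ref_region=ref_region,
        ))
    for i in range(n_fs):
        specs.append(UnitSpec(
            unit_class="FS", region=region,
            mean_rate=12.0 + 4.0 * (i % 3),
            tuning_center=None, tuning_gain=0.0,
            stim_gain=stim_gain, phase_kappa=kappa / 2,
            preferred_phase=preferred_phase, ref_region=ref_region,
        ))
    return specs


def session_rng(cfg: SynthConfig, session_index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(cfg.seed) % 2**31, int(session_index)])
    )


def gen_session(cfg: SynthConfig, session_index: int = 0,
                coherence: dict | None = None):
    """Generate one complete synthetic session plus its ground truth."""
    rng = session_rng(cfg, session_index)
    trials, tracking = gen_behavior(cfg, session_index, rng)
    duration = float(trials["t_choice"].iloc[-1] + cfg.iti)
    speed_t, speed_v = track_speed(tracking, sigma=2.0)
    lfp_traces = gen_lfp(cfg, duration, rng, speed_t, speed_v,
                         coherence=coherence)
    units = gen_spikes(cfg, lfp_traces, tracking, trials, duration, rng)

    from ..session import LFPTrace
    session = Session(
        meta={
            "rat_id": "synthetic",
            "session_index": int(session_index),
            "fs_lfp": float(cfg.lfp_fs),
            "fs_track": float(cfg.fs_track),
            "zone_length": float(cfg.zone_length),
            "duration": duration,
        },
        trials=trials,
        tracking=tracking,
        units=units,
        lfp={r: LFPTrace(region=r, samples=s, fs=cfg.lfp_fs)
             for r, s in lfp_traces.items()},
    )
    truth = GroundTruth(
        bifurcation_distance=cfg.bifurcation_distance,
        success_prob=float(cfg.success_prob[session_index]),
        mean_reaction_time=float(cfg.reaction_time[session_index]),
        stage=session_stage(session_index, cfg.n_sessions),
        coherence_4hz=dict(coherence if coherence is not None
                           else cfg.coherence_4hz),
        units=list(cfg.unit_specs),
    )
    return session, truth


def write_session_with_truth(cfg: SynthConfig, session_index: int,
                             out_dir, coherence: dict | None = None) -> Path:
    """Write ``session_XXX.h5`` plus a YAML ground-truth sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    session, truth = gen_session(cfg, session_index, coherence=coherence)
    path = out_dir / f"session_{session_index:03d}.h5"
    write_session(session, path)
    sidecar = path.with_suffix(".truth.yaml")
    with open(sidecar, "w") as fh:
        yaml.safe_dump(truth.as_dict(), fh, sort_keys=True)
    return path
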