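"""Shared paths and settings for the numbered analysis drivers.

The drivers simulate a compact training cohort (9 sessions tiling three
learning stages), then run the pipeline stages over it.  Session HDF5
files live under scratch/ (bulky, regenerable); result tables under
results/.
"""

from pathlib import Path

import numpy as np

from striosync.synth import SynthConfig, default_unit_specs

ROOT = Path(__file__).resolve().parents[1]
SESSIONS_DIR = ROOT / "scratch" / "sessions"
RESULTS_DIR = ROOT / "results"

SEED = 20250920
N_SESSIONS = 9

#: late-stage sessions get stronger pStr-dLGN 4 Hz coupling
COHERENCE_BY_STAGE = {"early": 0.3, "middle": 0.4, "late": 0.6}


def cohort_config() -> SynthConfig:
    return SynthConfig(
        n_sessions=N_SESSIONS,
        trials_per_session=20,
        seed=SEED,
        iti=5.0,
        success_prob=np.linspace(0.55, 0.95, N_SESSIONS),
        reaction_time=np.linspace(3.5, 1.5, N_SESSIONS),
        unit_specs=default_unit_specs(n_rs=6, n_fs=3, kappa=2.0,
                                      preferred_phase=300.0,
                                      ref_region="dLGN"),
    )


def pipeline_config() -> dict:
    from striosync.pipeline import load_config

    cfg = load_config()
    cfg["io"]["sessions"] = str(SESSIONS_DIR)
    return cfg
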