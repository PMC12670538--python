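import numpy as np
import pytest

from striosync.synth import SynthConfig, default_unit_specs, gen_session


@pytest.fixture(scope="session")
def tiny_session():
    """One small but complete synthetic session (behavior+spikes+LFP)."""
    cfg = SynthConfig(
        n_sessions=2, trials_per_session=8, seed=42, iti=4.0,
        reaction_time=np.array([2.5, 2.0]),
        success_prob=np.array([0.8, 0.9]),
        unit_specs=default_unit_specs(n_rs=3, n_fs=2, kappa=2.0,
                                      preferred_phase=300.0),
    )
    session, truth = gen_session(cfg, 0)
    return session, truth, cfg
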