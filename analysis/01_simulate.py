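#!/usr/bin/env python
"""Simulate the training cohort: 9 sessions spanning three learning stages.

Success rate rises 0.55 -> 0.95 and reaction time falls 3.5 -> 1.5 s over
the cohort; every session carries tracked trajectories bifurcating at
normalized distance 0.5, RS/FS units phase-locked to the dLGN 4 Hz rhythm,
and three-region LFPs whose pStr-dLGN 4 Hz coherence is raised in the late
stage (0.3 -> 0.6).  Ground truth is written beside every session.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import COHERENCE_BY_STAGE, SESSIONS_DIR, cohort_config
from striosync.synth import session_stage, write_session_with_truth
from striosync.synth.config import REGION_PAIRS


def main():
    cfg = cohort_config()
    for i in range(cfg.n_sessions):
        stage = session_stage(i, cfg.n_sessions)
        base = COHERENCE_BY_STAGE[stage]
        coherence = {pair: 0.3 for pair in REGION_PAIRS}
        coherence[("pStr", "dLGN")] = base
        path = write_session_with_truth(cfg, i, SESSIONS_DIR,
                                        coherence=coherence)
        print(f"session {i} ({stage}, pStr-dLGN 4Hz coherence {base}): "
              f"{path.name}")
    print(f"\n{cfg.n_sessions} sessions under {SESSIONS_DIR}")


if __name__ == "__main__":
    main()
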