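#!/usr/bin/env python
"""Behavioral learning curve, judgment points, and stage clustering.

Computes per-session success rate, reaction time and the permutation-band
judgment point, then Ward-clusters session-set features into early/middle/
late stages.  Writes results/sessions.csv and results/stage_sets.csv.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS_DIR, SEED, SESSIONS_DIR, pipeline_config
from striosync.pipeline import (
    _session_paths,
    _write,
    config_hash,
    run_stages,
)
from striosync.session import read_session


def main():
    cfg = pipeline_config()
    sessions = [read_session(p) for p in _session_paths(cfg)]
    tables = run_stages(cfg, sessions, SEED)
    RESULTS_DIR.mkdir(exist_ok=True)
    chash = config_hash(cfg)
    for name, df in tables.items():
        _write(df, RESULTS_DIR / f"{name}.csv", chash, SEED)

    per = tables["sessions"]
    print(per[["session_index", "success_rate", "reaction_time_median",
               "judgment_distance", "stage"]].to_string(index=False))
    print(f"\nlearning curve: success {per.success_rate.iloc[0]:.2f} -> "
          f"{per.success_rate.iloc[-1]:.2f}, reaction time "
          f"{per.reaction_time_median.iloc[0]:.2f} -> "
          f"{per.reaction_time_median.iloc[-1]:.2f} s")
    print(f"judgment distance (programmed 0.5): mean "
          f"{per.judgment_distance.mean():.3f}")
    print(f"stages: {per.stage.tolist()}")


if __name__ == "__main__":
    main()
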