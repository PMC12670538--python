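#!/usr/bin/env python
"""Unit characterization: RS/FS labels, selectivity, spatial information.

Requires 02 (stage labels).  Writes results/units.csv and prints the label
confusion against generator ground truth plus population summaries.
"""

import sys
from pathlib import Path

import pandas as pd
import yaml

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import RESULTS_DIR, SEED, SESSIONS_DIR, pipeline_config
from striosync.pipeline import _session_paths, _write, config_hash, run_units
from striosync.session import read_session


def main():
    cfg = pipeline_config()
    paths = _session_paths(cfg)
    sessions = [read_session(p) for p in paths]
    stages = pd.read_csv(RESULTS_DIR / "sessions.csv")
    tables = run_units(cfg, sessions, stages, SEED)
    _write(tables["units"], RESULTS_DIR / "units.csv", config_hash(cfg), SEED)

    units = tables["units"]
    truth_cls = []
    for path, session in zip(paths, sessions):
        truth = yaml.safe_load(path.with_suffix(".truth.yaml").read_text())
        lookup = {f"u{k:03d}_{u['region']}": u["unit_class"]
                  for k, u in enumerate(truth["units"])}
        for uid in session.units:
            truth_cls.append((session.meta["session_index"], uid,
                              lookup[uid]))
    truth_df = pd.DataFrame(truth_cls, columns=["session_index", "unit_id",
                                                "true_class"])
    merged = units.merge(truth_df, on=["session_index", "unit_id"])
    acc = (merged["label"] == merged["true_class"]).mean()
    print(f"units: {len(units)}; RS/FS label accuracy vs ground truth: "
          f"{acc:.1%}")
    print("\nspatial information (bits/spike) by label:")
    print(units.groupby("label")["spatial_info_bits"]
          .median().to_string())
    sel = units.groupby("stage")["stimulus_selective"].mean()
    print(f"\nstimulus-selective fraction by stage:\n{sel.to_string()}")


if __name__ == "__main__":
    main()
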