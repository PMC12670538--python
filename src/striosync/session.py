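"""Session container and HDF5 persistence.

One :class:`Session` holds everything recorded on one day for one rat:
per-trial events, head tracking, sorted units with mean waveforms, and
LFP traces per region.  The on-disk layout is plain HDF5::

    /meta                  (attrs: rat_id, session_index, fs_lfp, fs_track,
                            zone_length, duration, schema_version)
    /trials/{stimulus,choice,correct,t_entry,t_exit,t_choice}
    /tracking/{t,x,y}
    /units/<id>            (attrs: region, fs_wave; datasets: spike_times,
                            mean_waveform)
    /lfp/<region>          (attrs: fs; dataset: samples)

Conventions: all timestamps are seconds on one session clock starting at 0;
positions are maze units with ``x`` the along-track coordinate (judgment
zone spans ``0 <= x <= zone_length``) and ``y`` the lateral coordinate;
normalized distance is ``x / zone_length`` clipped to [0, 1]; phases are
degrees in [0, 360).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

SCHEMA_VERSION = "1.0"
REGIONS = ("pStr", "dLGN", "VC")
STIMULI = ("Stim1", "Stim2")
CHOICES = ("left", "right")
#: Stimulus -> rewarded arm mapping of the task.
CORRECT_ARM = {"Stim1": "left", "Stim2": "right"}

TRIAL_COLUMNS = ("stimulus", "choice", "correct", "t_entry", "t_exit", "t_choice")


class SchemaError(ValueError):
    """Raised when a session file or object violates the schema.

    ``issues`` lists every failing field, not just the first.
    """

    def __init__(self, issues):
        self.issues = list(issues)
        super().__init__("session schema violation:\n  " + "\n  ".join(self.issues))


@dataclass
class LFPTrace:
    region: str
    samples: np.ndarray  # µV
    fs: float = 1250.0

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs


@dataclass
class Unit:
    unit_id: str
    region: str
    spike_times: np.ndarray  # s, sorted
    mean_waveform: np.ndarray  # µV
    fs_wave: float = 20000.0


@dataclass
class Session:
    meta: dict
    trials: pd.DataFrame
    tracking: pd.DataFrame  # columns t, x, y
    units: dict = field(default_factory=dict)
    lfp: dict = field(default_factory=dict)

    @property
    def zone_length(self) -> float:
        return float(self.meta["zone_length"])

    @property
    def fs_track(self) -> float:
        return float(self.meta["fs_track"])

    def normalized_distance(self, x: np.ndarray) -> np.ndarray:
        return np.clip(np.asarray(x, float) / self.zone_length, 0.0, 1.0)


def normalized_distance(x, zone_length):
    """Along-track position -> normalized distance in [0, 1]."""
    return np.clip(np.asarray(x, float) / float(zone_length), 0.0, 1.0)


def validate_session(session: Session) -> list[str]:
    """Return a list of schema issues (empty when valid)."""
    issues = []
    for key in ("rat_id", "session_index", "fs_lfp", "fs_track", "zone_length"):
        if key not in session.meta:
            issues.append(f"/meta missing attribute '{key}'")
    if session.trials is None or len(session.trials) == 0:
        issues.append("/trials missing or empty")
    else:
        for col in TRIAL_COLUMNS:
            if col not in session.trials.columns:
                issues.append(f"/trials missing column '{col}'")
        if set(TRIAL_COLUMNS) <= set(session.trials.columns):
            tr = session.trials
            if not (tr["t_entry"] < tr["t_exit"]).all():
                issues.append("/trials: t_entry < t_exit violated")
            if not (tr["t_exit"] <= tr["t_choice"]).all():
                issues.append("/trials: t_exit <= t_choice violated")
            bad_stim = ~tr["stimulus"].isin(STIMULI)
            if bad_stim.any():
                issues.append("/trials: stimulus outside {Stim1, Stim2}")
            bad_choice = ~tr["choice"].isin(CHOICES)
            if bad_choice.any():
                issues.append("/trials: choice outside {left, right}")
            if not bad_stim.any() and not bad_choice.any():
                expected = tr["stimulus"].map(CORRECT_ARM) == tr["choice"]
                if not (tr["correct"].astype(bool) == expected).all():
                    issues.append("/trials: correct flag inconsistent with "
                                  "stimulus->arm rule")
    if session.tracking is None or len(session.tracking) == 0:
        issues.append("/tracking missing or empty")
    else:
        for col in ("t", "x", "y"):
            if col not in session.tracking.columns:
                issues.append(f"/tracking missing column '{col}'")
        if "t" in session.tracking.columns:
            t = session.tracking["t"].to_numpy()
            if t.size > 1 and (np.diff(t) <= 0).any():
                issues.append("/tracking: t not strictly increasing")
    for uid, unit in session.units.items():
        st = np.asarray(unit.spike_times)
        if st.size > 1 and (np.diff(st) < 0).any():
            issues.append(f"/units/{uid}: spike_times not sorted")
        if unit.region not in REGIONS:
            issues.append(f"/units/{uid}: unknown region '{unit.region}'")
    for region, trace in session.lfp.items():
        if region not in REGIONS:
            issues.append(f"/lfp/{region}: unknown region")
        if not np.all(np.isfinite(trace.samples)):
            issues.append(f"/lfp/{region}: non-finite samples")
    # Soft check: declared duration vs LFP length.
    dur = session.meta.get("duration")
    if dur is not None:
        for region, trace in session.lfp.items():
            if abs(trace.samples.size - trace.fs * dur) > 1.0:
                warnings.warn(
                    f"/lfp/{region}: length {trace.samples.size} inconsistent "
                    f"with fs*duration = {trace.fs * dur:.1f} by > 1 sample",
                    stacklevel=2,
                )
    return issues


def write_session(session: Session, path) -> None:
    issues = validate_session(session)
    if issues:
        raise SchemaError(issues)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        for key, val in session.meta.items():
            meta.attrs[key] = val
        meta.attrs["schema_version"] = SCHEMA_VERSION
        tg = f.create_group("trials")
        for col in TRIAL_COLUMNS:
            data = session.trials[col].to_numpy()
            if data.dtype == object or data.dtype.kind in "U":
                data = np.asarray(data, dtype="S")
            tg.create_dataset(col, data=data)
        kg = f.create_group("tracking")
        for col in ("t", "x", "y"):
            kg.create_dataset(col, data=session.tracking[col].to_numpy())
        ug = f.create_group("units")
        for uid, unit in session.units.items():
            g = ug.create_group(uid)
            g.attrs["region"] = unit.region
            g.attrs["fs_wave"] = unit.fs_wave
            g.create_dataset("spike_times", data=np.asarray(unit.spike_times))
            g.create_dataset("mean_waveform", data=np.asarray(unit.mean_waveform))
        lg = f.create_group("lfp")
        for region, trace in session.lfp.items():
            g = lg.create_group(region)
            g.attrs["fs"] = trace.fs
            g.create_dataset("samples", data=np.asarray(trace.samples))


def read_session(path, validate: bool = True) -> Session:
    issues = []
    with h5py.File(path, "r") as f:
        for group in ("meta", "trials", "tracking"):
            if group not in f:
                issues.append(f"/{group} missing")
        if issues:
            raise SchemaError(issues)
        meta = dict(f["meta"].attrs)
        meta = {k: (v.item() if isinstance(v, np.generic) else v)
                for k, v in meta.items()}
        cols = {}
        for col in TRIAL_COLUMNS:
            if col in f["trials"]:
                data = f["trials"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
        trials = pd.DataFrame(cols)
        if "correct" in trials:
            trials["correct"] = trials["correct"].astype(bool)
        tracking = pd.DataFrame(
            {col: f["tracking"][col][()] for col in ("t", "x", "y")
             if col in f["tracking"]}
        )
        units = {}
        for uid in sorted(f.get("units", {})):
            g = f["units"][uid]
            units[uid] = Unit(
                unit_id=uid,
                region=str(g.attrs["region"]),
                spike_times=g["spike_times"][()],
                mean_waveform=g["mean_waveform"][()],
                fs_wave=float(g.attrs["fs_wave"]),
            )
        lfp = {}
        for region in sorted(f.get("lfp", {})):
            g = f["lfp"][region]
            lfp[region] = LFPTrace(region=region, samples=g["samples"][()],
                                   fs=float(g.attrs["fs"]))
    session = Session(meta=meta, trials=trials, tracking=tracking,
                      units=units, lfp=lfp)
    if validate:
        issues = validate_session(session)
        if issues:
            raise SchemaError(issues)
    return session
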