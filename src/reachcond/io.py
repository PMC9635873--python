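"""Trial-record CSV format, run configuration and run logs.

The on-disk format is a flat, human-inspectable CSV with one row per trial:

    participant_id, design, platform, clamp_dir, phase, trial,
    cs (tone|light|compound), clamp_deg (15|0|empty),
    hand_angle_deg, angle_50ms_deg, rt_ms, mt_ms

Angles are stored raw (unoriented, degrees, CCW-positive); orientation is an
analysis step, never baked into files. ``clamp_deg`` is empty exactly on
no-feedback (probe) trials. Time fields are milliseconds.
"""

from __future__ import annotations

import json
import platform as _platform
import time
import uuid
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .schedule import PROBE, Trial, TrialSchedule
from .synthetic import DESIGN_TABLE, ParticipantData

COLUMNS = [
    "participant_id", "design", "platform", "clamp_dir", "phase", "trial",
    "cs", "clamp_deg", "hand_angle_deg", "angle_50ms_deg", "rt_ms", "mt_ms",
]


class SchemaError(ValueError):
    pass


def participant_frame(data: ParticipantData) -> pd.DataFrame:
    df = data.records.copy()
    df.insert(0, "participant_id", data.participant_id)
    df.insert(1, "design", data.design)
    df.insert(2, "platform", data.platform)
    df.insert(3, "clamp_dir", data.clamp_dir)
    return df[COLUMNS]


def write_trials(cohort, path) -> None:
    """Write a cohort (or single participant) to the trial-record CSV."""
    if isinstance(cohort, ParticipantData):
        cohort = [cohort]
    frame = pd.concat([participant_frame(p) for p in cohort], ignore_index=True)
    frame.to_csv(path, index=False, float_format="%.6f")


def _schedule_from_rows(rows: pd.DataFrame, design: str) -> TrialSchedule:
    trials = []
    cs_plus = "tone"
    for _, row in rows.iterrows():
        cs = row["cs"]
        if cs == "compound":
            cs_set = frozenset({"tone", "light"})
        elif cs in ("tone", "light"):
            cs_set = frozenset({cs})
        else:
            raise SchemaError(f"unknown cs value {cs!r} at trial {row['trial']}")
        us = None if pd.isna(row["clamp_deg"]) else float(row["clamp_deg"])
        if row["phase"] == PROBE and us is not None:
            raise SchemaError(
                f"probe trial {row['trial']} carries clamp_deg={us}"
            )
        if us == 15.0 and cs in ("tone", "light"):
            cs_plus = cs
        trials.append(Trial(index=int(row["trial"]), phase=row["phase"],
                            cs_set=cs_set, us=us))
    return TrialSchedule(trials=trials, design=design, seed=-1, cs_plus=cs_plus)


def read_trials(path):
    """Read a trial-record CSV back into a list of ParticipantData.

    The header is keyed by name (column order is free); missing or extra
    columns raise :class:`SchemaError`.
    """
    df = pd.read_csv(path)
    missing = [c for c in COLUMNS if c not in df.columns]
    extra = [c for c in df.columns if c not in COLUMNS]
    if missing or extra:
        raise SchemaError(
            f"trial-record schema mismatch: missing={missing}, extra={extra}"
        )
    for col in ("hand_angle_deg", "angle_50ms_deg", "rt_ms", "mt_ms"):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            raise SchemaError(
                f"non-numeric {col} at file rows {[int(i) + 2 for i in bad[:5]]}"
            )
    cohort = []
    for pid, rows in df.groupby("participant_id", sort=False):
        rows = rows.sort_values("trial")
        if not (rows["trial"].to_numpy() == np.arange(1, len(rows) + 1)).all():
            raise SchemaError(
                f"participant {pid}: trial indices not contiguous 1-based"
            )
        design = rows["design"].iloc[0]
        if design not in DESIGN_TABLE:
            raise SchemaError(f"participant {pid}: unknown design {design!r}")
        schedule = _schedule_from_rows(rows, design)
        records = rows[["trial", "phase", "cs", "clamp_deg", "hand_angle_deg",
                        "angle_50ms_deg", "rt_ms", "mt_ms"]].reset_index(drop=True)
        cohort.append(ParticipantData(
            participant_id=str(pid), design=design,
            platform=rows["platform"].iloc[0],
            clamp_dir=rows["clamp_dir"].iloc[0],
            cs_assignment=schedule.cs_plus, schedule=schedule, records=records,
        ))
    return cohort


def schedule_frame(schedule: TrialSchedule) -> pd.DataFrame:
    """Schedule as a trial-record-style table (behavioral fields empty)."""
    return pd.DataFrame({
        "trial": [t.index for t in schedule.trials],
        "phase": [t.phase for t in schedule.trials],
        "cs": ["compound" if t.cs_set == {"tone", "light"} else next(iter(t.cs_set))
               for t in schedule.trials],
        "clamp_deg": schedule.us_array,
    })


# ---------------------------------------------------------------------------
# configuration and run logs


def load_config(path) -> dict:
    """YAML key-value configuration (sections map to nested dicts)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    return cfg


def write_resolved_config(cfg: dict, outdir) -> Path:
    """Write the fully resolved configuration beside a run's outputs."""
    out = Path(outdir) / "resolved_config.yaml"
    with open(out, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return out


def write_run_log(outdir, command: str, seed, extra: dict | None = None) -> Path:
    """Structured run log: run id, seeds, package/python versions."""
    from . import __version__

    log = {
        "run_id": uuid.uuid4().hex,
        "command": command,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "reachcond_version": __version__,
        "python": _platform.python_version(),
        "numpy": np.__version__,
    }
    if extra:
        log.update(extra)
    out = Path(outdir) / "run_log.json"
    with open(out, "w") as fh:
        json.dump(log, fh, indent=2)
    return out
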