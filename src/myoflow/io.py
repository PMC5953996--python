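"""File formats: per-patient TAC CSVs, truth/FFR tables, study config.

TAC CSV dialect: header ``frame_start_s,frame_duration_s,blood,global,lad,
lcx,rca``; one file per patient per state per modality, activity in kBq/mL,
RFC-4180 with dot decimals.  Unknown extra columns are tolerated with a
warning; structural problems (gaps, negative durations, missing columns)
raise with the offending row named.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .retention import RetentionParams
from .stats import Thresholds
from .tac import FrameSchedule, TimeActivityCurve
from .waterpet import WaterModelParams

TAC_COLUMNS = ("frame_start_s", "frame_duration_s",
               "blood", "global", "lad", "lcx", "rca")
_COL_TO_LABEL = {"blood": "BLOOD", "global": "GLOBAL",
                 "lad": "LAD", "lcx": "LCX", "rca": "RCA"}
_LABEL_TO_COL = {v: k for k, v in _COL_TO_LABEL.items()}


def read_tac_file(path: str | Path) -> dict[str, TimeActivityCurve]:
    """Parse one TAC CSV into {region label: TAC} (five regions)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in TAC_COLUMNS]
    if extra:
        warnings.warn(f"{path.name}: ignoring unknown column(s) {extra}",
                      stacklevel=2)
    if len(df) < 4:
        raise ValueError(f"{path.name}: need at least 4 frames, got {len(df)}")
    start = df["frame_start_s"].to_numpy(dtype=float)
    dur = df["frame_duration_s"].to_numpy(dtype=float)
    bad = np.flatnonzero(dur <= 0)
    if bad.size:
        raise ValueError(
            f"{path.name} row {bad[0] + 2}: frame_duration_s must be positive")
    gaps = np.flatnonzero(~np.isclose(start[1:], start[:-1] + dur[:-1], atol=1e-6))
    if gaps.size:
        raise ValueError(
            f"{path.name} row {gaps[0] + 3}: frames not contiguous "
            f"(expected start {start[gaps[0]] + dur[gaps[0]]:g} s)")
    schedule = FrameSchedule(start, dur)
    return {label: TimeActivityCurve(schedule, df[col].to_numpy(dtype=float),
                                     label=label)
            for col, label in _COL_TO_LABEL.items()}


def write_tac_file(tacs: dict[str, TimeActivityCurve], path: str | Path) -> None:
    """Write a {label: TAC} set in the CSV dialect (6 decimals, stable bytes)."""
    ref = tacs["BLOOD"].schedule
    cols = {"frame_start_s": ref.frame_start, "frame_duration_s": ref.frame_duration}
    for label, col in _LABEL_TO_COL.items():
        cols[col] = tacs[label].values
    df = pd.DataFrame({k: [f"{x:.6f}" for x in v] for k, v in cols.items()})
    df = df[list(TAC_COLUMNS)]
    df.to_csv(path, index=False)


def read_ffr_table(path: str | Path) -> pd.DataFrame:
    """FFR CSV: patient_id, territory, ffr (territory in LAD/LCX/RCA)."""
    df = pd.read_csv(path, dtype={"patient_id": str})
    for col in ("patient_id", "territory", "ffr"):
        if col not in df.columns:
            raise ValueError(f"{Path(path).name}: missing column {col!r}")
    return df[["patient_id", "territory", "ffr"]].assign(
        ffr=lambda d: d["ffr"].astype(float))


def read_truth_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str})
    num_cols = ["true_rest_mbf", "true_stress_mbf", "true_mfr", "ffr"]
    return df.assign(**{c: df[c].astype(float) for c in num_cols})


@dataclass
class StudyConfig:
    """End-to-end pipeline configuration; JSON round-trip stable."""

    tac_dir: str = "."
    ffr_path: str = "truth.csv"   # any CSV with patient_id, territory, ffr
    out_dir: str = "results"
    retention: RetentionParams = field(default_factory=RetentionParams)
    water: WaterModelParams = field(default_factory=WaterModelParams)
    thresholds: Thresholds = field(default_factory=Thresholds)
    log_level: str = "INFO"
    seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "StudyConfig":
        data = json.loads(text)
        if "retention" in data:
            data["retention"] = RetentionParams(**data["retention"])
        if "water" in data:
            w = dict(data["water"])
            for k in ("mbf_bounds", "ptf_bounds", "va_bounds"):
                if k in w:
                    w[k] = tuple(w[k])
            if "inits" in w:
                w["inits"] = tuple(tuple(x) for x in w["inits"])
            data["water"] = WaterModelParams(**w)
        if "thresholds" in data:
            data["thresholds"] = Thresholds(**data["thresholds"])
        return cls(**data)


def dump_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, trailing newline)."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     allow_nan=True) + "\n")
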