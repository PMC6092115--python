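"""Readers and writers for the delimited-text trial dialects.

Each trial is a CSV (UTF-8, decimal point, no thousands separators) with a
``time`` column plus the paradigm's channels, and a JSON sidecar of the same
stem carrying metadata (sampling rate, subject/condition labels, paradigm
parameters).  All readers reject NaN/Inf cells and verify that the time
column is consistent with the declared sampling rate.

Paradigm dialects
-----------------
walk     : time, acc_vertical           (+ optional walk_start/walk_stop marks)
step     : time, ml_force, ap_foot_disp (+ foot_length_cm, stepping_side, baseline_interval)
perturb  : time, Fx, Fy, Fz, Mx, My, Mz, meta5_ap, malleolus_ap, knee_ap,
           trochanter_ap, shoulder_ap   (+ perturbation_onset, origin_offset)
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .apa import StepTrial
from .core import InvalidParameterError, UniformTimeSeries
from .reactive import MARKER_NAMES, ForcePlateRecord, MarkerSet, PerturbationTrial

_FLOAT_FMT = "%.10g"

PERTURB_COLUMNS = ["time", "Fx", "Fy", "Fz", "Mx", "My", "Mz"] + [
    f"{m}_ap" for m in MARKER_NAMES
]


def sidecar_path(csv_path: str | Path) -> Path:
    return Path(csv_path).with_suffix(".json")


def _read_table(path: Path, columns: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"{path}: missing columns {missing}")
    arr = df[columns].to_numpy(dtype=float)
    if not np.all(np.isfinite(arr)):
        raise InvalidParameterError(f"{path}: non-finite cells are not allowed")
    return df

def _read_sidecar(csv_path: Path) -> dict:
    meta_path = sidecar_path(csv_path)
    if not meta_path.exists():
        raise InvalidParameterError(f"missing sidecar JSON {meta_path}")
    return json.loads(meta_path.read_text())


def _check_time(path: Path, time: np.ndarray, fs: float) -> float:
    """Validate uniform sampling against the declared rate; return t0."""
    if time.size < 2:
        raise InvalidParameterError(f"{path}: need >= 2 samples")
    steps = np.diff(time)
    if np.any(np.abs(steps - 1.0 / fs) > 0.25 / fs):
        raise InvalidParameterError(f"{path}: time column inconsistent with fs={fs:g} Hz")
    return float(time[0])


def _series(df: pd.DataFrame, col: str, fs: float, t0: float, units: str) -> UniformTimeSeries:
    return UniformTimeSeries(df[col].to_numpy(dtype=float), fs=fs, t0=t0, label=col, units=units)


# -- walk -------------------------------------------------------------------


def write_walk_trial(
    csv_path: str | Path, series: UniformTimeSeries, meta: dict
) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time": series.times(), "acc_vertical": series.values}).to_csv(
        csv_path, index=False, float_format=_FLOAT_FMT
    )
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_walk_trial(csv_path: str | Path) -> tuple[UniformTimeSeries, dict]:
    csv_path = Path(csv_path)
    meta = _read_sidecar(csv_path)
    fs = float(meta["fs"])
    df = _read_table(csv_path, ["time", "acc_vertical"])
    t0 = _check_time(csv_path, df["time"].to_numpy(dtype=float), fs)
    series = _series(df, "acc_vertical", fs, t0, meta.get("units", "m/s^2"))
    return series, meta


# -- step -------------------------------------------------------------------


def write_step_trial(csv_path: str | Path, trial: StepTrial, meta: dict) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame(
        {
            "time": trial.ml_force.times(),
            "ml_force": trial.ml_force.values,
            "ap_foot_disp": trial.ap_foot_disp.values,
        }
    ).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = dict(meta)
    meta.setdefault("fs", trial.ml_force.fs)
    meta.setdefault("foot_length_cm", trial.foot_length)
    meta.setdefault("stepping_side", trial.stepping_side)
    meta.setdefault("baseline_interval", list(trial.baseline_interval))
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_step_trial(csv_path: str | Path) -> tuple[StepTrial, dict]:
    csv_path = Path(csv_path)
    meta = _read_sidecar(csv_path)
    fs = float(meta["fs"])
    df = _read_table(csv_path, ["time", "ml_force", "ap_foot_disp"])
    t0 = _check_time(csv_path, df["time"].to_numpy(dtype=float), fs)
    trial = StepTrial(
        ml_force=_series(df, "ml_force", fs, t0, "N"),
        ap_foot_disp=_series(df, "ap_foot_disp", fs, t0, "cm"),
        foot_length=float(meta["foot_length_cm"]),
        baseline_interval=tuple(meta.get("baseline_interval", (t0, t0 + 1.0))),
        stepping_side=meta.get("stepping_side", "left"),
    )
    return trial, meta


# -- perturbation -----------------------------------------------------------


def write_perturbation_trial(
    csv_path: str | Path, trial: PerturbationTrial, meta: dict
) -> None:
    csv_path = Path(csv_path)
    cols = {
        "time": trial.plate.fz.times(),
        "Fx": trial.plate.fx.values,
        "Fy": trial.plate.fy.values,
        "Fz": trial.plate.fz.values,
        "Mx": trial.plate.mx.values,
        "My": trial.plate.my.values,
        "Mz": trial.plate.mz.values,
    }
    for m in MARKER_NAMES:
        cols[f"{m}_ap"] = trial.markers[m].values
    pd.DataFrame(cols).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = dict(meta)
    meta.setdefault("fs", trial.plate.fz.fs)
    meta.setdefault("perturbation_onset", trial.perturbation_onset)
    meta.setdefault("analysis_window", trial.analysis_window)
    meta.setdefault("origin_offset", list(trial.plate.origin_offset))
    sidecar_path(csv_path).write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")


def read_perturbation_trial(csv_path: str | Path) -> tuple[PerturbationTrial, dict]:
    csv_path = Path(csv_path)
    meta = _read_sidecar(csv_path)
    fs = float(meta["fs"])
    df = _read_table(csv_path, PERTURB_COLUMNS)
    t0 = _check_time(csv_path, df["time"].to_numpy(dtype=float), fs)
    plate = ForcePlateRecord(
        fx=_series(df, "Fx", fs, t0, "N"),
        fy=_series(df, "Fy", fs, t0, "N"),
        fz=_series(df, "Fz", fs, t0, "N"),
        mx=_series(df, "Mx", fs, t0, "N*m"),
        my=_series(df, "My", fs, t0, "N*m"),
        mz=_series(df, "Mz", fs, t0, "N*m"),
        origin_offset=tuple(meta.get("origin_offset", (0.0, 0.0, 0.0))),
    )
    markers = MarkerSet(
        **{m: _series(df, f"{m}_ap", fs, t0, "cm") for m in MARKER_NAMES}
    )
    trial = PerturbationTrial(
        markers=markers,
        plate=plate,
        perturbation_onset=float(meta["perturbation_onset"]),
        analysis_window=float(meta.get("analysis_window", 2.5)),
    )
    return trial, meta


def write_json(path: str | Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
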