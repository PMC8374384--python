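"""Delimited-text I/O for every input and output table.

All files are comma-separated UTF-8 with a mandatory header row and a
decimal point.  Readers validate the schema and report the first
offending file line (1-based, counting the header) on malformed data.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .gas_exchange import BreathSeries
from .incremental_test import LactateCurve
from .nirs_vascular import NirsTrace
from .training_load import TrainingSession

__all__ = [
    "SchemaError",
    "read_breath_csv",
    "write_breath_csv",
    "read_lactate_csv",
    "write_lactate_csv",
    "read_nirs_csv",
    "write_nirs_csv",
    "read_session_csv",
    "write_session_csv",
    "read_cohort_csv",
    "write_cohort_csv",
]

BREATH_COLUMNS = ["time_s", "vo2_ml_min", "vco2_ml_min", "ve_l_min"]
LACTATE_COLUMNS = ["stage", "power_w", "lactate_mmol_l"]
NIRS_COLUMNS = ["time_s", "sto2_pct"]
SESSION_COLUMNS = ["time_s", "power_w", "cadence_rpm", "hr_bpm"]
COHORT_COLUMNS = [
    "subject_id",
    "sex",
    "age",
    "baseline_vo2max_ml_min",
    "post_vo2max_ml_min",
]


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def _read_table(path, required: list[str], numeric: list[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        # round_trip parsing keeps written floats bit-identical on re-read
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # malformed CSV structure
        raise SchemaError(f"{path}: cannot parse CSV ({exc})") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 one-based
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {line}"
            )
        if coerced.isna().any():
            line = int(coerced.isna().idxmax()) + 2
            raise SchemaError(f"{path}: empty value in column {col!r} at line {line}")
        df[col] = coerced.astype(float)
    return df


def read_breath_csv(path) -> BreathSeries:
    df = _read_table(path, BREATH_COLUMNS, BREATH_COLUMNS)
    hr = None
    if "hr_bpm" in df.columns:
        hr = pd.to_numeric(df["hr_bpm"], errors="coerce").to_numpy()
        if np.isnan(hr).any():
            hr = None
    try:
        return BreathSeries(
            time=df["time_s"].to_numpy(),
            vo2=df["vo2_ml_min"].to_numpy(),
            vco2=df["vco2_ml_min"].to_numpy(),
            ve=df["ve_l_min"].to_numpy(),
            hr=hr,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_breath_csv(path, series: BreathSeries) -> None:
    df = pd.DataFrame(
        {
            "time_s": series.time,
            "vo2_ml_min": series.vo2,
            "vco2_ml_min": series.vco2,
            "ve_l_min": series.ve,
        }
    )
    if series.hr is not None:
        df["hr_bpm"] = series.hr
    df.to_csv(path, index=False)


def read_lactate_csv(path) -> LactateCurve:
    df = _read_table(path, LACTATE_COLUMNS, ["power_w", "lactate_mmol_l"])
    try:
        return LactateCurve(
            power=df["power_w"].to_numpy(), lactate=df["lactate_mmol_l"].to_numpy()
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_lactate_csv(path, curve: LactateCurve) -> None:
    pd.DataFrame(
        {
            "stage": np.arange(len(curve)),  # stage 0 = pre-exercise baseline
            "power_w": curve.power,
            "lactate_mmol_l": curve.lactate,
        }
    ).to_csv(path, index=False)


def read_nirs_csv(path, occlusion_start_s: float, cuff_release_s: float) -> NirsTrace:
    df = _read_table(path, NIRS_COLUMNS, NIRS_COLUMNS)
    try:
        return NirsTrace(
            time=df["time_s"].to_numpy(),
            sto2=df["sto2_pct"].to_numpy(),
            occlusion_start=occlusion_start_s,
            cuff_release=cuff_release_s,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_nirs_csv(path, trace: NirsTrace) -> None:
    pd.DataFrame({"time_s": trace.time, "sto2_pct": trace.sto2}).to_csv(
        path, index=False
    )


def read_session_csv(
    path, kind: str = "MICT", interval_windows=()
) -> TrainingSession:
    df = _read_table(path, SESSION_COLUMNS, SESSION_COLUMNS)
    try:
        return TrainingSession(
            time=df["time_s"].to_numpy(),
            power=df["power_w"].to_numpy(),
            hr=df["hr_bpm"].to_numpy(),
            cadence=df["cadence_rpm"].to_numpy(),
            kind=kind,
            interval_windows=tuple(tuple(w) for w in interval_windows),
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def write_session_csv(path, session: TrainingSession) -> None:
    pd.DataFrame(
        {
            "time_s": session.time,
            "power_w": session.power,
            "cadence_rpm": session.cadence
            if session.cadence is not None
            else np.full(len(session.time), np.nan),
            "hr_bpm": session.hr,
        }
    ).to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return _read_table(
        path, COHORT_COLUMNS, ["age", "baseline_vo2max_ml_min", "post_vo2max_ml_min"]
    )


def write_cohort_csv(path, cohort: pd.DataFrame) -> None:
    cohort.to_csv(path, index=False)
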