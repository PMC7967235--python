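"""Readers and writers for the timestamped CSV channels.

All four input channels are plain CSV with ISO 8601 timestamps in a single
patient-local timezone-naive clock.  Rows whose timestamp cannot be parsed
are dropped with a logged warning; a missing required column is a hard
format error.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    ACCEL_COLUMNS,
    DAILY_SCORE_COLUMNS,
    HR_COLUMNS,
    INGESTION_COLUMNS,
    PAIRING_COLUMNS,
    DailyScores,
    PatientStream,
    canonicalize_theta,
    derive_theta,
)

log = logging.getLogger("restaq.io")


class FormatError(ValueError):
    """Raised when an input file does not match the expected CSV schema."""


class EmptyStreamError(ValueError):
    """Raised when the accelerometer channel contains no usable rows."""


def _read_table(
    path: str | Path | None,
    required: list[str],
    optional: Iterable[str] = (),
    timestamp_cols: Iterable[str] = ("timestamp",),
) -> pd.DataFrame:
    columns = list(required) + [c for c in optional if c not in required]
    if path is None:
        return pd.DataFrame({c: pd.Series(dtype="object") for c in columns})
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    for col in timestamp_cols:
        if col not in df.columns:
            continue
        parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            log.warning("%s: dropped %d row(s) with unparseable %s", path, int(bad.sum()), col)
        df[col] = parsed
        df = df[df[col].notna()]
    return df.reset_index(drop=True)


def read_patient_stream(
    accel_path: str | Path,
    hr_path: Optional[str | Path] = None,
    pairing_path: Optional[str | Path] = None,
    ingestion_path: Optional[str | Path] = None,
    patient_id: str = "P001",
) -> PatientStream:
    """Load, validate and sort the four channels of one patient.

    ``theta_deg`` may be absent from the accelerometer file, in which case the
    posture angle is derived from the mean accelerations (the x-axis is
    calibrated along the longitudinal body axis).  Angles are canonicalized
    so that 0 means lying/horizontal.
    """
    accel = _read_table(
        accel_path,
        required=[c for c in ACCEL_COLUMNS if c != "theta_deg"],
        optional=["theta_deg"],
    )
    if accel.empty:
        raise EmptyStreamError(f"{accel_path}: no usable accelerometer rows")
    if "theta_deg" not in accel.columns or accel["theta_deg"].isna().all():
        accel["theta_deg"] = derive_theta(
            accel["ax"].to_numpy(float),
            accel["ay"].to_numpy(float),
            accel["az"].to_numpy(float),
        )
    accel["theta_deg"] = canonicalize_theta(accel["theta_deg"].to_numpy(float))
    accel = accel[ACCEL_COLUMNS].sort_values("timestamp", kind="stable").reset_index(drop=True)

    hr = _read_table(hr_path, required=HR_COLUMNS)
    hr = hr.sort_values("timestamp", kind="stable").reset_index(drop=True)

    pairing = _read_table(pairing_path, required=PAIRING_COLUMNS, timestamp_cols=("start", "end"))
    pairing = pairing.sort_values("start", kind="stable").reset_index(drop=True)

    ingestions = _read_table(ingestion_path, required=INGESTION_COLUMNS)
    ingestions = ingestions.sort_values("timestamp", kind="stable").reset_index(drop=True)

    return PatientStream(
        patient_id=patient_id, accel=accel, hr=hr, pairing=pairing, ingestions=ingestions
    )


def daily_scores_frame(patient_id: str, scores: Iterable[DailyScores]) -> pd.DataFrame:
    """Assemble per-day scores into the canonical output table."""
    rows = []
    for s in sorted(scores, key=lambda s: s.day_id):
        rows.append(
            {
                "patient_id": patient_id,
                "day": s.day_id.isoformat(),
                "lrp_start": s.lrp_start.isoformat() if s.lrp_start is not None else "",
                "lrp_duration_min": s.lrp_duration_min,
                "lrp_quality": s.lrp_quality,
                "quality_z": s.quality_z,
                "start_z": s.start_z,
                "duration_z": s.duration_z,
                "composite_z": s.composite_z,
                "ingestion_time_min": s.ingestion_time_min,
                "ingestion_z": s.ingestion_z,
            }
        )
    return pd.DataFrame(rows, columns=DAILY_SCORE_COLUMNS)


def write_daily_scores(frame: pd.DataFrame, path: str | Path) -> None:
    """Write the daily-scores table with a fixed column order.

    Floats are written with ``repr`` precision so a read-back round-trips to
    well below 1e-9 relative error.
    """
    out = frame.reindex(columns=DAILY_SCORE_COLUMNS)
    out.to_csv(path, index=False, float_format="%.12g")


def read_daily_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DAILY_SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df
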