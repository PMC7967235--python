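"""Partition each patient-day into 15-minute intervals and label them.

An interval is analyzable only if (1) the patch was never pairing with the
phone during it, (2) it holds at least ``min_accel_records`` per-minute
accelerometer records and (3) at least ``min_ecg_records`` heart-rate
records.  Non-analyzable intervals are MISSING.  An analyzable interval is
REST when strictly more than ``rest_fraction`` of its collected records have
a posture angle strictly below ``rest_angle_deg`` from horizontal, otherwise
ACTIVE.  The rest fraction is taken over the records actually collected
(10–15 of them), not over the nominal slot count.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import DayGrid, Interval15, PatientStream, State


def minute_is_rest(theta_deg: float, cfg: RunConfig) -> bool:
    """True when a per-minute record counts as rest (strict threshold)."""
    return bool(theta_deg < cfg.rest_angle_deg)


def is_analyzable(iv: Interval15, cfg: RunConfig) -> bool:
    """All three data-quality conditions, evaluated on interval counts."""
    return (
        not iv.pairing_overlap
        and iv.n_accel >= cfg.min_accel_records
        and iv.n_ecg >= cfg.min_ecg_records
    )


def classify_interval(iv: Interval15, cfg: RunConfig) -> State:
    """MISSING if not analyzable, else REST/ACTIVE by the strict >70% rule."""
    if not is_analyzable(iv, cfg):
        return State.MISSING
    return State.REST if iv.rest_minute_fraction > cfg.rest_fraction else State.ACTIVE


def _counts_per_interval(
    times: np.ndarray, day_start: np.datetime64, n_iv: int, iv_len_ns: int
) -> np.ndarray:
    """Histogram of timestamps over the interval grid, half-open bins."""
    offs = (times - day_start).astype("timedelta64[ns]").astype(np.int64)
    idx = offs // iv_len_ns
    inside = (idx >= 0) & (idx < n_iv)
    return np.bincount(idx[inside].astype(int), minlength=n_iv), idx, inside


def partition_day(
    stream: PatientStream, day_start: pd.Timestamp, cfg: RunConfig, day_id: dt.date | None = None
) -> DayGrid:
    """Build one labeled DayGrid for the window starting at ``day_start``.

    Interval membership is half-open ``[start, start + interval_minutes)``;
    pairing overlap is any non-zero intersection of a pairing span with the
    interval.
    """
    n_iv = cfg.intervals_per_day
    iv_len = pd.Timedelta(minutes=cfg.interval_minutes)
    iv_len_ns = iv_len.value
    start64 = np.datetime64(day_start, "ns")

    accel_t = stream.accel["timestamp"].to_numpy(dtype="datetime64[ns]")
    n_accel, accel_idx, accel_in = _counts_per_interval(accel_t, start64, n_iv, iv_len_ns)

    theta = stream.accel["theta_deg"].to_numpy(float)
    rest_min = theta < cfg.rest_angle_deg
    n_rest = np.bincount(
        accel_idx[accel_in & rest_min].astype(int), minlength=n_iv
    )

    if stream.hr.empty:
        n_ecg = np.zeros(n_iv, dtype=int)
    else:
        hr_t = stream.hr["timestamp"].to_numpy(dtype="datetime64[ns]")
        n_ecg, _, _ = _counts_per_interval(hr_t, start64, n_iv, iv_len_ns)

    overlap = np.zeros(n_iv, dtype=bool)
    if not stream.pairing.empty:
        iv_starts = start64 + np.arange(n_iv) * np.timedelta64(iv_len_ns, "ns")
        iv_ends = iv_starts + np.timedelta64(iv_len_ns, "ns")
        for ps, pe in zip(
            stream.pairing["start"].to_numpy(dtype="datetime64[ns]"),
            stream.pairing["end"].to_numpy(dtype="datetime64[ns]"),
        ):
            overlap |= (iv_starts < pe) & (ps < iv_ends)

    all_idx = np.arange(len(accel_t))
    intervals: list[Interval15] = []
    for i in range(n_iv):
        members = all_idx[accel_in & (accel_idx == i)]
        frac = n_rest[i] / n_accel[i] if n_accel[i] > 0 else np.nan
        iv = Interval15(
            start=day_start + i * iv_len,
            state=State.MISSING,
            n_accel=int(n_accel[i]),
            n_ecg=int(n_ecg[i]),
            pairing_overlap=bool(overlap[i]),
            rest_minute_fraction=float(frac) if n_accel[i] > 0 else float("nan"),
            record_idx=members,
        )
        iv.state = classify_interval(iv, cfg)
        if iv.state == State.MISSING:
            iv.rest_minute_fraction = float("nan")
        intervals.append(iv)

    if day_id is None:
        day_id = day_start.date()
    return DayGrid(day_id=day_id, start=day_start, intervals=intervals)


def day_starts_for_stream(stream: PatientStream, cfg: RunConfig) -> list[pd.Timestamp]:
    """Day-window starts (at the configured boundary clock time) covering all
    accelerometer data of the stream."""
    if stream.accel.empty:
        return []
    boundary = pd.Timedelta(minutes=cfg.day_boundary_minutes)
    first = stream.accel["timestamp"].iloc[0]
    last = stream.accel["timestamp"].iloc[-1]
    first_day = (first - boundary).normalize()
    last_day = (last - boundary).normalize()
    days = pd.date_range(first_day, last_day, freq="D")
    return [d + boundary for d in days]


def build_day_grids(stream: PatientStream, cfg: RunConfig) -> list[DayGrid]:
    """Labeled DayGrids for every day window touched by the stream's data.

    The day label is the calendar date on which the window starts (noon of
    day D opens the window labeled D by default).
    """
    grids = []
    for start in day_starts_for_stream(stream, cfg):
        grids.append(partition_day(stream, start, cfg, day_id=start.date()))
    return grids


def grids_to_frame(grids: list[DayGrid]) -> pd.DataFrame:
    """Flatten grids into the interval dump table."""
    rows = []
    for g in grids:
        for iv in g.intervals:
            rows.append(
                {
                    "day": g.day_id.isoformat(),
                    "interval_start": iv.start.isoformat(),
                    "state": iv.state.code,
                    "n_accel": iv.n_accel,
                    "n_ecg": iv.n_ecg,
                    "rest_fraction": iv.rest_minute_fraction,
                }
            )
    return pd.DataFrame(
        rows, columns=["day", "interval_start", "state", "n_accel", "n_ecg", "rest_fraction"]
    )
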