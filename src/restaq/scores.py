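"""Per-patient standardised rest metrics and ingestion metrics.

Each day's LRP quality, start time (minutes from the day-window boundary)
and duration are turned into z-scores against the patient's own mean and
sample SD across days.  The composite rest score is the sum of the three
absolute z-scores — a magnitude of deviation from the patient's typical
rest.  Ingestion events yield an overall ingestion rate and a daily
ingestion-time z-score; single-day outliers in the composite score are
matched to ingestion-time outliers within a configurable day lag.
"""

from __future__ import annotations

import datetime as dt
import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .types import PatientStream

log = logging.getLogger("restaq.scores")


def zscore_series(values: pd.Series, ddof: int = 1) -> pd.Series:
    """Standardise a per-day series against its own mean and SD.

    Sample SD (``ddof=1``) by default.  A constant series maps to all-zero
    z-scores with a logged warning; fewer than two non-missing values yield
    an all-NaN result.
    """
    v = values.dropna().astype(float)
    out = pd.Series(np.nan, index=values.index, dtype=float)
    if len(v) < 2:
        return out
    sd = v.std(ddof=ddof)
    if sd == 0 or not np.isfinite(sd):
        log.warning("constant series: z-scores set to 0")
        out[v.index] = 0.0
        return out
    out[v.index] = (v - v.mean()) / sd
    return out


def composite_rest(quality_z: float, start_z: float, duration_z: float) -> float:
    """|quality z| + |start z| + |duration z| for one day's rest period."""
    return abs(quality_z) + abs(start_z) + abs(duration_z)


def ingestion_days(stream: PatientStream) -> list[dt.date]:
    """Distinct calendar days with a recorded ingestion (duplicates collapse)."""
    if stream.ingestions.empty:
        return []
    return sorted(stream.ingestions["timestamp"].dt.date.unique())


def ingestion_rate(stream: PatientStream) -> float:
    """Fraction of regimen days with a recorded ingestion.

    The regimen span runs from the first day with patch data through the
    last day with an ingestion record, inclusive, assuming a once-daily
    regimen.  With no ingestion events the rate is 0 over the patch span.
    """
    patch = stream.patch_dates()
    if not patch:
        raise ValueError("no patch data: regimen span undefined")
    days = ingestion_days(stream)
    if not days:
        log.warning("patient %s: no ingestion events; rate 0", stream.patient_id)
        return 0.0
    span = (days[-1] - patch[0]).days + 1
    if span <= 0:
        raise ValueError("last ingestion precedes first patch-data day")
    return len([d for d in days if d >= patch[0]]) / span


def ingestion_times(stream: PatientStream) -> pd.Series:
    """Clock time of each ingestion day's (earliest) dose, minutes from midnight."""
    if stream.ingestions.empty:
        return pd.Series(dtype=float)
    ts = stream.ingestions["timestamp"]
    first = ts.groupby(ts.dt.date).min()
    minutes = first.dt.hour * 60 + first.dt.minute + first.dt.second / 60.0
    minutes.index = pd.Index(first.index, name="day")
    return minutes.astype(float)


def ingestion_time_z(stream: PatientStream, ddof: int = 1) -> pd.Series:
    """Daily ingestion clock times standardised within the patient."""
    times = ingestion_times(stream)
    if len(times) < 2:
        return pd.Series(dtype=float)
    return zscore_series(times, ddof=ddof)


def _single_day_outliers(
    series: pd.Series, threshold: float, two_sided: bool, strict_single: bool
) -> list[dt.date]:
    """Days whose value crosses the threshold while neighbours do not."""
    s = series.dropna()
    mag = s.abs() if two_sided else s
    flagged = mag > threshold
    days = []
    by_day = dict(zip(s.index, flagged))
    for day, is_out in by_day.items():
        if not is_out:
            continue
        if strict_single:
            neighbours = (day - dt.timedelta(days=1), day + dt.timedelta(days=1))
            if any(by_day.get(n, False) for n in neighbours):
                continue
        days.append(day)
    return sorted(days)


def outlier_coincidences(
    composite: pd.Series,
    ingestion_z: pd.Series,
    cfg: RunConfig,
) -> list[tuple[dt.date, dt.date]]:
    """Pairs of (rest-outlier day, ingestion-outlier day) within the day lag.

    A rest outlier is a day whose composite score is unusually large for
    the patient: by default the composite series is itself standardised and
    a one-sided z above ``outlier_z`` flags the day (the composite sums
    three |z| terms, so its typical value is well above any fixed
    threshold).  An ingestion outlier has |ingestion-time z| above the
    threshold.  With the single-day rule on (default), a day only counts
    when its calendar neighbours are not themselves outliers.
    """
    if cfg.composite_outlier_mode == "zscore":
        rest_series = zscore_series(composite, ddof=cfg.sd_ddof_score)
    else:
        rest_series = composite
    rest_days = _single_day_outliers(
        rest_series, cfg.outlier_z, two_sided=False, strict_single=cfg.single_day_outliers
    )
    ing_days = _single_day_outliers(
        ingestion_z, cfg.outlier_z, two_sided=True, strict_single=cfg.single_day_outliers
    )
    pairs = []
    for dr in rest_days:
        for di in ing_days:
            if abs((dr - di).days) <= cfg.outlier_lag_days:
                pairs.append((dr, di))
    return sorted(pairs)
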