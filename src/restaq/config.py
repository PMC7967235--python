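"""Run-time configuration for the rest-quality pipeline.

Every threshold that the algorithm uses lives here as a default rather than a
constant buried in code, so sensitivity analyses can vary any of them from a
single JSON file or CLI flag.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

from pydantic import BaseModel, Field, field_validator


def parse_clock(value: str) -> int:
    """Parse an ``HH:MM`` clock string into minutes from midnight."""
    hh, mm = value.split(":")
    minutes = int(hh) * 60 + int(mm)
    if not 0 <= minutes < 24 * 60:
        raise ValueError(f"clock time out of range: {value!r}")
    return minutes


class RunConfig(BaseModel):
    """All tunable parameters of the rest-quality pipeline.

    Attributes
    ----------
    rest_angle_deg:
        A per-minute accelerometer record is classified as rest when its
        posture angle is strictly less than this many degrees from horizontal.
    interval_minutes:
        Length of the non-overlapping data-quality intervals (minutes).
    rest_fraction:
        An analyzable interval is REST when strictly more than this fraction
        of its collected records are rest minutes.
    min_accel_records:
        Minimum accelerometer records for an interval to be analyzable.
    min_ecg_records:
        Minimum ECG (heart-rate) records for an interval to be analyzable.
    gap_search_intervals:
        Maximum gap (in intervals) bridged when extending the longest
        continuous rest period.
    min_rescue_run:
        Minimum length of a candidate rest run annexed across a gap that
        contains a single active interval.
    rolling_window_minutes:
        Width of the rolling feature windows within each interval.
    day_boundary_clock_time:
        Clock time at which one "day" ends and the next begins.  Noon keeps a
        night's sleep inside a single day window.
    outlier_z:
        |z| threshold used when flagging daily outliers.
    outlier_lag_days:
        Maximum day offset when pairing rest outliers with ingestion-time
        outliers.
    kmeans_restarts:
        Number of k-means restarts (``n_init``).
    rng_seed:
        Seed for every stochastic step (k-means initialisation).
    two_active_blocks:
        If True (default), a bridging gap containing two or more active
        intervals blocks annexation; if False only three or more block.
    iterative_extension:
        If True (default) the extension scan restarts from the new period
        edge after every annexation; if False a single pass per end is made.
    sd_ddof_feature:
        Delta degrees of freedom for the rolling-window SD feature
        (0 = population SD over the 3 points).
    sd_ddof_score:
        Delta degrees of freedom for the per-patient z-score SD
        (1 = sample SD).
    fit_scope:
        ``"lrp"`` fits the rest-reference clustering on windows inside the
        longest rest periods only (default); ``"all-windows"`` fits on every
        analyzable interval's windows.
    composite_outlier_mode:
        ``"zscore"`` (default) standardises the composite series within the
        patient and flags days with one-sided z above ``outlier_z``; the
        composite is a sum of three |z| terms whose typical value is well
        above 2, so flagging must be relative to the patient's own
        composite distribution.  ``"threshold"`` compares the raw composite
        to ``outlier_z`` directly.
    single_day_outliers:
        Require an outlier day's neighbours to be non-outliers before the day
        participates in coincidence matching.
    min_eligible_days:
        Minimum number of distinct days with patch data for a patient to be
        included in cohort metrics.
    """

    rest_angle_deg: float = 30.0
    interval_minutes: int = 15
    rest_fraction: float = 0.70
    min_accel_records: int = 10
    min_ecg_records: int = 2
    gap_search_intervals: int = 5
    min_rescue_run: int = 4
    rolling_window_minutes: int = 3
    day_boundary_clock_time: str = "12:00"
    outlier_z: float = 2.0
    outlier_lag_days: int = 1
    kmeans_restarts: int = 10
    rng_seed: int = 0
    two_active_blocks: bool = True
    iterative_extension: bool = True
    sd_ddof_feature: int = 0
    sd_ddof_score: int = 1
    fit_scope: Literal["lrp", "all-windows"] = "lrp"
    composite_outlier_mode: Literal["zscore", "threshold"] = "zscore"
    single_day_outliers: bool = True
    min_eligible_days: int = 7

    @field_validator(
        "rest_angle_deg",
        "interval_minutes",
        "min_accel_records",
        "min_ecg_records",
        "gap_search_intervals",
        "min_rescue_run",
        "rolling_window_minutes",
        "outlier_z",
        "kmeans_restarts",
        "min_eligible_days",
    )
    @classmethod
    def _positive(cls, v):
        if v <= 0:
            raise ValueError("threshold must be positive")
        return v

    @field_validator("rest_fraction")
    @classmethod
    def _fraction(cls, v: float) -> float:
        if not 0.0 < v < 1.0:
            raise ValueError("rest_fraction must lie in (0, 1)")
        return v

    @field_validator("day_boundary_clock_time")
    @classmethod
    def _clock(cls, v: str) -> str:
        parse_clock(v)
        return v

    @property
    def day_boundary_minutes(self) -> int:
        return parse_clock(self.day_boundary_clock_time)

    @property
    def intervals_per_day(self) -> int:
        return 24 * 60 // self.interval_minutes

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(self.model_dump_json(indent=2) + "\n")

    def config_hash(self) -> str:
        import hashlib

        return hashlib.sha256(
            self.model_dump_json().encode()
        ).hexdigest()[:12]
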