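"""Domain containers shared across the pipeline.

Per-minute accelerometer summaries, 5-minute heart-rate records, patch
pairing spans and ingestion events are carried as pandas DataFrames inside a
:class:`PatientStream`; the remaining classes are light results containers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np
import pandas as pd

#: Canonical column sets of the tabular channels.
ACCEL_COLUMNS = ["timestamp", "steps", "ax", "ay", "az", "theta_deg"]
HR_COLUMNS = ["timestamp", "mean_hr"]
PAIRING_COLUMNS = ["start", "end"]
INGESTION_COLUMNS = ["timestamp"]

DAILY_SCORE_COLUMNS = [
    "patient_id",
    "day",
    "lrp_start",
    "lrp_duration_min",
    "lrp_quality",
    "quality_z",
    "start_z",
    "duration_z",
    "composite_z",
    "ingestion_time_min",
    "ingestion_z",
]


class State(IntEnum):
    """Label of a 15-minute interval."""

    REST = 0
    ACTIVE = 1
    MISSING = 2

    @property
    def code(self) -> str:
        return {State.REST: "R", State.ACTIVE: "A", State.MISSING: "M"}[self]


def derive_theta(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Posture angle (degrees from horizontal) from mean accelerations.

    The patch calibrates its x-axis along the longitudinal body axis, so the
    inclination of that axis relative to gravity gives the body's tilt:
    ``theta = |asin(a_x / ||a||)|`` in degrees, 0 = lying, 90 = upright.
    Zero-norm rows yield NaN.
    """
    norm = np.sqrt(ax**2 + ay**2 + az**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.clip(np.where(norm > 0, ax / norm, np.nan), -1.0, 1.0)
    return np.abs(np.degrees(np.arcsin(ratio)))


def canonicalize_theta(theta: np.ndarray) -> np.ndarray:
    """Fold posture angles into [0, 180] with 0 = horizontal/lying."""
    return np.abs(np.asarray(theta, dtype=float)) % 360.0 % 180.0


@dataclass
class PatientStream:
    """All recorded channels for one patient, each sorted by time.

    ``accel`` holds one row per minute with columns ``timestamp, steps, ax,
    ay, az, theta_deg``; ``hr`` one row per 5 minutes; ``pairing`` spans with
    ``start, end``; ``ingestions`` one timestamp per recorded dose event.
    """

    patient_id: str
    accel: pd.DataFrame
    hr: pd.DataFrame
    pairing: pd.DataFrame
    ingestions: pd.DataFrame

    def patch_dates(self) -> list[dt.date]:
        """Distinct calendar dates carrying accelerometer data."""
        if self.accel.empty:
            return []
        return sorted(self.accel["timestamp"].dt.date.unique())

    def n_patch_days(self) -> int:
        return len(self.patch_dates())

    def is_eligible(self, min_days: int = 7) -> bool:
        """Patients need a minimum number of days with patch data before
        per-patient statistics (z-scores, clustering) are meaningful."""
        return self.n_patch_days() >= min_days


@dataclass
class Interval15:
    """One data-quality interval with its classification inputs."""

    start: pd.Timestamp
    state: State
    n_accel: int
    n_ecg: int
    pairing_overlap: bool
    rest_minute_fraction: float  # NaN when MISSING
    record_idx: np.ndarray = field(default_factory=lambda: np.empty(0, int))


@dataclass
class DayGrid:
    """A single day window partitioned into contiguous intervals."""

    day_id: dt.date
    start: pd.Timestamp
    intervals: list[Interval15]

    @property
    def states(self) -> list[State]:
        return [iv.state for iv in self.intervals]


@dataclass
class RestPeriod:
    """A day's longest rest period: an inclusive interval-index span."""

    day_id: dt.date
    span: tuple[int, int]  # inclusive indices into the DayGrid
    start_time: pd.Timestamp
    duration_min: int
    rest_indices: list[int]  # REST intervals inside the span (scored)
    n_bridged_missing: int = 0
    n_bridged_active: int = 0


@dataclass
class ClusterModel:
    """Per-patient normalisation ranges plus rest-reference clustering.

    ``centroid_rr`` is the rest-reference centroid (mean posture angle
    nearest horizontal); ``centroid_dfr`` the deviation-from-rest centroid.
    Coordinates are in min–max normalised feature space.
    """

    feature_names: list[str]
    mins: np.ndarray
    maxs: np.ndarray
    centroid_rr: np.ndarray
    centroid_dfr: np.ndarray
    rr_label_rule: str
    theta_index: int = 1

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
            "centroid_rr": self.centroid_rr.tolist(),
            "centroid_dfr": self.centroid_dfr.tolist(),
            "rr_label_rule": self.rr_label_rule,
            "theta_index": self.theta_index,
        }


@dataclass
class DailyScores:
    """Standardised rest metrics for one patient-day."""

    day_id: dt.date
    lrp_start: Optional[pd.Timestamp] = None
    lrp_duration_min: Optional[float] = None
    lrp_quality: Optional[float] = None
    quality_z: Optional[float] = None
    start_z: Optional[float] = None
    duration_z: Optional[float] = None
    composite_z: Optional[float] = None
    ingestion_time_min: Optional[float] = None
    ingestion_z: Optional[float] = None


@dataclass
class PatientSummary:
    """Whole-regimen roll-up for one patient."""

    patient_id: str
    ingestion_rate: float
    regimen_days: int
    mean_composite: Optional[float]
    n_coincidences: int
    coincidences: list[tuple[dt.date, dt.date]] = field(default_factory=list)
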