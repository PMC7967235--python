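"""Shared fixtures: configs, hand-built streams, and a cached simulated patient."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from restaq.config import RunConfig
from restaq.pipeline import run_patient
from restaq.synthetic import SimConfig, simulate_patient
from restaq.types import PatientStream


@pytest.fixture
def cfg() -> RunConfig:
    return RunConfig()


def make_stream(
    accel_rows=None,
    hr_rows=None,
    pairing_rows=None,
    ingestion_times=None,
    patient_id="T001",
) -> PatientStream:
    """Build a PatientStream from plain tuples.

    ``accel_rows``: (timestamp, steps, ax, ay, az, theta_deg) tuples.
    ``hr_rows``: (timestamp, mean_hr).  ``pairing_rows``: (start, end).
    """
    accel = pd.DataFrame(
        accel_rows or [],
        columns=["timestamp", "steps", "ax", "ay", "az", "theta_deg"],
    )
    if len(accel):
        accel["timestamp"] = pd.to_datetime(accel["timestamp"])
    hr = pd.DataFrame(hr_rows or [], columns=["timestamp", "mean_hr"])
    if len(hr):
        hr["timestamp"] = pd.to_datetime(hr["timestamp"])
    pairing = pd.DataFrame(pairing_rows or [], columns=["start", "end"])
    if len(pairing):
        pairing["start"] = pd.to_datetime(pairing["start"])
        pairing["end"] = pd.to_datetime(pairing["end"])
    ingestions = pd.DataFrame(
        {"timestamp": pd.to_datetime(ingestion_times or [])}
    )
    return PatientStream(
        patient_id=patient_id, accel=accel, hr=hr, pairing=pairing, ingestions=ingestions
    )


def minute_block(start, n, theta=5.0, ax=0.0, ay=0.0, az=1.0, steps=0):
    """n consecutive per-minute accel rows starting at ``start``."""
    t0 = pd.Timestamp(start)
    return [
        (t0 + pd.Timedelta(minutes=i), steps, ax, ay, az, theta) for i in range(n)
    ]


def hr_block(start, n_minutes, hr=60.0):
    """Heart-rate rows every 5 minutes across ``n_minutes``."""
    t0 = pd.Timestamp(start)
    return [
        (t0 + pd.Timedelta(minutes=i), hr) for i in range(0, n_minutes, 5)
    ]


@pytest.fixture(scope="session")
def sim_patient():
    """One default 10-day synthetic patient, seed 0 (shared, read-only)."""
    return simulate_patient(SimConfig(n_days=10), seed=0)


@pytest.fixture(scope="session")
def sim_result(sim_patient):
    stream, truth = sim_patient
    return run_patient(stream, RunConfig(rng_seed=0)), truth
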