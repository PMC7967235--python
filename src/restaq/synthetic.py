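"""Synthetic patch-data generator with ground truth.

Emulates the wearable patch's channels — per-minute accelerometer summaries
(steps, mean a_x/a_y/a_z in g, posture angle), a 5-minute mean heart rate,
app-pairing spans and once-daily ingestion events — for a patient with a
known nightly rest schedule.  During rest the posture angle hugs horizontal
and the (a_y, a_z) vector sits on the 1-g circle plus sensor noise; during
activity the longitudinal axis carries gravity and steps accumulate.
Missing spans blank the channels, awakenings interrupt rest with short
active blocks, and designated days can be made restless, rest-disrupted or
dose-shifted to plant known outliers.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .config import parse_clock
from .types import ACCEL_COLUMNS, HR_COLUMNS, INGESTION_COLUMNS, PAIRING_COLUMNS, PatientStream


class SimConfig(BaseModel):
    """Ground-truth parameters of one simulated patient.

    Clock strings are ``HH:MM``.  Rest blocks start around
    ``rest_start_clock`` each night and last ``rest_duration_mean_min`` on
    average; awakenings are short active blocks inside the rest span.
    ``restless_days`` amplify movement noise without breaking the rest
    classification; ``rest_disrupt_days`` shift and shorten the rest block;
    ``dose_outlier_days`` shift that day's dose time by
    ``dose_outlier_shift_sd`` standard deviations.
    """

    n_days: int = Field(default=10, ge=1)
    start_date: str = "2021-03-01"
    rest_start_clock: str = "23:00"
    rest_start_sd_min: float = Field(default=30.0, ge=0)
    rest_duration_mean_min: float = 480.0
    rest_duration_sd_min: float = Field(default=45.0, ge=0)
    awakening_rate: float = Field(default=1.0, ge=0)
    awakening_min_min: int = 1
    awakening_max_min: int = 20
    awakening_mean_min: float = Field(default=3.0, gt=0)
    theta_rest_mean_deg: float = 5.0
    theta_active_mean_deg: float = 80.0
    theta_jitter_sd_deg: float = Field(default=8.0, ge=0)
    accel_noise_sd_g: float = Field(default=0.05, ge=0)
    missing_span_rate: float = Field(default=0.1, ge=0, le=1)
    missing_len_min_min: int = 30
    missing_len_max_min: int = 90
    pairing_daily: bool = True
    pairing_len_min: int = 5
    adherence_prob: float = Field(default=0.9, ge=0, le=1)
    dose_days: Optional[list[int]] = None  # explicit day indices override adherence_prob
    dose_time_clock: str = "09:00"
    dose_time_sd_min: float = Field(default=30.0, ge=0)
    dose_outlier_days: list[int] = Field(default_factory=list)
    dose_outlier_shift_sd: float = 4.0
    restless_days: list[int] = Field(default_factory=list)
    restless_theta_factor: float = 2.5
    restless_noise_factor: float = 6.0
    restless_awakening_rate: float = 4.0
    rest_disrupt_days: list[int] = Field(default_factory=list)
    rest_disrupt_start_shift_min: float = 240.0
    rest_disrupt_duration_cut_min: float = 240.0
    day_boundary_clock_time: str = "12:00"

    def base_date(self) -> dt.date:
        return dt.date.fromisoformat(self.start_date)


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    rest_blocks: dict[dt.date, tuple[pd.Timestamp, pd.Timestamp]]
    dose_times: dict[dt.date, Optional[pd.Timestamp]]
    minute_labels: pd.Series  # index: minute timestamps; values: rest/active/missing
    restless_days: list[dt.date] = field(default_factory=list)
    disrupted_days: list[dt.date] = field(default_factory=list)


def _day_window_start(cfg: SimConfig, day_index: int) -> pd.Timestamp:
    return pd.Timestamp(cfg.base_date() + dt.timedelta(days=day_index)) + pd.Timedelta(
        minutes=parse_clock(cfg.day_boundary_clock_time)
    )


def simulate_patient(
    cfg: SimConfig, seed: int = 0, patient_id: str = "SIM-001"
) -> tuple[PatientStream, GroundTruth]:
    """Generate one patient's four channels plus ground truth.

    Deterministic for a given (config, seed): the same inputs produce
    byte-identical CSVs when written.
    """
    rng = np.random.default_rng(seed)
    boundary_min = parse_clock(cfg.day_boundary_clock_time)
    t0 = _day_window_start(cfg, 0)
    n_min = cfg.n_days * 24 * 60
    minutes = t0 + pd.to_timedelta(np.arange(n_min), unit="min")

    # 0 = active, 1 = rest, 2 = missing (labels on the minute grid)
    label = np.zeros(n_min, dtype=np.int8)
    rest_blocks: dict[dt.date, tuple[pd.Timestamp, pd.Timestamp]] = {}
    restless = np.zeros(n_min, dtype=bool)

    rest_start_min = parse_clock(cfg.rest_start_clock)
    for day in range(cfg.n_days):
        day_date = cfg.base_date() + dt.timedelta(days=day)
        offset = (rest_start_min - boundary_min) % (24 * 60)
        start_noise = rng.normal(0.0, cfg.rest_start_sd_min)
        dur_noise = rng.normal(0.0, cfg.rest_duration_sd_min)
        if day in cfg.rest_disrupt_days:
            # planted disruptions are exact displacements so recovery tests
            # measure detection, not the generator's own night-to-night noise
            start = day * 1440 + offset + cfg.rest_disrupt_start_shift_min
            duration = cfg.rest_duration_mean_min - cfg.rest_disrupt_duration_cut_min
        else:
            start = day * 1440 + offset + start_noise
            duration = cfg.rest_duration_mean_min + dur_noise
        duration = float(np.clip(duration, 60, 1439 - offset))
        s = int(np.clip(round(start), day * 1440, (day + 1) * 1440 - 61))
        e = int(np.clip(round(start + duration), s + 60, (day + 1) * 1440 - 1))
        label[s:e] = 1
        rest_blocks[day_date] = (minutes[s], minutes[e - 1] + pd.Timedelta(minutes=1))

        rate = (
            cfg.restless_awakening_rate
            if day in cfg.restless_days or day in cfg.rest_disrupt_days
            else cfg.awakening_rate
        )
        for _ in range(rng.poisson(rate)):
            # awakening durations are right-skewed: most are brief
            w_len = int(
                np.clip(
                    rng.geometric(1.0 / cfg.awakening_mean_min),
                    cfg.awakening_min_min,
                    cfg.awakening_max_min,
                )
            )
            if e - s <= w_len + 2:
                continue
            w_start = int(rng.integers(s + 1, e - w_len - 1))
            label[w_start : w_start + w_len] = 0
        if day in cfg.restless_days:
            restless[s:e] = True

    # Missing spans blank both accelerometer and heart-rate channels.
    for day in range(cfg.n_days):
        if rng.random() < cfg.missing_span_rate:
            m_len = int(rng.integers(cfg.missing_len_min_min, cfg.missing_len_max_min + 1))
            m_start = int(rng.integers(day * 1440, (day + 1) * 1440 - m_len))
            label[m_start : m_start + m_len] = 2

    is_rest = label == 1
    is_active = label == 0
    observed = label != 2

    jitter = np.full(n_min, cfg.theta_jitter_sd_deg)
    noise = np.full(n_min, cfg.accel_noise_sd_g)
    jitter[restless] *= cfg.restless_theta_factor
    noise[restless] *= cfg.restless_noise_factor

    theta = np.empty(n_min)
    theta[is_rest] = np.abs(
        cfg.theta_rest_mean_deg + rng.normal(0.0, 1.0, is_rest.sum()) * jitter[is_rest]
    )
    theta[is_active] = np.clip(
        cfg.theta_active_mean_deg + rng.normal(0.0, 1.0, is_active.sum()) * jitter[is_active],
        0.0,
        180.0,
    )

    ax = np.empty(n_min)
    ay = np.empty(n_min)
    az = np.empty(n_min)
    phi = rng.uniform(0.0, 2 * np.pi, n_min)
    ax[is_rest] = rng.normal(0.0, 1.0, is_rest.sum()) * noise[is_rest]
    ay[is_rest] = np.cos(phi[is_rest]) + rng.normal(0.0, 1.0, is_rest.sum()) * noise[is_rest]
    az[is_rest] = np.sin(phi[is_rest]) + rng.normal(0.0, 1.0, is_rest.sum()) * noise[is_rest]
    n_act = is_active.sum()
    ax[is_active] = rng.normal(0.95, 0.10 + noise[is_active])
    ay[is_active] = rng.normal(0.0, 0.25, n_act)
    az[is_active] = rng.normal(0.0, 0.25, n_act)

    steps = np.zeros(n_min, dtype=int)
    steps[is_active] = rng.poisson(8.0, n_act)

    accel = pd.DataFrame(
        {
            "timestamp": minutes[observed],
            "steps": steps[observed],
            "ax": ax[observed],
            "ay": ay[observed],
            "az": az[observed],
            "theta_deg": theta[observed],
        },
        columns=ACCEL_COLUMNS,
    ).reset_index(drop=True)

    hr_mask = observed & (np.arange(n_min) % 5 == 0)
    hr_vals = np.where(
        is_rest[hr_mask],
        rng.normal(60.0, 4.0, hr_mask.sum()),
        rng.normal(80.0, 6.0, hr_mask.sum()),
    )
    hr = pd.DataFrame(
        {"timestamp": minutes[hr_mask], "mean_hr": hr_vals}, columns=HR_COLUMNS
    )

    pairing_rows = []
    if cfg.pairing_daily:
        for day in range(cfg.n_days):
            # daytime pairing, 1-10 h after the day boundary, away from rest
            p_start = day * 1440 + int(rng.integers(60, 600))
            pairing_rows.append(
                {
                    "start": minutes[p_start],
                    "end": minutes[p_start] + pd.Timedelta(minutes=cfg.pairing_len_min),
                }
            )
    pairing = pd.DataFrame(pairing_rows, columns=PAIRING_COLUMNS)

    dose_min = parse_clock(cfg.dose_time_clock)
    dose_rows = []
    dose_truth: dict[dt.date, Optional[pd.Timestamp]] = {}
    if cfg.dose_days is not None:
        adherent = [d in set(cfg.dose_days) for d in range(cfg.n_days)]
        _ = rng.random(cfg.n_days)  # keep stream alignment with the Bernoulli path
    else:
        adherent = (rng.random(cfg.n_days) < cfg.adherence_prob).tolist()
    for day in range(cfg.n_days):
        day_date = cfg.base_date() + dt.timedelta(days=day)
        if not adherent[day]:
            dose_truth[day_date] = None
            continue
        jitter = rng.normal(0.0, cfg.dose_time_sd_min)
        if day in cfg.dose_outlier_days:
            # exact planted shift (see rest_disrupt_days comment above)
            minutes_from_midnight = dose_min + cfg.dose_outlier_shift_sd * cfg.dose_time_sd_min
        else:
            minutes_from_midnight = dose_min + jitter
        t = pd.Timestamp(day_date) + pd.Timedelta(minutes=minutes_from_midnight)
        t = t.floor("min")
        dose_rows.append({"timestamp": t})
        dose_truth[day_date] = t
    ingestions = pd.DataFrame(dose_rows, columns=INGESTION_COLUMNS)

    stream = PatientStream(
        patient_id=patient_id, accel=accel, hr=hr, pairing=pairing, ingestions=ingestions
    )
    truth = GroundTruth(
        rest_blocks=rest_blocks,
        dose_times=dose_truth,
        minute_labels=pd.Series(
            np.array(["active", "rest", "missing"])[label], index=minutes
        ),
        restless_days=[cfg.base_date() + dt.timedelta(days=d) for d in cfg.restless_days],
        disrupted_days=[cfg.base_date() + dt.timedelta(days=d) for d in cfg.rest_disrupt_days],
    )
    return stream, truth


def simulate_cohort(
    n_patients: int,
    base_cfg: SimConfig,
    seed: int = 0,
    sampler: Optional[Callable[[int, np.random.Generator], SimConfig]] = None,
) -> tuple[list[tuple[PatientStream, GroundTruth]], pd.DataFrame]:
    """Independent patients from a split master seed.

    Patient ``i`` uses child seed ``i`` of ``SeedSequence(seed)``, so any
    patient can be regenerated in isolation.  ``sampler(i, rng)`` may return
    a per-patient config; by default every patient shares ``base_cfg``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_patients)
    out = []
    manifest_rows = []
    for i, child in enumerate(children):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        cfg_i = base_cfg if sampler is None else sampler(i, np.random.default_rng(child_seed))
        pid = f"SIM-{i + 1:03d}"
        out.append(simulate_patient(cfg_i, seed=child_seed, patient_id=pid))
        manifest_rows.append(
            {
                "patient_id": pid,
                "seed": child_seed,
                "n_days": cfg_i.n_days,
                "adherence_prob": cfg_i.adherence_prob,
                "rest_duration_mean_min": cfg_i.rest_duration_mean_min,
                "accel_noise_sd_g": cfg_i.accel_noise_sd_g,
            }
        )
    return out, pd.DataFrame(manifest_rows)


def write_patient_csvs(stream: PatientStream, out_dir, truth: GroundTruth | None = None) -> None:
    """Write the four channel CSVs (and truth.json when given) to a directory."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stream.accel.to_csv(out / "accel.csv", index=False, float_format="%.12g")
    stream.hr.to_csv(out / "hr.csv", index=False, float_format="%.12g")
    stream.pairing.to_csv(out / "pairing.csv", index=False)
    stream.ingestions.to_csv(out / "ingestions.csv", index=False)
    if truth is not None:
        payload = {
            "rest_blocks": {
                d.isoformat(): [a.isoformat(), b.isoformat()]
                for d, (a, b) in truth.rest_blocks.items()
            },
            "dose_times": {
                d.isoformat(): (t.isoformat() if t is not None else None)
                for d, t in truth.dose_times.items()
            },
            "restless_days": [d.isoformat() for d in truth.restless_days],
            "disrupted_days": [d.isoformat() for d in truth.disrupted_days],
        }
        (out / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")
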