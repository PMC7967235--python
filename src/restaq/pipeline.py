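"""End-to-end pipeline: intervals → rest periods → features → quality → scores.

``run_patient`` takes one :class:`PatientStream` and produces labeled day
grids, daily longest rest periods, the per-patient cluster model, per-window
and per-interval quality, daily z-scores and ingestion metrics.
``run_cohort`` maps it over eligible patients and assembles the cohort
tables.
"""

from __future__ import annotations

import datetime as dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import features as feat
from . import intervals as iv_mod
from . import quality as q_mod
from . import restperiod as rp_mod
from . import scores as sc_mod
from .config import RunConfig
from .io import daily_scores_frame, write_daily_scores
from .types import (
    ClusterModel,
    DailyScores,
    DayGrid,
    PatientStream,
    PatientSummary,
    RestPeriod,
    State,
)

log = logging.getLogger("restaq.pipeline")


class IneligiblePatientError(ValueError):
    """Patient lacks the minimum number of days with patch data."""


@dataclass
class PatientResult:
    patient_id: str
    grids: list[DayGrid]
    lrps: dict[dt.date, RestPeriod]
    model: Optional[ClusterModel]
    window_table: pd.DataFrame  # day, interval, window, distance + features
    interval_quality: pd.DataFrame  # day, interval, n_points, quality
    daily: list[DailyScores]
    summary: Optional[PatientSummary]
    coincidences: list[tuple[dt.date, dt.date]] = field(default_factory=list)

    def daily_frame(self) -> pd.DataFrame:
        return daily_scores_frame(self.patient_id, self.daily)


def _collect_windows(
    grids: list[DayGrid],
    lrps: dict[dt.date, RestPeriod],
    stream: PatientStream,
    cfg: RunConfig,
    scope: str,
) -> pd.DataFrame:
    """Feature windows as one table: day, interval, window, f0..f3."""
    defs = feat.canonical_features(cfg)
    rows = []
    for grid in grids:
        if scope == "lrp":
            if grid.day_id not in lrps:
                continue
            indices = lrps[grid.day_id].rest_indices
        else:  # all analyzable windows, day and night
            indices = [
                i for i, s in enumerate(grid.states) if s in (State.REST, State.ACTIVE)
            ]
        for w in feat.windows_for_intervals(grid, indices, stream.accel, cfg, defs):
            rows.append(
                {
                    "day": grid.day_id,
                    "interval": w.interval_index,
                    "window": w.window_index,
                    **{d.name: v for d, v in zip(defs, w.feature_vector)},
                }
            )
    cols = ["day", "interval", "window"] + [d.name for d in defs]
    return pd.DataFrame(rows, columns=cols)


def run_patient(
    stream: PatientStream, cfg: RunConfig, enforce_eligibility: bool = True
) -> PatientResult:
    """Run every stage for one patient."""
    if enforce_eligibility and not stream.is_eligible(cfg.min_eligible_days):
        raise IneligiblePatientError(
            f"{stream.patient_id}: {stream.n_patch_days()} patch-data day(s) "
            f"< {cfg.min_eligible_days}"
        )
    grids = iv_mod.build_day_grids(stream, cfg)
    lrps = rp_mod.daily_lrps(grids, cfg)
    feat_names = [d.name for d in feat.canonical_features(cfg)]

    score_tbl = _collect_windows(grids, lrps, stream, cfg, scope="lrp")
    fit_tbl = (
        score_tbl
        if cfg.fit_scope == "lrp"
        else _collect_windows(grids, lrps, stream, cfg, scope="all")
    )

    model: Optional[ClusterModel] = None
    window_table = score_tbl.copy()
    interval_quality = pd.DataFrame(columns=["day", "interval", "n_points", "quality"])
    day_quality: dict[dt.date, float] = {}

    if len(fit_tbl) >= 2:
        fit_pts = fit_tbl[feat_names].to_numpy(float)
        _, mins, maxs = q_mod.normalize(fit_pts)
        try:
            model = q_mod.fit_clusters(
                q_mod.apply_normalization(fit_pts, mins, maxs),
                cfg,
                feature_names=feat_names,
                theta_index=feat.THETA_INDEX,
            )
            model.mins, model.maxs = mins, maxs
        except q_mod.DegenerateClusterError:
            log.warning(
                "%s: degenerate single-cluster data; no quality metrics",
                stream.patient_id,
            )
            model = None

    if model is not None and len(score_tbl) > 0:
        pts = q_mod.apply_normalization(
            score_tbl[feat_names].to_numpy(float), model.mins, model.maxs
        )
        window_table["distance"] = q_mod.rest_distance(pts, model)
        expected = feat.window_count(cfg.interval_minutes, cfg.rolling_window_minutes)
        iq_rows = []
        for (day, iv_idx), grp in window_table.groupby(["day", "interval"], sort=True):
            iq_rows.append(
                {
                    "day": day,
                    "interval": iv_idx,
                    "n_points": len(grp),
                    "quality": q_mod.window_quality(
                        grp["distance"].to_numpy(), expected_points=expected
                    ),
                }
            )
        interval_quality = pd.DataFrame(iq_rows)
        for day, grp in interval_quality.groupby("day"):
            day_quality[day] = q_mod.lrp_quality(grp["quality"].to_numpy())

    # --- daily z-scores -----------------------------------------------------
    all_days = [g.day_id for g in grids]
    grid_by_day = {g.day_id: g for g in grids}
    qual = pd.Series({d: day_quality.get(d, np.nan) for d in all_days}, dtype=float)
    start_min = pd.Series(
        {
            d: (
                (lrps[d].start_time - grid_by_day[d].start).total_seconds() / 60.0
                if d in lrps
                else np.nan
            )
            for d in all_days
        },
        dtype=float,
    )
    duration = pd.Series(
        {d: (lrps[d].duration_min if d in lrps else np.nan) for d in all_days},
        dtype=float,
    )
    qz = sc_mod.zscore_series(qual, ddof=cfg.sd_ddof_score)
    sz = sc_mod.zscore_series(start_min, ddof=cfg.sd_ddof_score)
    dz = sc_mod.zscore_series(duration, ddof=cfg.sd_ddof_score)

    ing_times = sc_mod.ingestion_times(stream)
    ing_z = sc_mod.ingestion_time_z(stream, ddof=cfg.sd_ddof_score)

    daily: list[DailyScores] = []
    composite = pd.Series(np.nan, index=all_days, dtype=float)
    for d in all_days:
        rp = lrps.get(d)
        comp = None
        if all(np.isfinite([qz.get(d, np.nan), sz.get(d, np.nan), dz.get(d, np.nan)])):
            comp = sc_mod.composite_rest(qz[d], sz[d], dz[d])
            composite[d] = comp

        def _val(series, day):
            v = series.get(day, np.nan)
            return float(v) if np.isfinite(v) else None

        daily.append(
            DailyScores(
                day_id=d,
                lrp_start=rp.start_time if rp else None,
                lrp_duration_min=float(rp.duration_min) if rp else None,
                lrp_quality=_val(qual, d),
                quality_z=_val(qz, d),
                start_z=_val(sz, d),
                duration_z=_val(dz, d),
                composite_z=comp,
                ingestion_time_min=_val(ing_times, d) if len(ing_times) else None,
                ingestion_z=_val(ing_z, d) if len(ing_z) else None,
            )
        )

    coincidences = sc_mod.outlier_coincidences(composite, ing_z, cfg)
    try:
        rate = sc_mod.ingestion_rate(stream)
        span = (
            (sc_mod.ingestion_days(stream)[-1] - stream.patch_dates()[0]).days + 1
            if sc_mod.ingestion_days(stream)
            else stream.n_patch_days()
        )
    except ValueError:
        rate, span = 0.0, 0
    finite_comp = composite.dropna()
    summary = PatientSummary(
        patient_id=stream.patient_id,
        ingestion_rate=rate,
        regimen_days=span,
        mean_composite=float(finite_comp.mean()) if len(finite_comp) else None,
        n_coincidences=len(coincidences),
        coincidences=coincidences,
    )
    return PatientResult(
        patient_id=stream.patient_id,
        grids=grids,
        lrps=lrps,
        model=model,
        window_table=window_table,
        interval_quality=interval_quality,
        daily=daily,
        summary=summary,
        coincidences=coincidences,
    )


def run_cohort(
    streams: list[PatientStream], cfg: RunConfig
) -> tuple[list[PatientResult], list[str]]:
    """Run all eligible patients; returns results and skipped patient ids."""
    results, skipped = [], []
    for s in streams:
        try:
            results.append(run_patient(s, cfg))
        except IneligiblePatientError as exc:
            log.warning("skipping ineligible patient: %s", exc)
            skipped.append(s.patient_id)
    return results, skipped


def write_outputs(
    results: list[PatientResult], cfg: RunConfig, out_dir: str | Path
) -> Path:
    """Write every stage dump plus the cohort score tables to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = cfg.config_hash()

    def _concat(frames: list[pd.DataFrame]) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()

    iv_frames, lrp_frames, wq_frames, daily_frames = [], [], [], []
    summaries, coin_rows, models = [], [], {}
    for r in results:
        f = iv_mod.grids_to_frame(r.grids)
        f.insert(0, "patient_id", r.patient_id)
        iv_frames.append(f)
        f = rp_mod.lrps_to_frame(r.lrps, cfg)
        f.insert(0, "patient_id", r.patient_id)
        lrp_frames.append(f)
        f = r.interval_quality.copy()
        if len(f):
            f.insert(0, "patient_id", r.patient_id)
            f["day"] = f["day"].map(lambda d: d.isoformat())
        wq_frames.append(f)
        daily_frames.append(r.daily_frame())
        if r.model is not None:
            models[r.patient_id] = r.model.to_dict()
        if r.summary is not None:
            summaries.append(
                {
                    "patient_id": r.patient_id,
                    "ingestion_rate": r.summary.ingestion_rate,
                    "regimen_days": r.summary.regimen_days,
                    "mean_composite": r.summary.mean_composite,
                    "n_coincidences": r.summary.n_coincidences,
                }
            )
        for dr, di in r.coincidences:
            coin_rows.append(
                {
                    "patient_id": r.patient_id,
                    "rest_day": dr.isoformat(),
                    "ingestion_day": di.isoformat(),
                }
            )

    _concat(iv_frames).to_csv(out / "intervals.csv", index=False, float_format="%.12g")
    _concat(lrp_frames).to_csv(out / "lrp.csv", index=False, float_format="%.12g")
    _concat(wq_frames).to_csv(out / "window_quality.csv", index=False, float_format="%.12g")
    write_daily_scores(_concat(daily_frames), out / "daily_scores.csv")
    pd.DataFrame(
        summaries,
        columns=[
            "patient_id",
            "ingestion_rate",
            "regimen_days",
            "mean_composite",
            "n_coincidences",
        ],
    ).to_csv(out / "patient_summary.csv", index=False, float_format="%.12g")
    pd.DataFrame(
        coin_rows, columns=["patient_id", "rest_day", "ingestion_day"]
    ).to_csv(out / "coincidences.csv", index=False)
    (out / "models.json").write_text(json.dumps(models, indent=2, sort_keys=True) + "\n")
    (out / "run_manifest.json").write_text(
        json.dumps(
            {"config": json.loads(cfg.model_dump_json()), "config_hash": cfg_hash},
            indent=2,
            sort_keys=True,
        )
        + "\n"
    )
    return out
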