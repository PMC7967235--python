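"""Diagnostic plots, drawn from the pipeline's dump CSVs only.

Plots never recompute anything: they read ``intervals.csv``, ``lrp.csv``,
``window_quality.csv`` and ``daily_scores.csv`` written by the pipeline, so
a figure can never disagree with the numeric outputs.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

STATE_COLORS = {"R": "#2166ac", "A": "#d6604d", "M": "#cccccc"}


def _load(out_dir: Path, name: str) -> pd.DataFrame:
    path = out_dir / name
    return pd.read_csv(path) if path.exists() else pd.DataFrame()


def plot_rasters(out_dir: str | Path, patient_id: str | None = None) -> list[Path]:
    """Write the three diagnostic figures for one patient.

    (a) day x interval state raster; (b) daily rest-period bars coloured by
    window quality; (c) composite and ingestion-time z-scores with outlier
    markers.  Returns the written image paths.
    """
    out = Path(out_dir)
    intervals = _load(out, "intervals.csv")
    if intervals.empty:
        return []
    if patient_id is None:
        patient_id = intervals["patient_id"].iloc[0]
    intervals = intervals[intervals["patient_id"] == patient_id]
    wq = _load(out, "window_quality.csv")
    wq = wq[wq["patient_id"] == patient_id] if len(wq) else wq
    daily = _load(out, "daily_scores.csv")
    daily = daily[daily["patient_id"] == patient_id] if len(daily) else daily
    lrp = _load(out, "lrp.csv")
    lrp = lrp[lrp["patient_id"] == patient_id] if len(lrp) else lrp

    written: list[Path] = []
    days = sorted(intervals["day"].unique())
    day_pos = {d: i for i, d in enumerate(days)}
    n_iv = intervals.groupby("day").size().max()

    # (a) state raster
    fig, ax = plt.subplots(figsize=(10, max(2, 0.22 * len(days))))
    img = np.full((len(days), n_iv, 3), 1.0)
    order = {"R": 0, "A": 1, "M": 2}
    palette = np.array(
        [matplotlib.colors.to_rgb(STATE_COLORS[c]) for c in ("R", "A", "M")]
    )
    grp = intervals.sort_values(["day", "interval_start"])
    for d, sub in grp.groupby("day"):
        codes = [order[s] for s in sub["state"]]
        img[day_pos[d], : len(codes)] = palette[codes]
    ax.imshow(img, aspect="auto", interpolation="nearest")
    ax.set_xlabel("15-min interval within day (from day boundary)")
    ax.set_ylabel("day")
    ax.set_title(f"{patient_id}: interval states (blue rest, red active, grey missing)")
    p = out / f"raster_states_{patient_id}.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # (b) LRP bars coloured by window quality
    fig, ax = plt.subplots(figsize=(10, max(2, 0.22 * len(days))))
    if len(wq):
        vmax = max(wq["quality"].max(), 1e-9)
        cmap = plt.get_cmap("viridis")
        for _, row in wq.iterrows():
            if row["day"] not in day_pos:
                continue
            y = day_pos[row["day"]]
            ax.barh(
                y,
                1,
                left=row["interval"],
                height=0.8,
                color=cmap(row["quality"] / vmax),
            )
        sm = plt.cm.ScalarMappable(
            cmap=cmap, norm=matplotlib.colors.Normalize(0, vmax)
        )
        fig.colorbar(sm, ax=ax, label="window quality (lower = better rest)")
    ax.set_ylim(-0.5, len(days) - 0.5)
    ax.invert_yaxis()
    ax.set_xlabel("15-min interval within day")
    ax.set_ylabel("day")
    ax.set_title(f"{patient_id}: longest rest periods, window quality")
    p = out / f"raster_lrp_{patient_id}.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)

    # (c) z-score overlay
    fig, ax = plt.subplots(figsize=(10, 3.2))
    if len(daily):
        daily = daily.sort_values("day")
        x = np.arange(len(daily))
        comp = pd.to_numeric(daily["composite_z"], errors="coerce")
        ingz = pd.to_numeric(daily["ingestion_z"], errors="coerce")
        ax.plot(x, comp, "o-", color="tab:orange", label="composite rest z")
        ax.plot(x, ingz, "s-", color="tab:blue", label="ingestion time z")
        out_mask = comp > 2
        ax.plot(x[out_mask], comp[out_mask], "o", mfc="none", mec="k", ms=12)
        out_mask = ingz.abs() > 2
        ax.plot(x[out_mask], ingz[out_mask], "s", mfc="none", mec="k", ms=12)
        ax.axhline(2, color="grey", lw=0.8, ls="--")
        ax.axhline(-2, color="grey", lw=0.8, ls="--")
        ax.set_xticks(x[:: max(1, len(x) // 15)])
        ax.set_xticklabels(daily["day"].iloc[:: max(1, len(x) // 15)], rotation=45)
        ax.legend(loc="upper right")
    ax.set_ylabel("z score")
    ax.set_title(f"{patient_id}: composite rest and ingestion-time z scores")
    p = out / f"zscores_{patient_id}.png"
    fig.savefig(p, dpi=120, bbox_inches="tight")
    plt.close(fig)
    written.append(p)
    return written
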