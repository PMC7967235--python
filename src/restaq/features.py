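"""Rolling-window accelerometer features.

Within every 15-minute interval, 3-minute rolling windows (stride one
minute, never spanning an interval boundary) are cut from the per-minute
records, giving 13 windows for a fully sampled interval.  Four canonical
features summarise each window:

* ``yz_circ_dev`` — mean of ``| sqrt(a_y^2 + a_z^2) - 1 |``: how far the
  y–z acceleration magnitude deviates from the 1-g circle.  Lying still
  puts gravity almost entirely in the y–z plane of the torso patch, so the
  deviation is near 0 during quality rest and grows with movement or
  uprightness.
* ``theta_mean`` — mean posture angle in degrees (0 = lying, 90 = upright).
* ``accel_norm_mean`` — mean of the 3-D acceleration norm in g.
* ``ax_sd`` — standard deviation of the longitudinal (x) acceleration
  (population SD over the window's points by default).

A registry of candidate features (means/SDs per axis, norms, circular
statistics, step statistics, ranges) supports the optional
agglomeration-based selection path; the default pipeline uses the four
canonical features without selection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .config import RunConfig
from .types import DayGrid, Interval15

#: Channels a feature may consume; each is a (window_minutes,) float array.
CHANNELS = ("ax", "ay", "az", "theta_deg", "steps")


@dataclass
class FeatureDef:
    """A named, documented window feature."""

    name: str
    fn: Callable[[dict[str, np.ndarray]], float]
    units: str
    description: str
    canonical: bool = False


@dataclass
class FeatureWindow:
    """One 3-minute rolling window inside a 15-minute interval."""

    interval_index: int
    window_index: int
    record_idx: np.ndarray
    feature_vector: np.ndarray = field(default_factory=lambda: np.empty(0))


# ---------------------------------------------------------------------------
# Canonical features


def feat_yz_circ_dev(block: dict[str, np.ndarray]) -> float:
    """Mean deviation of the (a_y, a_z) magnitude from the 1-g circle."""
    return float(np.mean(np.abs(np.hypot(block["ay"], block["az"]) - 1.0)))


def feat_theta_mean(block: dict[str, np.ndarray]) -> float:
    """Mean posture angle over the window (degrees from horizontal)."""
    return float(np.mean(block["theta_deg"]))


def feat_accel_norm_mean(block: dict[str, np.ndarray]) -> float:
    """Mean 3-D acceleration norm over the window (g)."""
    return float(
        np.mean(np.sqrt(block["ax"] ** 2 + block["ay"] ** 2 + block["az"] ** 2))
    )


def feat_ax_sd(block: dict[str, np.ndarray], ddof: int = 0) -> float:
    """Standard deviation of the x acceleration over the window (g)."""
    return float(np.std(block["ax"], ddof=ddof))


def canonical_features(cfg: RunConfig | None = None) -> list[FeatureDef]:
    """The four selected rest features, in fixed pipeline order.

    The posture-angle feature sits at index 1; the clustering stage uses
    that coordinate to designate the rest-reference cluster.
    """
    ddof = cfg.sd_ddof_feature if cfg is not None else 0
    return [
        FeatureDef(
            "yz_circ_dev",
            feat_yz_circ_dev,
            "g",
            "mean |sqrt(a_y^2+a_z^2) - 1|, deviation from the 1-g circle",
            canonical=True,
        ),
        FeatureDef(
            "theta_mean", feat_theta_mean, "deg", "mean posture angle", canonical=True
        ),
        FeatureDef(
            "accel_norm_mean",
            feat_accel_norm_mean,
            "g",
            "mean 3-D acceleration norm",
            canonical=True,
        ),
        FeatureDef(
            "ax_sd",
            lambda b, _d=ddof: feat_ax_sd(b, _d),
            "g",
            "SD of x acceleration",
            canonical=True,
        ),
    ]


#: Index of the posture-angle feature in the canonical vector.
THETA_INDEX = 1


# ---------------------------------------------------------------------------
# Window extraction


def _slot_channels(
    iv: Interval15, accel: pd.DataFrame, cfg: RunConfig
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Align an interval's records onto its minute-slot grid.

    Returns per-channel arrays of length ``interval_minutes`` (NaN for empty
    slots) plus the record index occupying each slot (-1 when empty).  When
    two records share a minute slot the first is kept.
    """
    n_slots = cfg.interval_minutes
    chans = {c: np.full(n_slots, np.nan) for c in CHANNELS}
    slot_rec = np.full(n_slots, -1, dtype=int)
    if len(iv.record_idx) == 0:
        return chans, slot_rec
    ts = accel["timestamp"].to_numpy(dtype="datetime64[ns]")[iv.record_idx]
    start = np.datetime64(iv.start, "ns")
    slots = ((ts - start) // np.timedelta64(60_000_000_000, "ns")).astype(int)
    for rec, slot in zip(iv.record_idx, slots):
        if 0 <= slot < n_slots and slot_rec[slot] < 0:
            slot_rec[slot] = rec
    occupied = slot_rec >= 0
    for c in CHANNELS:
        vals = accel[c].to_numpy(float)
        chans[c][occupied] = vals[slot_rec[occupied]]
    return chans, slot_rec


def rolling_windows(
    iv: Interval15,
    accel: pd.DataFrame,
    cfg: RunConfig,
    interval_index: int = 0,
    feature_defs: Sequence[FeatureDef] | None = None,
) -> list[FeatureWindow]:
    """All complete rolling windows of an interval, with feature vectors.

    Windows are ``rolling_window_minutes`` consecutive minute slots, stride
    one; a window containing an empty slot is dropped rather than imputed.
    """
    if feature_defs is None:
        feature_defs = canonical_features(cfg)
    w = cfg.rolling_window_minutes
    chans, slot_rec = _slot_channels(iv, accel, cfg)
    n_slots = cfg.interval_minutes
    windows: list[FeatureWindow] = []
    for j in range(max(0, n_slots - w + 1)):
        sl = slice(j, j + w)
        if np.any(slot_rec[sl] < 0):
            continue
        block = {c: chans[c][sl] for c in CHANNELS}
        vec = np.array([fd.fn(block) for fd in feature_defs], dtype=float)
        windows.append(
            FeatureWindow(
                interval_index=interval_index,
                window_index=j,
                record_idx=slot_rec[sl].copy(),
                feature_vector=vec,
            )
        )
    return windows


def window_count(n_slots: int, w: int) -> int:
    """Number of complete rolling windows over contiguous slots."""
    return max(0, n_slots - w + 1)


# ---------------------------------------------------------------------------
# Candidate registry (optional selection path)


def _stat_feature(channel: str, stat: str, ddof: int = 0) -> Callable:
    ops = {
        "mean": lambda x: float(np.mean(x)),
        "sd": lambda x: float(np.std(x, ddof=ddof)),
        "min": lambda x: float(np.min(x)),
        "max": lambda x: float(np.max(x)),
        "range": lambda x: float(np.max(x) - np.min(x)),
        "sum": lambda x: float(np.sum(x)),
        "rms": lambda x: float(np.sqrt(np.mean(np.square(x)))),
    }
    op = ops[stat]
    return lambda block: op(block[channel])


def _norm_feature(stat: str) -> Callable:
    def fn(block):
        norm = np.sqrt(block["ax"] ** 2 + block["ay"] ** 2 + block["az"] ** 2)
        return float(np.mean(norm) if stat == "mean" else np.std(norm))

    return fn


def _yz_mag_feature(stat: str) -> Callable:
    def fn(block):
        mag = np.hypot(block["ay"], block["az"])
        return float(np.mean(mag) if stat == "mean" else np.std(mag))

    return fn


def feat_yz_angular_dispersion(block: dict[str, np.ndarray]) -> float:
    """Circular dispersion (1 - resultant length) of atan2(a_z, a_y).

    The angular counterpart of the circular-deviation feature; kept in the
    registry as a distinct candidate, not among the canonical four.
    """
    ang = np.arctan2(block["az"], block["ay"])
    r = np.hypot(np.mean(np.cos(ang)), np.mean(np.sin(ang)))
    return float(1.0 - r)


def candidate_registry(cfg: RunConfig | None = None) -> list[FeatureDef]:
    """~35 documented rolling-window statistics used as candidate features.

    These are standard actimetry window statistics standing in for the
    original candidate pool; only the four canonical features are part of
    the default quality pipeline.
    """
    defs = list(canonical_features(cfg))
    for ch, unit in (("ax", "g"), ("ay", "g"), ("az", "g"), ("theta_deg", "deg")):
        for stat in ("mean", "sd", "min", "max", "range", "rms"):
            name = f"{ch.replace('_deg', '')}_{stat}"
            if name in {"ax_sd", "theta_mean"}:
                continue  # canonical versions already present
            defs.append(
                FeatureDef(name, _stat_feature(ch, stat), unit, f"{stat} of {ch}")
            )
    defs.append(FeatureDef("norm_sd", _norm_feature("sd"), "g", "SD of 3-D norm"))
    defs.append(
        FeatureDef("yz_mag_mean", _yz_mag_feature("mean"), "g", "mean y-z magnitude")
    )
    defs.append(
        FeatureDef("yz_mag_sd", _yz_mag_feature("sd"), "g", "SD of y-z magnitude")
    )
    defs.append(
        FeatureDef(
            "yz_angular_dispersion",
            feat_yz_angular_dispersion,
            "1",
            "circular dispersion of the y-z acceleration angle",
        )
    )
    for stat in ("sum", "mean", "max"):
        defs.append(
            FeatureDef(
                f"steps_{stat}", _stat_feature("steps", stat), "steps", f"{stat} of steps"
            )
        )
    return defs


class SelectionError(ValueError):
    """Raised when feature selection cannot produce k features."""


def _patient_clusters(matrix: np.ndarray, k: int) -> np.ndarray:
    """Cluster feature columns by 1 - |Pearson r| average-linkage merging."""
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(matrix, rowvar=False)
    corr = np.nan_to_num(corr, nan=0.0)
    dist = 1.0 - np.abs(corr)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="average")
    return fcluster(z, t=k, criterion="maxclust")


def select_features(
    matrices: Sequence[np.ndarray], feature_defs: Sequence[FeatureDef], k: int
) -> list[FeatureDef]:
    """Pick ``k`` features that patients consistently keep in distinct clusters.

    ``matrices`` holds one (n_windows, n_features) array per patient.  For
    every patient, features are merged hierarchically (1 - |Pearson r|
    distance, average linkage) into ``k`` clusters.  Co-assignment
    frequencies across patients are then clustered once more and the most
    central feature of each consensus group is returned, so near-duplicate
    features collapse to a single representative.
    """
    p = len(feature_defs)
    variances = np.nanvar(np.vstack(matrices), axis=0)
    if int(np.sum(variances > 0)) < k:
        raise SelectionError(f"fewer than k={k} candidate features with nonzero variance")
    if k == p:
        return list(feature_defs)

    co = np.zeros((p, p))
    for m in matrices:
        labels = _patient_clusters(m, k)
        co += labels[:, None] == labels[None, :]
    co /= len(matrices)

    dist = 1.0 - co
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    groups = fcluster(z, t=k, criterion="maxclust")

    chosen: list[int] = []
    for g in sorted(set(groups)):
        members = np.flatnonzero(groups == g)
        # representative: highest mean co-assignment with its group, then
        # highest variance, then registry order
        score = co[np.ix_(members, members)].mean(axis=1)
        order = sorted(
            range(len(members)),
            key=lambda i: (-score[i], -variances[members[i]], members[i]),
        )
        chosen.append(int(members[order[0]]))
    return [feature_defs[i] for i in sorted(chosen)]


# ---------------------------------------------------------------------------


def windows_for_intervals(
    grid: DayGrid,
    indices: Sequence[int],
    accel: pd.DataFrame,
    cfg: RunConfig,
    feature_defs: Sequence[FeatureDef] | None = None,
) -> list[FeatureWindow]:
    """Feature windows for selected intervals of one day grid."""
    out: list[FeatureWindow] = []
    for i in indices:
        out.extend(
            rolling_windows(
                grid.intervals[i], accel, cfg, interval_index=i, feature_defs=feature_defs
            )
        )
    return out
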