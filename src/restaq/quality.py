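"""Per-patient rest-reference clustering and the rest-quality distance.

The four window features are min–max normalised to the patient's own range,
then clustered with k-means (k=2).  The cluster whose centroid has the
smaller normalised posture-angle coordinate is the rest reference (RR); the
other is deviation-from-rest (DFR).  Every window point assigned to RR
scores 0; a DFR point scores its Euclidean distance to the RR centroid, so
lower values mean better rest.  Window scores are summed per 15-minute
interval and averaged over the intervals of a longest rest period.
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.cluster import KMeans

from .config import RunConfig
from .types import ClusterModel

log = logging.getLogger("restaq.quality")


class DegenerateClusterError(ValueError):
    """All points identical: the patient has a single degenerate cluster."""


def normalize(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Min–max normalise each feature to [0, 1] over the given points.

    A zero-range (constant) feature is mapped to 0 for every point, with a
    logged warning; the returned (mins, maxs) record the ranges used.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) < 2:
        raise ValueError("need at least two points to normalise")
    mins = pts.min(axis=0)
    maxs = pts.max(axis=0)
    span = maxs - mins
    degenerate = span <= 0
    if degenerate.any():
        log.warning(
            "degenerate feature(s) with zero range at index %s; set to 0",
            np.flatnonzero(degenerate).tolist(),
        )
    safe = np.where(degenerate, 1.0, span)
    normed = (pts - mins) / safe
    normed[:, degenerate] = 0.0
    return normed, mins, maxs


def apply_normalization(points: np.ndarray, mins: np.ndarray, maxs: np.ndarray) -> np.ndarray:
    span = maxs - mins
    degenerate = span <= 0
    safe = np.where(degenerate, 1.0, span)
    normed = (np.asarray(points, float) - mins) / safe
    normed[:, degenerate] = 0.0
    return normed


def fit_clusters(
    points: np.ndarray,
    cfg: RunConfig,
    feature_names: list[str] | None = None,
    theta_index: int = 1,
) -> ClusterModel:
    """Fit the per-patient RR/DFR model on normalised window points.

    k-means with two clusters and ``kmeans_restarts`` seeded restarts; the
    rest-reference cluster is the one whose centroid posture-angle
    coordinate is nearer horizontal (smaller).
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) < 2 or np.allclose(pts, pts[0]):
        raise DegenerateClusterError(
            "all window points identical: data form a single rest cluster"
        )
    km = KMeans(
        n_clusters=2,
        n_init=cfg.kmeans_restarts,
        random_state=cfg.rng_seed % (2**32),
    ).fit(pts)
    c0, c1 = km.cluster_centers_
    if c0[theta_index] <= c1[theta_index]:
        rr, dfr = c0, c1
    else:
        rr, dfr = c1, c0
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(pts.shape[1])]
    return ClusterModel(
        feature_names=list(feature_names),
        mins=np.zeros(pts.shape[1]),
        maxs=np.ones(pts.shape[1]),
        centroid_rr=rr.copy(),
        centroid_dfr=dfr.copy(),
        rr_label_rule=(
            f"centroid with smaller normalised posture angle "
            f"({rr[theta_index]:.4f} <= {dfr[theta_index]:.4f})"
        ),
        theta_index=theta_index,
    )


def rest_distance(points: np.ndarray, model: ClusterModel) -> np.ndarray:
    """Rest-quality distance of normalised points.

    Points nearer the RR centroid (ties included) score 0; the rest score
    their Euclidean distance to the RR centroid.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[1] != len(model.centroid_rr):
        raise ValueError(
            f"dimension mismatch: point has {pts.shape[1]} features, "
            f"model has {len(model.centroid_rr)}"
        )
    d_rr = np.linalg.norm(pts - model.centroid_rr, axis=1)
    d_dfr = np.linalg.norm(pts - model.centroid_dfr, axis=1)
    out = np.where(d_rr <= d_dfr, 0.0, d_rr)
    return out if np.asarray(points).ndim == 2 else out[0]


def window_quality(distances: np.ndarray, expected_points: int = 13) -> float:
    """Sum of a 15-minute interval's window distances.

    Intervals with fewer than the nominal number of windows (dropped windows
    over data gaps) are rescaled by ``expected/n`` so interval sums stay
    comparable.
    """
    d = np.asarray(distances, dtype=float)
    n = len(d)
    if n == 0:
        raise ValueError("window_quality needs at least one scored point")
    total = float(d.sum())
    if n < expected_points:
        total *= expected_points / n
    return total


def lrp_quality(interval_qualities: np.ndarray) -> float:
    """Mean window quality over the scored intervals of one rest period."""
    q = np.asarray(interval_qualities, dtype=float)
    if len(q) == 0:
        raise ValueError("lrp_quality needs at least one scored interval")
    return float(q.mean())
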