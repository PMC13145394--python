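"""GPS mobility features: movement annotation, stay clustering, home detection.

Raw traces are event-based (a point is recorded when the phone detects a
location change), so traces are sparse and unevenly sampled.  The pipeline
is: great-circle distances and speeds between consecutive points ->
stationary / transition classification -> DBSCAN over stationary points ->
home-cluster detection from night occupancy -> per-block mobility features.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from ._time import dt64

EARTH_RADIUS_M = 6_371_000.0
#: DBSCAN neighborhood radius in radians of great-circle angle (~100 m).
DBSCAN_EPS_RAD = 100.0 / EARTH_RADIUS_M
#: Walking speed (m/s); at or above this a point is in transition.
WALKING_SPEED_MPS = 1.4
#: Consecutive-point distance bound (m) for the stationary rule.
STATIONARY_DISTANCE_M = 150.0
#: Cap on the dwell time attributed to a single point (minutes).  Event-based
#: sampling leaves long silent gaps at stays; without a cap one point could
#: claim hours.
DWELL_CAP_MIN = 30.0
#: Fraction of a person's total GPS points used as DBSCAN min_samples.
MIN_SAMPLES_FRACTION = 0.03
#: Night window (local clock hours) for home detection: 20:00-06:00.
NIGHT_START_H = 20
NIGHT_END_H = 6


def haversine_m(p1, p2) -> float | np.ndarray:
    """Great-circle distance in meters between (lat, lon) pairs in degrees.

    Accepts scalars or broadcastable arrays; symmetric and non-negative.
    """
    lat1, lon1 = np.radians(np.asarray(p1[0], float)), np.radians(np.asarray(p1[1], float))
    lat2, lon2 = np.radians(np.asarray(p2[0], float)), np.radians(np.asarray(p2[1], float))
    dphi = lat2 - lat1
    dlam = lon2 - lon1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlam / 2.0) ** 2
    # guard rounding: a must stay in [0, 1]
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))
    if np.ndim(d) == 0:
        return float(d)
    return d


def annotate_movement(points: pd.DataFrame) -> pd.DataFrame:
    """Annotate a time-sorted GPS trace with distances, speeds and dwell.

    Parameters
    ----------
    points : DataFrame with columns ``timestamp`` (tz-aware), ``lat``, ``lon``.

    Returns a copy with columns ``distance_m``, ``dt_s``, ``speed_mps``,
    ``stationary``, ``degenerate``, ``dwell_min``.  A point is stationary iff
    its speed is strictly below walking speed (1.4 m/s) AND the distance to
    the previous point is strictly below 150 m.  The first point inherits the
    first pair's label.  Pairs with dt == 0 are flagged degenerate and get no
    speed.  ``dwell_min`` is the time to the next point, capped at 30 min
    (last point gets 0).
    """
    df = points.copy()
    n = len(df)
    if n == 0:
        for c in ("distance_m", "dt_s", "speed_mps", "dwell_min"):
            df[c] = pd.Series(dtype=float)
        df["stationary"] = pd.Series(dtype=bool)
        df["degenerate"] = pd.Series(dtype=bool)
        return df
    if not df["timestamp"].is_monotonic_increasing:
        raise ValueError("GPS points must be sorted by timestamp")
    lat = df["lat"].to_numpy(float)
    lon = df["lon"].to_numpy(float)
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    ts = dt64(df["timestamp"])
    dist = np.full(n, np.nan)
    dt = np.full(n, np.nan)
    if n > 1:
        dist[1:] = haversine_m((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
        dt[1:] = (ts[1:] - ts[:-1]) / np.timedelta64(1, "s")
    degenerate = dt == 0
    speed = np.full(n, np.nan)
    ok = (dt > 0) & np.isfinite(dist)
    speed[ok] = dist[ok] / dt[ok]
    stationary = np.zeros(n, bool)
    stationary[ok] = (speed[ok] < WALKING_SPEED_MPS) & (dist[ok] < STATIONARY_DISTANCE_M)
    if n > 1:
        # first point inherits the first pair's label
        first_pair = np.flatnonzero(ok)
        stationary[0] = stationary[first_pair[0]] if first_pair.size else True
    else:
        stationary[0] = True
    dwell = np.zeros(n)
    if n > 1:
        fwd = (ts[1:] - ts[:-1]) / np.timedelta64(1, "m")
        dwell[:-1] = np.minimum(fwd, DWELL_CAP_MIN)
    df["distance_m"] = dist
    df["dt_s"] = dt
    df["speed_mps"] = speed
    df["stationary"] = stationary
    df["degenerate"] = degenerate
    df["dwell_min"] = dwell
    return df


@dataclass
class ClusterSet:
    """Result of density clustering of stationary points.

    ``assignments`` is aligned with the stationary-point frame passed to
    :func:`cluster_stationary`; -1 marks noise.  Cluster ids are canonical:
    clusters are numbered by the earliest timestamp of their core points, so
    the labeling is invariant to input order.
    """

    assignments: np.ndarray
    core_mask: np.ndarray
    home_id: int | None = None
    home_is_fallback: bool = False
    min_samples_used: int = 0
    eps_used: float = DBSCAN_EPS_RAD
    night_counts: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        labels = self.assignments
        return int(len(set(labels[labels >= 0])))


def min_samples_for(n_total_points: int) -> int:
    """min_samples = 3% of the person's total GPS points, at least 2."""
    return max(2, math.ceil(MIN_SAMPLES_FRACTION * n_total_points))


def cluster_stationary(
    stationary: pd.DataFrame,
    n_total_points: int,
    eps_rad: float = DBSCAN_EPS_RAD,
    min_samples: int | None = None,
) -> ClusterSet:
    """DBSCAN over stationary points with great-circle (haversine) distance.

    min_samples defaults to max(2, ceil(0.03 * n_total_points)).  Core points
    and their partition are order-invariant by construction; border points
    are assigned deterministically to the cluster of their earliest-timestamp
    core neighbor within eps, so the full partition is invariant to input
    permutation up to label names (labels themselves are canonicalized by
    earliest core-point timestamp).
    """
    if min_samples is None:
        min_samples = min_samples_for(n_total_points)
    n = len(stationary)
    if n == 0:
        return ClusterSet(
            assignments=np.empty(0, int),
            core_mask=np.empty(0, bool),
            min_samples_used=min_samples,
            eps_used=eps_rad,
        )
    coords = np.radians(stationary[["lat", "lon"]].to_numpy(float))
    db = DBSCAN(eps=eps_rad, min_samples=min_samples, metric="haversine").fit(coords)
    core_mask = np.zeros(n, bool)
    core_mask[db.core_sample_indices_] = True
    labels = np.full(n, -1, int)
    if core_mask.any():
        ts = dt64(stationary["timestamp"])
        core_idx = np.flatnonzero(core_mask)
        labels[core_idx] = db.labels_[core_idx]
        # deterministic border assignment: earliest-timestamp core neighbor
        border_idx = np.flatnonzero(~core_mask)
        if border_idx.size:
            nn = NearestNeighbors(metric="haversine").fit(coords[core_idx])
            neigh = nn.radius_neighbors(coords[border_idx], radius=eps_rad, return_distance=False)
            for b, cands in zip(border_idx, neigh):
                if len(cands):
                    chosen = core_idx[cands[np.argmin(ts[core_idx[cands]])]]
                    labels[b] = labels[chosen]
        # canonical labels ordered by earliest core timestamp per cluster
        order = {}
        for lab in np.unique(labels[labels >= 0]):
            members = core_idx[labels[core_idx] == lab]
            order[lab] = ts[members].min() if members.size else ts[labels == lab].min()
        remap = {old: new for new, old in enumerate(sorted(order, key=lambda k: order[k]))}
        labels = np.array([remap.get(l, -1) for l in labels], int)
    return ClusterSet(
        assignments=labels,
        core_mask=core_mask,
        min_samples_used=min_samples,
        eps_used=eps_rad,
    )


def night_windows(start, end, utc_offset_h: int = 1):
    """Enumerate (start, end) UTC bounds of local 20:00-06:00 nights in span."""
    tz = pd.Timedelta(hours=utc_offset_h)
    local_start = (pd.Timestamp(start) + tz).normalize()
    local_end = (pd.Timestamp(end) + tz).normalize()
    nights = []
    day = local_start - pd.Timedelta(days=1)
    while day <= local_end:
        ns = day + pd.Timedelta(hours=NIGHT_START_H) - tz
        ne = day + pd.Timedelta(days=1, hours=NIGHT_END_H) - tz
        if ne > pd.Timestamp(start) and ns < pd.Timestamp(end):
            nights.append((ns, ne))
        day += pd.Timedelta(days=1)
    return nights


def find_home(
    cluster_set: ClusterSet,
    stationary: pd.DataFrame,
    nights: list[tuple],
    min_nights: int = 4,
    min_night_frac: float = 0.5,
) -> ClusterSet:
    """Select the home cluster from night occupancy, with a fallback.

    A night (local 20:00-06:00) counts toward the cluster holding the
    maximal dwell within that night.  Home is the cluster with >= 4 nights
    AND >= 50% of assessed nights (nights with any clustered dwell).  If no
    cluster qualifies, the fallback is the most-visited cluster by total
    dwell minutes (ties: more member points, then lower id).
    """
    cs = cluster_set
    labels = cs.assignments
    if len(stationary) == 0 or cs.n_clusters == 0:
        cs.home_id = None
        cs.home_is_fallback = False
        return cs
    ts = dt64(stationary["timestamp"])
    dwell = stationary["dwell_min"].to_numpy(float)
    night_hits: dict[int, int] = {}
    assessed = 0
    for ns, ne in nights:
        in_night = (ts >= dt64(ns)) & (ts < dt64(ne)) & (labels >= 0)
        if not in_night.any():
            continue
        assessed += 1
        per = {}
        for lab in np.unique(labels[in_night]):
            per[lab] = dwell[in_night & (labels == lab)].sum()
        best = max(per, key=lambda k: (per[k], -k))
        night_hits[best] = night_hits.get(best, 0) + 1
    cs.night_counts = dict(night_hits)
    home = None
    for lab, cnt in sorted(night_hits.items()):
        if cnt >= min_nights and assessed > 0 and cnt >= min_night_frac * assessed:
            if home is None or cnt > night_hits[home]:
                home = lab
    if home is not None:
        cs.home_id = int(home)
        cs.home_is_fallback = False
        return cs
    # fallback: greatest total dwell, then most points, then lowest id
    cands = []
    for lab in np.unique(labels[labels >= 0]):
        m = labels == lab
        cands.append((dwell[m].sum(), int(m.sum()), -int(lab)))
    best = max(range(len(cands)), key=lambda i: cands[i])
    cs.home_id = int(-cands[best][2])
    cs.home_is_fallback = True
    return cs


def mobility_features(
    annotated: pd.DataFrame,
    cluster_labels_full: np.ndarray,
    home_id: int | None,
    window: tuple,
    block_minutes: float = 120.0,
) -> dict:
    """Per-block mobility features over the half-open window [start, end).

    ``annotated`` is the full annotated trace; ``cluster_labels_full`` aligns
    with it (-1 for non-stationary / noise points).  Distance sums consecutive
    in-window segments only; dwell minutes are attributed to the point opening
    each interval.
    """
    start, end = window
    ts = dt64(annotated["timestamp"])
    m = (ts >= dt64(start)) & (ts < dt64(end))
    n_pts = int(m.sum())
    if n_pts == 0:
        return {
            "distance_km": np.nan,
            "n_gps_points": np.nan,
            "minutes_home": np.nan,
            "minutes_transition": np.nan,
            "minutes_stationary": np.nan,
            "missing_gps": True,
        }
    sub = annotated.loc[m]
    lat = sub["lat"].to_numpy(float)
    lon = sub["lon"].to_numpy(float)
    dist_m = float(np.sum(haversine_m((lat[:-1], lon[:-1]), (lat[1:], lon[1:])))) if n_pts > 1 else 0.0
    dwell = sub["dwell_min"].to_numpy(float)
    stat = sub["stationary"].to_numpy(bool)
    labs = cluster_labels_full[m]
    minutes_stationary = float(dwell[stat].sum())
    minutes_transition = float(dwell[~stat].sum())
    # no home cluster at all -> home-dependent feature is missing, not zero
    minutes_home = float(dwell[stat & (labs == home_id)].sum()) if home_id is not None else np.nan
    return {
        "distance_km": dist_m / 1000.0,
        "n_gps_points": float(n_pts),
        "minutes_home": minutes_home,
        "minutes_transition": minutes_transition,
        "minutes_stationary": minutes_stationary,
        "missing_gps": False,
    }


@dataclass
class GpsPipelineResult:
    annotated: pd.DataFrame
    cluster_set: ClusterSet
    labels_full: np.ndarray


def cluster_report(result: "GpsPipelineResult") -> dict:
    """JSON-ready summary: per-cluster centroid, dwell, nights, home flag."""
    ann = result.annotated
    stat = ann[ann["stationary"]].reset_index(drop=True)
    cs = result.cluster_set
    clusters = []
    for lab in sorted(set(cs.assignments[cs.assignments >= 0])):
        m = cs.assignments == lab
        clusters.append({
            "id": int(lab),
            "centroid": [float(stat.loc[m, "lat"].mean()),
                         float(stat.loc[m, "lon"].mean())],
            "n_points": int(m.sum()),
            "dwell_min": float(stat.loc[m, "dwell_min"].sum()),
            "night_count": int(cs.night_counts.get(lab, 0)),
            "is_home": bool(cs.home_id == lab),
        })
    return {
        "n_points_total": int(len(ann)),
        "min_samples": int(cs.min_samples_used),
        "eps_radians": float(cs.eps_used),
        "home_id": None if cs.home_id is None else int(cs.home_id),
        "home_is_fallback": bool(cs.home_is_fallback),
        "clusters": clusters,
    }


def process_trace(points: pd.DataFrame, utc_offset_h: int = 1) -> GpsPipelineResult:
    """Run annotation, clustering and home detection for one participant."""
    ann = annotate_movement(points)
    stat = ann[ann["stationary"]]
    cs = cluster_stationary(stat, n_total_points=len(ann))
    if len(ann):
        nights = night_windows(ann["timestamp"].min(), ann["timestamp"].max(), utc_offset_h)
    else:
        nights = []
    cs = find_home(cs, stat, nights)
    labels_full = np.full(len(ann), -1, int)
    if len(stat):
        labels_full[np.flatnonzero(ann["stationary"].to_numpy(bool))] = cs.assignments
    return GpsPipelineResult(annotated=ann, cluster_set=cs, labels_full=labels_full)
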