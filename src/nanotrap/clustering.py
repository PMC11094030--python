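"""Spatiotemporal nanocluster detection by 3D DBSCAN.

Detections from all trajectories are embedded in (x, y, pseudo-time):
the temporal axis is rescaled by epsilon/time_window so that a single
neighborhood radius epsilon applies in both space and transformed time
(two co-located detections separated by exactly one time window are
exactly epsilon apart).  DBSCAN in this 3D metric yields clusters that
are compact in space *and* time — spatiotemporal nanoclusters.  From the
clusters we compute the per-cell metrics reported for nanocluster
analyses: radius, lifetime, density, the fraction of clusters belonging
to hotspots (repeated clustering at the same membrane location), and
per-cluster trajectory rates during vs. immediately before the cluster
lifetime.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.neighbors import NearestNeighbors

from .tracks import TrackSet, filter_tracks

__all__ = [
    "ClusteringParams",
    "SpatioTemporalCluster",
    "ClusterMetrics",
    "BOOSH_NEURONS",
    "BOOSH_PC12",
    "NASTIC_LIKE",
    "pseudo_spatial_transform",
    "dbscan3d",
    "find_clusters",
    "screen_clusters",
    "cluster_metrics",
    "detect_hotspots",
    "trajectory_rates",
]


@dataclass
class ClusteringParams:
    """Parameters of the spatiotemporal clustering and its screens."""

    epsilon: float = 0.05            # µm, neighborhood radius
    min_points: int = 3              # DBSCAN core threshold (self included)
    time_window: float = 10.0        # s mapped onto epsilon
    acquisition_time: float | None = None
    frame_time: float = 0.02
    cluster_size_screen: float = 0.15   # µm, max cluster radius
    min_traj_length: int = 8
    max_traj_length: int = 100
    msd_screen: bool = False
    radius_factor: float = 1.0       # compatibility multiplier on the footprint
    cluster_threshold: int = 3       # min member trajectories

    def validate(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")
        if self.time_window <= 0:
            raise ValueError("time_window must be positive")


# Published presets for the two cell systems analyzed with this pipeline.
BOOSH_NEURONS = ClusteringParams(epsilon=0.05, min_points=8, time_window=10.0,
                                 acquisition_time=60.0, cluster_size_screen=0.3)
BOOSH_PC12 = ClusteringParams(epsilon=0.05, min_points=3, time_window=10.0,
                              acquisition_time=320.0, cluster_size_screen=0.15)
NASTIC_LIKE = ClusteringParams(epsilon=0.05, min_points=3, time_window=20.0,
                               acquisition_time=320.0, cluster_size_screen=0.15,
                               radius_factor=1.2, cluster_threshold=3)


@dataclass
class SpatioTemporalCluster:
    """One DBSCAN cluster of detections with spatial and temporal extent."""

    cluster_id: int
    traj_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray
    centroid: tuple[float, float] = field(init=False)
    radius: float = field(init=False)       # RMS member distance to centroid
    t_start: float = field(init=False)
    t_end: float = field(init=False)

    def __post_init__(self) -> None:
        cx, cy = float(np.mean(self.x)), float(np.mean(self.y))
        self.centroid = (cx, cy)
        self.radius = float(np.sqrt(np.mean((self.x - cx) ** 2
                                            + (self.y - cy) ** 2)))
        self.t_start = float(np.min(self.t))
        self.t_end = float(np.max(self.t))

    @property
    def lifetime(self) -> float:
        return self.t_end - self.t_start

    @property
    def n_detections(self) -> int:
        return len(self.x)

    @property
    def n_trajectories(self) -> int:
        return len(np.unique(self.traj_ids))

    def footprint_radius(self, radius_factor: float = 1.0) -> float:
        return self.radius * radius_factor


@dataclass
class ClusterMetrics:
    """Per-cell nanocluster summary."""

    density: float                 # clusters/µm²
    mean_radius: float             # µm
    mean_lifetime: float           # s
    hotspot_fraction: float        # %
    n_clusters: int
    per_cluster: pd.DataFrame      # one row per surviving cluster


# ---------------------------------------------------------------------------
# Transform + DBSCAN
# ---------------------------------------------------------------------------

def pseudo_spatial_transform(ts: TrackSet | pd.DataFrame,
                             params: ClusteringParams
                             ) -> tuple[np.ndarray, pd.DataFrame]:
    """Map detections to (x, y, t·epsilon/time_window).

    Returns the 3D point cloud and the matching detection table, both
    canonically sorted by (t, traj) so that clustering is deterministic.
    """
    params.validate()
    df = ts.data if isinstance(ts, TrackSet) else ts
    df = df.sort_values(["t", "traj"], kind="stable").reset_index(drop=True)
    scale = params.epsilon / params.time_window
    pts = np.column_stack([df["x"].to_numpy(), df["y"].to_numpy(),
                           df["t"].to_numpy() * scale])
    return pts, df


def dbscan3d(points: np.ndarray, epsilon: float, min_points: int) -> np.ndarray:
    """Deterministic DBSCAN in the transformed 3D metric.

    Standard semantics: a core point has >= min_points neighbors within
    epsilon (itself included); clusters are the connected components of
    core points with their reachable border points; noise is labeled -1.
    Points are processed in input order and border points join the first
    cluster that reaches them, making the labeling deterministic for a
    fixed input order.
    """
    points = np.asarray(points, dtype=float)
    n = len(points)
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    nn = NearestNeighbors(radius=epsilon)
    nn.fit(points)
    neigh = nn.radius_neighbors(points, return_distance=False)
    core = np.array([len(a) >= min_points for a in neigh])
    visited = np.zeros(n, dtype=bool)
    cid = 0
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        # grow a new cluster from this core point (BFS, input order)
        labels[i] = cid
        visited[i] = True
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for k in sorted(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                if core[k] and not visited[k]:
                    visited[k] = True
                    queue.append(k)
        cid += 1
    return labels


def find_clusters(ts: TrackSet, params: ClusteringParams,
                  prefilter: bool = True) -> list[SpatioTemporalCluster]:
    """Run the full detection: length filter, transform, 3D DBSCAN.

    Returns raw (unscreened) clusters; apply :func:`screen_clusters` or
    :func:`cluster_metrics` for the size and membership screens.
    """
    params.validate()
    if prefilter:
        ts = filter_tracks(ts, min_len=params.min_traj_length,
                           max_len=params.max_traj_length)
    pts, df = pseudo_spatial_transform(ts, params)
    labels = dbscan3d(pts, params.epsilon, params.min_points)
    clusters = []
    for cid in np.unique(labels[labels >= 0]):
        m = labels == cid
        clusters.append(SpatioTemporalCluster(
            cluster_id=int(cid),
            traj_ids=df.loc[m, "traj"].to_numpy(),
            x=df.loc[m, "x"].to_numpy(),
            y=df.loc[m, "y"].to_numpy(),
            t=df.loc[m, "t"].to_numpy(),
        ))
    return clusters


def screen_clusters(clusters: list[SpatioTemporalCluster],
                    params: ClusteringParams) -> list[SpatioTemporalCluster]:
    """Discard clusters larger than the size screen or with fewer member
    trajectories than the cluster threshold."""
    return [c for c in clusters
            if c.radius <= params.cluster_size_screen
            and c.n_trajectories >= params.cluster_threshold]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def cluster_metrics(clusters: list[SpatioTemporalCluster], roi_area: float,
                    params: ClusteringParams) -> ClusterMetrics:
    """Density, mean radius/lifetime and hotspot fraction after screening."""
    if roi_area <= 0:
        raise ValueError("roi_area must be positive")
    surv = screen_clusters(clusters, params)
    if not surv:
        empty = pd.DataFrame(columns=["cluster_id", "cx", "cy", "radius",
                                      "t_start", "t_end", "lifetime",
                                      "n_detections", "n_trajectories",
                                      "hotspot"])
        return ClusterMetrics(0.0, math.nan, math.nan, 0.0, 0, empty)
    frac, flags = detect_hotspots(surv)
    per = pd.DataFrame({
        "cluster_id": [c.cluster_id for c in surv],
        "cx": [c.centroid[0] for c in surv],
        "cy": [c.centroid[1] for c in surv],
        "radius": [c.radius for c in surv],
        "t_start": [c.t_start for c in surv],
        "t_end": [c.t_end for c in surv],
        "lifetime": [c.lifetime for c in surv],
        "n_detections": [c.n_detections for c in surv],
        "n_trajectories": [c.n_trajectories for c in surv],
        "hotspot": flags,
    })
    return ClusterMetrics(
        density=len(surv) / roi_area,
        mean_radius=float(per["radius"].mean()),
        mean_lifetime=float(per["lifetime"].mean()),
        hotspot_fraction=frac,
        n_clusters=len(surv),
        per_cluster=per,
    )


def detect_hotspots(clusters: list[SpatioTemporalCluster]
                    ) -> tuple[float, np.ndarray]:
    """Fraction (%) of clusters that re-form at the same membrane location.

    A cluster belongs to a hotspot if another cluster with a strictly
    non-overlapping lifetime has its centroid within the sum of the two
    radii.  Returns the percentage and the per-cluster boolean flags.
    """
    n = len(clusters)
    flags = np.zeros(n, dtype=bool)
    for i in range(n):
        ci = clusters[i]
        for j in range(i + 1, n):
            cj = clusters[j]
            disjoint = ci.t_end < cj.t_start or cj.t_end < ci.t_start
            if not disjoint:
                continue
            dx = ci.centroid[0] - cj.centroid[0]
            dy = ci.centroid[1] - cj.centroid[1]
            if math.hypot(dx, dy) <= ci.radius + cj.radius:
                flags[i] = True
                flags[j] = True
    frac = 100.0 * flags.mean() if n else 0.0
    return float(frac), flags


def trajectory_rates(cluster: SpatioTemporalCluster, ts: TrackSet,
                     radius_factor: float = 1.0) -> tuple[float, float]:
    """Trajectory rates at the cluster location before vs during its life.

    ``rate_during`` counts trajectories with at least one detection inside
    the cluster's xy footprint during [t_start, t_end], per second of
    lifetime; ``rate_before`` applies the same spatial footprint to the
    window of equal length immediately before t_start (clipped at the
    acquisition start, normalizing by the actual window).  Zero-lifetime
    clusters are undefined and reported as (nan, nan) with a warning.
    """
    life = cluster.lifetime
    if life <= 0:
        warnings.warn(f"cluster {cluster.cluster_id} has zero lifetime; "
                      "rates undefined")
        return (math.nan, math.nan)
    r = cluster.footprint_radius(radius_factor)
    cx, cy = cluster.centroid
    df = ts.data
    inside = (df["x"] - cx) ** 2 + (df["y"] - cy) ** 2 <= r ** 2
    t = df["t"]
    during = inside & (t >= cluster.t_start) & (t <= cluster.t_end)
    before_start = max(cluster.t_start - life, 0.0)
    before_win = cluster.t_start - before_start
    before = inside & (t >= before_start) & (t < cluster.t_start)
    n_during = df.loc[during, "traj"].nunique()
    n_before = df.loc[before, "traj"].nunique()
    rate_during = n_during / life
    rate_before = n_before / before_win if before_win > 0 else math.nan
    return (float(rate_before), float(rate_during))
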