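"""Shared fixtures: synthetic acquisitions reused across test modules.

Session scope keeps the heavier trapping simulations to a single run.
"""

import numpy as np
import pytest

from nanotrap import clustering, synthetic, tracks


@pytest.fixture(scope="session")
def trap_config():
    """A trapping-rich acquisition: dense, long-lived clusters, high
    capture probability, no escape — the regime where lateral trapping
    dominates the trajectory statistics."""
    return synthetic.SimulationConfig(
        roi_side=4.0, duration=40.0, stim_time=20.0,
        cluster_density=1.0, cluster_radius=0.12, cluster_lifetime=25.0,
        d_free=0.1, d_confined=0.003,
        recruitment_rate_pre=0.6, recruitment_rate_post=1.5,
        trap_probability=0.9, escape_rate=0.0, bleach_rate=1.0,
        localization_sigma=0.01, seed=42,
    )


@pytest.fixture(scope="session")
def trap_sim(trap_config):
    ts, gt = synthetic.generate_tracks(trap_config)
    return tracks.filter_tracks(ts), gt


@pytest.fixture(scope="session")
def trap_clusters(trap_sim):
    """DBSCAN nanoclusters detected on the trapping simulation."""
    ts, _gt = trap_sim
    params = clustering.ClusteringParams(
        epsilon=0.05, min_points=8, time_window=10.0,
        cluster_size_screen=0.3)
    cl = clustering.screen_clusters(clustering.find_clusters(ts, params),
                                    params)
    return cl, params


@pytest.fixture(scope="session")
def forced_trap_sim():
    """Forced-capture acquisition (trap probability 1, no escape) with
    noiseless detections; used for label-recovery checks."""
    cfg = synthetic.SimulationConfig(
        roi_side=4.0, duration=30.0, stim_time=15.0,
        cluster_density=1.0, cluster_radius=0.15, cluster_lifetime=40.0,
        d_free=0.1, d_confined=0.002,
        recruitment_rate_pre=1.0, recruitment_rate_post=1.0,
        trap_probability=1.0, escape_rate=0.0, bleach_rate=1.0,
        localization_sigma=0.0, seed=7,
    )
    ts, gt = synthetic.generate_tracks(cfg)
    return cfg, ts, gt


@pytest.fixture(scope="session")
def recovery_sim():
    """Layout-recovery acquisition.

    Designed so that every occupied planted cluster maps to one cohesive
    detection cloud while free motion leaves no dense structures: the
    footprint is on the neighborhood (epsilon) scale so a captured
    track's detections concentrate within one DBSCAN ball; cluster
    lifetimes sit inside the time window so occupancy is temporally
    contiguous; free diffusion is fast enough that untrapped tracks do
    not linger (transient stops of slow walkers mimic confinement);
    and the track density stays well below the mistracking limit.
    Clustering this field uses min_points matched to the per-visitor
    detection yield (a captured track leaves ~25-60 detections in its
    host, coincidental free crossings far fewer).
    """
    cfg = synthetic.SimulationConfig(
        roi_side=10.0, duration=40.0, stim_time=20.0,
        cluster_density=0.54, cluster_radius=0.06, cluster_lifetime=8.0,
        d_free=0.5, d_confined=0.01,
        recruitment_rate_pre=0.15, recruitment_rate_post=0.15,
        trap_probability=1.0, escape_rate=0.0, bleach_rate=1.5,
        localization_sigma=0.0, seed=13,
    )
    ts, gt = synthetic.generate_tracks(cfg)
    return cfg, ts, gt


def truth_clusters(gt):
    """Planted cluster layout as SpatioTemporalCluster-compatible stand-ins."""
    out = []
    for i in range(gt.clusters.n):
        out.append(_TruthCluster(
            cluster_id=i,
            centroid=(gt.clusters.centers[i, 0], gt.clusters.centers[i, 1]),
            radius=float(gt.clusters.radii[i]),
            t_start=float(gt.clusters.t_birth[i]),
            t_end=float(gt.clusters.t_death[i]),
        ))
    return out


class _TruthCluster:
    """Duck-typed cluster built from generator ground truth."""

    def __init__(self, cluster_id, centroid, radius, t_start, t_end):
        self.cluster_id = cluster_id
        self.centroid = centroid
        self.radius = radius
        self.t_start = t_start
        self.t_end = t_end

    @property
    def lifetime(self):
        return self.t_end - self.t_start

    def footprint_radius(self, radius_factor=1.0):
        return self.radius * radius_factor
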