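"""Synthetic sptPALM acquisitions with known ground truth.

Emulates the statistical structure of single-particle tracking of a
membrane protein that is recruited to the plasma membrane, diffuses
laterally, and becomes trapped in nanoscale clusters: 50 Hz frames,
photoblinking-limited track lifetimes of ~8–100 detections, membrane
diffusion of 0.02–0.05 µm²/s, nanoclusters of ~0.08–0.1 µm radius at
0.5–3 clusters/µm², a step increase of the molecule-appearance rate at
stimulation, Bernoulli capture on cluster crossing with reflecting
confinement, and isotropic Gaussian localization noise.

Every downstream stage (mobility, clustering, trapping, kinetics, model
fitting) is exercised against these generators, whose labels are exact.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .tracks import TrackSet

__all__ = [
    "SimulationConfig",
    "ClusterField",
    "GroundTruth",
    "generate_cluster_field",
    "generate_tracks",
    "generate_intensity_trace",
    "biphasic_curve",
]


@dataclass
class SimulationConfig:
    """Generator settings; defaults are the study conditions being emulated.

    Rates are per µm² per s for appearances, per s for escape/bleach;
    lengths in µm, times in s.  ``seed`` is mandatory for track
    generation — reproducibility is part of the contract.
    """

    roi_side: float = 10.0
    frame_time: float = 0.02           # 50 Hz acquisition
    duration: float = 60.0
    cluster_density: float | None = 0.54   # clusters/µm², pre-stimulation scale
    n_clusters: int | None = None
    cluster_radius: float = 0.09
    cluster_lifetime: float = 8.0      # mean, exponential
    cluster_layout: str = "uniform"    # or "grid"
    d_free: float = 0.045
    d_confined: float = 0.005
    recruitment_rate_pre: float = 0.3  # appearances µm⁻² s⁻¹
    recruitment_rate_post: float = 0.9
    stim_time: float = 30.0
    trap_probability: float = 0.3      # per cluster crossing
    escape_rate: float = 0.2           # s⁻¹
    bleach_rate: float = 2.5           # s⁻¹ → geometric track lifetime
    localization_sigma: float = 0.02
    seed: int | None = None

    def validate(self) -> None:
        if self.roi_side <= 0:
            raise ValueError("roi_side must be positive")
        if self.frame_time <= 0:
            raise ValueError("frame_time must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name in ("cluster_radius", "cluster_lifetime", "d_free",
                     "d_confined", "recruitment_rate_pre",
                     "recruitment_rate_post", "escape_rate", "bleach_rate",
                     "localization_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.d_confined > self.d_free:
            raise ValueError("d_confined must not exceed d_free")
        if not 0.0 <= self.trap_probability <= 1.0:
            raise ValueError("trap_probability must be in [0, 1]")
        if self.cluster_radius > self.roi_side / 2:
            raise ValueError("cluster_radius exceeds half the ROI side")

    @property
    def roi_area(self) -> float:
        return self.roi_side ** 2


@dataclass
class ClusterField:
    """Planted cluster layout: centers, radii and lifetimes."""

    centers: np.ndarray        # (n, 2) µm
    radii: np.ndarray          # (n,) µm
    t_birth: np.ndarray        # (n,) s
    t_death: np.ndarray        # (n,) s

    @property
    def n(self) -> int:
        return len(self.radii)

    def alive(self, t: float) -> np.ndarray:
        return (self.t_birth <= t) & (t <= self.t_death)


@dataclass
class GroundTruth:
    """Per-trajectory labels plus the planted cluster layout.

    ``labels`` has one row per trajectory: ``traj``, ``trapped`` (bool),
    ``entry_step`` (index of the first in-cluster detection; -1 when never
    trapped), ``cluster_id`` (-1 when never trapped) and ``regime``
    ("free"/"trapped").  Entry steps index *true* positions inside the
    host footprint; localization noise is applied afterwards.
    """

    labels: pd.DataFrame
    clusters: ClusterField

    def entering(self) -> pd.DataFrame:
        """Trajectories that start free and later enter a cluster."""
        lab = self.labels
        return lab[lab["trapped"] & (lab["entry_step"] >= 1)]

    def to_json(self, path) -> None:
        payload = {
            "labels": self.labels.to_dict(orient="list"),
            "clusters": {
                "centers": self.clusters.centers.tolist(),
                "radii": self.clusters.radii.tolist(),
                "t_birth": self.clusters.t_birth.tolist(),
                "t_death": self.clusters.t_death.tolist(),
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        cf = ClusterField(
            centers=np.asarray(payload["clusters"]["centers"], float).reshape(-1, 2),
            radii=np.asarray(payload["clusters"]["radii"], float),
            t_birth=np.asarray(payload["clusters"]["t_birth"], float),
            t_death=np.asarray(payload["clusters"]["t_death"], float),
        )
        return cls(labels=pd.DataFrame(payload["labels"]), clusters=cf)


# ---------------------------------------------------------------------------
# Cluster layout
# ---------------------------------------------------------------------------

def generate_cluster_field(config: SimulationConfig,
                           rng: np.random.Generator | None = None) -> ClusterField:
    """Place nanoclusters in the ROI.

    ``uniform`` layout: Poisson count with mean density × area, uniform
    centers, births uniform over the acquisition and exponential lifetimes.
    ``grid`` layout: regular grid at spacing 1/sqrt(density), alive for the
    whole acquisition (the evenly-distributed geometry used by the
    reaction-diffusion model).
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    L = config.roi_side
    if config.cluster_layout == "grid":
        if not config.cluster_density or config.cluster_density <= 0:
            return _empty_field()
        spacing = 1.0 / math.sqrt(config.cluster_density)
        coords = np.arange(spacing / 2, L, spacing)
        cx, cy = np.meshgrid(coords, coords)
        centers = np.column_stack([cx.ravel(), cy.ravel()])
        n = len(centers)
        return ClusterField(
            centers=centers,
            radii=np.full(n, config.cluster_radius),
            t_birth=np.zeros(n),
            t_death=np.full(n, config.duration),
        )
    if config.n_clusters is not None:
        n = int(config.n_clusters)
    else:
        density = config.cluster_density or 0.0
        if density < 0:
            raise ValueError("cluster_density must be non-negative")
        n = int(rng.poisson(density * config.roi_area))
    if n == 0:
        return _empty_field()
    centers = rng.uniform(0.0, L, size=(n, 2))
    births = rng.uniform(0.0, config.duration, size=n)
    lifetimes = (rng.exponential(config.cluster_lifetime, size=n)
                 if config.cluster_lifetime > 0 else np.zeros(n))
    return ClusterField(
        centers=centers,
        radii=np.full(n, config.cluster_radius),
        t_birth=births,
        t_death=births + lifetimes,
    )


def _empty_field() -> ClusterField:
    return ClusterField(centers=np.empty((0, 2)), radii=np.empty(0),
                        t_birth=np.empty(0), t_death=np.empty(0))


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def generate_tracks(
    config: SimulationConfig,
    clusters: ClusterField | None = None,
) -> tuple[TrackSet, GroundTruth]:
    """Simulate an sptPALM acquisition and return tracks plus ground truth.

    Molecules appear as a Poisson process whose rate steps from
    ``recruitment_rate_pre`` to ``recruitment_rate_post`` at ``stim_time``.
    Free molecules take 2D Brownian steps (variance ``2·d_free·frame_time``
    per axis, reflected at the ROI boundary).  On crossing into a live
    cluster footprint a molecule is captured with ``trap_probability``;
    captured molecules diffuse at ``d_confined`` with reflection at the
    cluster boundary until escape (rate ``escape_rate``), cluster death, or
    photobleaching (geometric lifetime at ``bleach_rate``).  Detections are
    the true positions plus isotropic Gaussian noise.  All randomness flows
    from ``config.seed`` through per-molecule substreams.
    """
    config.validate()
    if config.seed is None:
        raise ValueError("config.seed is required; reproducibility is mandatory")
    ss = np.random.SeedSequence(config.seed)
    root = np.random.default_rng(ss.spawn(1)[0])
    if clusters is None:
        clusters = generate_cluster_field(config, rng=root)

    dt = config.frame_time
    L = config.roi_side
    area = config.roi_area
    stim = min(config.stim_time, config.duration)

    # appearance times: two-piece homogeneous Poisson process
    n_pre = root.poisson(config.recruitment_rate_pre * area * stim)
    n_post = root.poisson(config.recruitment_rate_post * area
                          * (config.duration - stim))
    births = np.concatenate([
        root.uniform(0.0, stim, size=n_pre),
        root.uniform(stim, config.duration, size=n_post),
    ])
    births.sort()
    n_mol = len(births)

    p_bleach = 1.0 - math.exp(-config.bleach_rate * dt) if config.bleach_rate > 0 else 0.0
    p_escape = 1.0 - math.exp(-config.escape_rate * dt) if config.escape_rate > 0 else 0.0
    sig_free = math.sqrt(2.0 * config.d_free * dt)
    sig_conf = math.sqrt(2.0 * config.d_confined * dt)

    streams = ss.spawn(n_mol + 1)[1:]
    rows_traj, rows_x, rows_y, rows_t = [], [], [], []
    labels = []
    for i in range(n_mol):
        rng = np.random.default_rng(streams[i])
        t0 = births[i]
        frame0 = int(math.ceil(t0 / dt))
        max_frames = int(math.floor(config.duration / dt)) - frame0 + 1
        if max_frames < 1:
            continue
        n_det = int(rng.geometric(p_bleach)) if p_bleach > 0 else max_frames
        n_det = min(n_det, max_frames)
        pos = rng.uniform(0.0, L, size=2)
        host = -1          # cluster index while trapped
        entry_step = -1
        entry_host = -1    # host at the moment of first capture
        xs = np.empty(n_det)
        ys = np.empty(n_det)
        for k in range(n_det):
            t = (frame0 + k) * dt
            if k > 0:
                if host >= 0:
                    # confinement ends if the host cluster dies
                    if t > clusters.t_death[host]:
                        host = -1
                if host >= 0:
                    pos = pos + rng.normal(0.0, sig_conf, size=2)
                    pos = _reflect_circle(pos, clusters.centers[host],
                                          clusters.radii[host])
                    if p_escape > 0 and rng.random() < p_escape:
                        host = -1
                else:
                    # status at the previous detection: a cluster born in
                    # between counts as a fresh crossing opportunity
                    prev_inside = _inside_which(pos, clusters, t - dt)
                    pos = pos + rng.normal(0.0, sig_free, size=2)
                    pos = _reflect_box(pos, L)
                    idx = _inside_which(pos, clusters, t)
                    if idx >= 0 and prev_inside < 0:
                        if config.trap_probability >= 1.0 or (
                                config.trap_probability > 0
                                and rng.random() < config.trap_probability):
                            host = idx
                            if entry_step < 0:
                                entry_step = k
                                entry_host = idx
            else:
                idx = _inside_which(pos, clusters, t)
                if idx >= 0:
                    if config.trap_probability >= 1.0 or (
                            config.trap_probability > 0
                            and rng.random() < config.trap_probability):
                        host = idx
                        entry_step = 0
                        entry_host = idx
            xs[k] = pos[0]
            ys[k] = pos[1]
        if config.localization_sigma > 0:
            xs = xs + rng.normal(0.0, config.localization_sigma, size=n_det)
            ys = ys + rng.normal(0.0, config.localization_sigma, size=n_det)
        tid = len(labels)
        rows_traj.append(np.full(n_det, tid))
        rows_x.append(xs)
        rows_y.append(ys)
        rows_t.append((frame0 + np.arange(n_det)) * dt)
        trapped = entry_step >= 0
        labels.append((tid, trapped, entry_step if trapped else -1,
                       entry_host, "trapped" if trapped else "free"))

    if rows_traj:
        df = pd.DataFrame({
            "traj": np.concatenate(rows_traj).astype(int),
            "x": np.concatenate(rows_x),
            "y": np.concatenate(rows_y),
            "t": np.concatenate(rows_t),
        })
    else:
        df = pd.DataFrame({"traj": pd.Series(dtype=int), "x": [], "y": [], "t": []})
    ts = TrackSet(df, frame_time=dt, roi_area=area, duration=config.duration)
    lab = pd.DataFrame(labels, columns=["traj", "trapped", "entry_step",
                                        "cluster_id", "regime"])
    return ts, GroundTruth(labels=lab, clusters=clusters)


def _reflect_box(pos: np.ndarray, L: float) -> np.ndarray:
    out = pos.copy()
    for a in range(2):
        v = out[a] % (2 * L)
        out[a] = v if v <= L else 2 * L - v
    return out


def _reflect_circle(pos: np.ndarray, center: np.ndarray, r: float) -> np.ndarray:
    d = pos - center
    dist = math.hypot(d[0], d[1])
    if dist <= r or dist == 0.0:
        return pos
    new_dist = max(2 * r - dist, 0.0)
    return center + d * (new_dist / dist)


def _inside_which(pos: np.ndarray, clusters: ClusterField, t: float) -> int:
    if clusters.n == 0:
        return -1
    live = clusters.alive(t)
    if not live.any():
        return -1
    d = clusters.centers - pos
    dist2 = np.einsum("ij,ij->i", d, d)
    inside = live & (dist2 <= clusters.radii ** 2)
    idx = np.flatnonzero(inside)
    return int(idx[0]) if len(idx) else -1


# ---------------------------------------------------------------------------
# Fluorescence traces
# ---------------------------------------------------------------------------

def biphasic_curve(t: np.ndarray, stim_time: float, t_peak: float,
                   fold: float, decay_rate: float = 0.0) -> np.ndarray:
    """Smooth fold-change curve: flat 1 before stimulation, sine-squared
    rise to ``fold`` at ``stim_time + t_peak``, then exponential decay."""
    t = np.asarray(t, dtype=float)
    tau = t - stim_time
    rise = np.sin(0.5 * math.pi * np.clip(tau / t_peak, 0.0, 1.0)) ** 2
    curve = 1.0 + (fold - 1.0) * rise
    post = tau > t_peak
    if decay_rate > 0:
        curve = np.where(
            post, 1.0 + (fold - 1.0) * np.exp(-decay_rate * (tau - t_peak)),
            curve)
    return curve


def generate_intensity_trace(
    times: np.ndarray,
    baseline: float,
    noise_sd: float = 0.0,
    bleach_rate: float = 0.0,
    seed: int | None = None,
    fold_curve: np.ndarray | None = None,
    stim_time: float = 0.0,
    roi_kind: str = "whole-cell",
):
    """Synthetic TIRF fluorescence-intensity trace.

    ``trace = baseline × fold_curve × exp(−bleach_rate·t) + N(0, noise_sd)``,
    deterministic given ``seed``.  Returns a :class:`~nanotrap.kinetics.IntensityTrace`.
    """
    from .kinetics import IntensityTrace

    times = np.asarray(times, dtype=float)
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if bleach_rate < 0:
        raise ValueError("bleach_rate must be non-negative")
    curve = np.ones_like(times) if fold_curve is None else np.asarray(fold_curve, float)
    fi = baseline * curve * np.exp(-bleach_rate * times)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fi = fi + rng.normal(0.0, noise_sd, size=len(times))
    return IntensityTrace(times=times, fi=fi, stim_time=stim_time,
                          roi_kind=roi_kind)
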