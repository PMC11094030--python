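"""Trajectory containers, TRXYT/CSV I/O and mobility metrics.

Single-particle tracking experiments (sptPALM at 50 Hz) yield thousands of
short trajectories per cell.  This module holds them in a tidy
:class:`pandas.DataFrame` wrapped by :class:`TrackSet`, reads/writes the
plain-text TRXYT format used by localization-clustering tools, applies the
standard length and density filters, and computes per-track mean squared
displacement (MSD), diffusion coefficients, and the mobile/immobile summary
statistics reported for each cell.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "TrackSet",
    "MSDProfile",
    "MobilityMetrics",
    "read_tracks",
    "write_tracks",
    "filter_tracks",
    "msd_curve",
    "mobility_metrics",
    "diffusion_length",
    "D_FLOOR",
]

#: Floor applied to diffusion coefficients before taking log10 (µm²/s).
D_FLOOR = 1e-5

#: Default histogram bin edges for Log10D frequency distributions.
LOG10D_BINS = np.round(np.arange(-5.0, 1.05, 0.1), 10)

TRACK_COLUMNS = ["traj", "x", "y", "t"]


@dataclass
class TrackSet:
    """A set of single-molecule trajectories from one acquisition.

    ``data`` has columns ``traj`` (trajectory id), ``x``/``y`` (µm), ``t``
    (s) and ``frame`` (``t / frame_time``, rounded).  Rows are sorted by
    (traj, t).
    """

    data: pd.DataFrame
    frame_time: float = 0.02
    roi_area: float = 1.0
    duration: float | None = None
    density_flagged: bool = False

    def __post_init__(self) -> None:
        if self.roi_area <= 0:
            raise ValueError("roi_area must be positive")
        df = self.data
        missing = [c for c in ("traj", "x", "y", "t") if c not in df.columns]
        if missing:
            raise ValueError(f"track table missing columns {missing}")
        if "frame" not in df.columns:
            df = df.assign(frame=np.rint(df["t"] / self.frame_time).astype(int))
        self.data = df.sort_values(["traj", "t"], kind="stable").reset_index(drop=True)
        if self.duration is None:
            self.duration = float(self.data["t"].max()) if len(self.data) else 0.0

    @property
    def n_tracks(self) -> int:
        return int(self.data["traj"].nunique())

    @property
    def track_density(self) -> float:
        """Trajectories per µm² of ROI over the whole acquisition."""
        return self.n_tracks / self.roi_area

    def lengths(self) -> pd.Series:
        return self.data.groupby("traj", sort=True).size()

    def iter_tracks(self):
        """Yield ``(traj_id, (n, 2) xy array, (n,) t array)`` per trajectory."""
        for tid, g in self.data.groupby("traj", sort=True):
            yield tid, g[["x", "y"]].to_numpy(), g["t"].to_numpy()

    def __len__(self) -> int:
        return self.n_tracks


@dataclass
class MSDProfile:
    """MSD curve of one trajectory and the short-lag linear fit."""

    lags: np.ndarray          # s, strictly increasing
    msd: np.ndarray           # µm²
    d_coef: float             # µm²/s, from MSD = 4 D τ + c, floored at D_FLOOR
    intercept: float          # µm²
    auc: float                # µm²·s, trapezoid over the reported lag range


@dataclass
class MobilityMetrics:
    """Per-cell mobility summary over a TrackSet."""

    d_per_track: pd.Series            # µm²/s indexed by traj
    log10d: pd.Series
    bin_edges: np.ndarray
    frequency: np.ndarray             # fractions, sums to 1
    mobile_fraction: float
    mobile_immobile_ratio: float      # inf sentinel when nothing is immobile
    mean_msd: np.ndarray              # µm², ragged average per lag
    msd_lags: np.ndarray              # s
    mean_auc: float                   # µm²·s
    logd_threshold: float = -1.45


def diffusion_length(d: float, t: float) -> float:
    """Root mean squared 2D displacement reach: sqrt(4 D t), in µm."""
    if d < 0 or t < 0:
        raise ValueError("d and t must be non-negative")
    return math.sqrt(4.0 * d * t)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_tracks(
    path,
    format: str = "trxyt",
    frame_time: float = 0.02,
    roi_area: float = 1.0,
    duration: float | None = None,
) -> TrackSet:
    """Read a trajectory table (TRXYT or CSV dialect) into a TrackSet.

    TRXYT is whitespace-separated ``traj x[µm] y[µm] t[s]`` with no header;
    the CSV dialect has a ``trajectory,x,y,t`` header.  Malformed lines are
    dropped with a warning naming their line numbers.  Non-monotonic time
    within a trajectory id raises, naming the id.
    """
    if format == "trxyt":
        raw = pd.read_csv(path, sep=r"\s+", header=None,
                          names=TRACK_COLUMNS, comment="#", dtype=str,
                          engine="python")
    elif format == "csv":
        raw = pd.read_csv(path, dtype=str)
        raw = raw.rename(columns={raw.columns[0]: "traj",
                                  raw.columns[1]: "x",
                                  raw.columns[2]: "y",
                                  raw.columns[3]: "t"})
    else:
        raise ValueError(f"unknown track format {format!r}")

    num = raw[TRACK_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = num.isna().any(axis=1)
    if bad.any():
        offset = 2 if format == "csv" else 1  # header line for csv
        lines = [int(i) + offset for i in np.flatnonzero(bad.to_numpy())]
        warnings.warn(f"dropped {bad.sum()} malformed line(s): {lines}")
        num = num[~bad]
    df = num.reset_index(drop=True)
    if len(df):
        df["traj"] = df["traj"].astype(int)
        for tid, g in df.groupby("traj"):
            dt = np.diff(g["t"].to_numpy())
            if len(dt) and (dt <= 0).any():
                raise ValueError(f"non-monotonic time in trajectory {tid}")
    return TrackSet(df, frame_time=frame_time, roi_area=roi_area,
                    duration=duration)


def write_tracks(ts: TrackSet, path, format: str = "trxyt") -> None:
    """Write a TrackSet as TRXYT (no header) or CSV (with header)."""
    df = ts.data[TRACK_COLUMNS]
    if format == "trxyt":
        df.to_csv(path, sep=" ", header=False, index=False,
                  float_format="%.9f")
    elif format == "csv":
        df.rename(columns={"traj": "trajectory"}).to_csv(
            path, index=False, float_format="%.9f")
    else:
        raise ValueError(f"unknown track format {format!r}")


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def filter_tracks(
    ts: TrackSet,
    min_len: int = 8,
    max_len: float = math.inf,
    density_limit: float = 50.0,
    reject: bool = False,
) -> TrackSet:
    """Keep trajectories with min_len <= length <= max_len.

    Tracks shorter than 8 detections are excluded by default to suppress
    non-specific background.  If the retained track density exceeds
    ``density_limit`` (trajectories/µm²; high detection densities induce
    mistracking) the returned set carries ``density_flagged=True``, or the
    whole set is rejected when ``reject`` is set.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    if min_len > max_len:
        raise ValueError("min_len > max_len")
    sizes = ts.lengths()
    keep = sizes.index[(sizes >= min_len) & (sizes <= max_len)]
    df = ts.data[ts.data["traj"].isin(keep)].reset_index(drop=True)
    out = replace(ts, data=df)
    if out.track_density > density_limit:
        if reject:
            raise ValueError(
                f"track density {out.track_density:.1f}/µm² exceeds "
                f"limit {density_limit}/µm²; acquisition rejected")
        warnings.warn(
            f"track density {out.track_density:.1f}/µm² exceeds "
            f"{density_limit}/µm²; flagging set (mistracking likely)")
        out.density_flagged = True
    return out


# ---------------------------------------------------------------------------
# MSD and mobility
# ---------------------------------------------------------------------------

def msd_curve(
    xy: np.ndarray,
    frame_time: float,
    max_lag: int | None = None,
    fit_points: int = 4,
) -> MSDProfile:
    """Time-origin-averaged MSD of one trajectory and its linear fit.

    MSD(τ_k) is averaged over all pairs of detections k frames apart.  The
    diffusion coefficient comes from an ordinary least-squares fit of
    ``MSD = 4 D τ + c`` over the first ``fit_points`` lags; the free
    intercept absorbs static localization noise.  D is floored at
    ``D_FLOOR`` so Log10D stays finite.  ``auc`` is the trapezoidal
    integral of the MSD over the reported lags (µm²·s).
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    if max_lag is None:
        max_lag = min(n - 1, 8)
    if max_lag >= n:
        raise ValueError(f"max_lag {max_lag} >= trajectory length {n}")
    if n <= fit_points:
        raise ValueError("trajectory shorter than the fit window")
    lags = np.arange(1, max_lag + 1) * frame_time
    msd = np.empty(max_lag)
    for k in range(1, max_lag + 1):
        d = xy[k:] - xy[:-k]
        msd[k - 1] = np.mean(np.einsum("ij,ij->i", d, d))
    npts = min(fit_points, max_lag)
    slope, intercept = np.polyfit(lags[:npts], msd[:npts], 1)
    d_coef = max(slope / 4.0, D_FLOOR)
    auc = float(np.trapezoid(msd, lags))
    return MSDProfile(lags=lags, msd=msd, d_coef=float(d_coef),
                      intercept=float(intercept), auc=auc)


def mobility_metrics(
    ts: TrackSet,
    logd_threshold: float = -1.45,
    lag_range: int = 8,
    fit_points: int = 4,
    bins: np.ndarray | None = None,
) -> MobilityMetrics:
    """Per-cell mobility summary: Log10D distribution, M/IMM, MSD, AUC.

    The mobile fraction is the share of tracks with Log10D above
    ``logd_threshold`` (µm²/s); the mobile-to-immobile ratio (M/IMM)
    divides the two counts and is reported as +inf (with a warning) when
    every track is mobile.  The mean MSD curve is a ragged average: each
    lag k ≤ ``lag_range`` averages over the tracks long enough to reach it.
    """
    if ts.n_tracks == 0:
        raise ValueError("empty TrackSet")
    if bins is None:
        bins = LOG10D_BINS
    d_vals, aucs, ids = [], [], []
    msd_sum = np.zeros(lag_range)
    msd_cnt = np.zeros(lag_range, dtype=int)
    for tid, xy, _t in ts.iter_tracks():
        if len(xy) <= fit_points:
            continue
        prof = msd_curve(xy, ts.frame_time,
                         max_lag=min(lag_range, len(xy) - 1),
                         fit_points=fit_points)
        ids.append(tid)
        d_vals.append(prof.d_coef)
        aucs.append(prof.auc)
        k = len(prof.msd)
        msd_sum[:k] += prof.msd
        msd_cnt[:k] += 1
    if not d_vals:
        raise ValueError("no trajectory long enough for an MSD fit")
    d_series = pd.Series(d_vals, index=ids, name="D")
    logd = np.log10(d_series.clip(lower=D_FLOOR))
    hist, _ = np.histogram(logd, bins=bins)
    freq = hist / hist.sum() if hist.sum() else hist.astype(float)
    mobile = int((logd > logd_threshold).sum())
    immobile = len(logd) - mobile
    if immobile == 0:
        warnings.warn("all tracks mobile; M/IMM reported as +inf")
        ratio = math.inf
    else:
        ratio = mobile / immobile
    with np.errstate(invalid="ignore"):
        mean_msd = np.where(msd_cnt > 0, msd_sum / np.maximum(msd_cnt, 1), np.nan)
    lags = np.arange(1, lag_range + 1) * ts.frame_time
    return MobilityMetrics(
        d_per_track=d_series, log10d=logd, bin_edges=np.asarray(bins),
        frequency=freq, mobile_fraction=mobile / len(logd),
        mobile_immobile_ratio=ratio, mean_msd=mean_msd, msd_lags=lags,
        mean_auc=float(np.mean(aucs)), logd_threshold=logd_threshold)
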