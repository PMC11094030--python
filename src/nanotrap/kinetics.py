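"""Recruitment kinetics from fluorescence traces and cumulative track counts.

Fluorescence-intensity (FI) traces of membrane regions (whole cell, or
high-/low-fluorescence areas) are reduced to time-to-peak, fold change
over baseline, and post-peak decay slope; the decay is compared against a
photobleaching control to decide whether the signal leaves the region
faster than bleaching alone explains.  Cumulative single-particle track
counts per µm² are blocked into 30 s chunks and differentiated to give an
appearance-rate time series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tracks import TrackSet

__all__ = [
    "IntensityTrace",
    "KineticsResult",
    "analyze_trace",
    "compare_decay_to_bleach",
    "cumulative_track_rate",
]


@dataclass
class IntensityTrace:
    """Mean FI (arbitrary units) over one ROI vs time."""

    times: np.ndarray
    fi: np.ndarray
    stim_time: float
    roi_id: str = ""
    roi_kind: str = "whole-cell"   # whole-cell | HFA | LFA | bleach-control

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fi = np.asarray(self.fi, dtype=float)
        if len(self.times) != len(self.fi):
            raise ValueError("times and fi must have equal length")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if not np.isfinite(self.fi).all():
            raise ValueError("FI values must be finite")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "fi": self.fi,
                             "roi_kind": self.roi_kind})


@dataclass
class KineticsResult:
    time_to_peak: float       # s, from stim_time
    fold_change: float        # smoothed peak / baseline
    decay_slope: float        # FI/s over the post-peak window
    baseline: float           # mean pre-stimulation FI
    peak_time: float          # absolute time of the (smoothed) peak
    unresolved_peak: bool     # trace never declines after the peak


def _smooth(fi: np.ndarray, k: int) -> np.ndarray:
    if k <= 1:
        return fi.astype(float)
    return (pd.Series(fi).rolling(k, center=True, min_periods=1)
            .mean().to_numpy())


def analyze_trace(
    trace: IntensityTrace,
    smoothing_window: float = 5.0,
    baseline_window: float = 30.0,
    decay_window: float = 100.0,
) -> KineticsResult:
    """Baseline, time-to-peak, fold change and decay slope of one trace.

    The baseline is the mean raw FI over ``baseline_window`` seconds
    before stimulation; the peak is the argmax of a centered
    moving-average smoothed trace (window ``smoothing_window`` s) after
    stimulation; the decay slope is an ordinary least-squares slope of
    raw FI over ``decay_window`` seconds after the peak.  The peak is
    flagged unresolved when the smoothed trace never drops below it
    afterwards (e.g. a plateau running into the end of the acquisition).
    """
    t, fi = trace.times, trace.fi
    if not (t[0] <= trace.stim_time <= t[-1]):
        raise ValueError("stim_time outside the trace")
    post = t >= trace.stim_time
    if post.sum() < 10:
        raise ValueError("need >= 10 samples after stimulation")
    pre = (t < trace.stim_time) & (t >= trace.stim_time - baseline_window)
    if not pre.any():
        raise ValueError("no pre-stimulation samples for the baseline")
    baseline = float(fi[pre].mean())
    k = max(1, int(round(smoothing_window / trace.dt)))
    smoothed = _smooth(fi, k)
    post_idx = np.flatnonzero(post)
    peak_local = int(np.argmax(smoothed[post_idx]))
    peak_idx = int(post_idx[peak_local])
    peak_val = float(smoothed[peak_idx])
    peak_time = float(t[peak_idx])
    after = smoothed[peak_idx + 1:]
    span = max(peak_val - baseline, abs(peak_val) * 1e-9, 1e-300)
    unresolved = bool(len(after) == 0 or after.min() > peak_val - 0.01 * span)
    fold = peak_val / baseline if baseline != 0 else math.inf
    dwin = (t >= peak_time) & (t <= peak_time + decay_window)
    if dwin.sum() >= 2:
        slope = float(np.polyfit(t[dwin], fi[dwin], 1)[0])
    else:
        slope = math.nan
    return KineticsResult(
        time_to_peak=peak_time - trace.stim_time, fold_change=fold,
        decay_slope=slope, baseline=baseline, peak_time=peak_time,
        unresolved_peak=unresolved)


def compare_decay_to_bleach(
    trace: IntensityTrace,
    bleach_trace: IntensityTrace,
    window: tuple[float, float],
    log_scale: bool = True,
) -> dict:
    """Compare the post-peak decay slope against a photobleaching control.

    Fits straight lines to both traces over the common time ``window``
    (on log-FI by default, giving decay constants for exponential
    bleaching; raw-linear mode when ``log_scale`` is off or any FI is
    non-positive).  The verdict is positive when the signal trace decays
    strictly faster (more negative slope) than bleaching alone.
    """
    t0, t1 = window
    for tr in (trace, bleach_trace):
        if t0 < tr.times[0] or t1 > tr.times[-1]:
            raise ValueError("window not covered by both traces")
    out = {}
    for name, tr in (("trace", trace), ("bleach", bleach_trace)):
        m = (tr.times >= t0) & (tr.times <= t1)
        y = tr.fi[m]
        use_log = log_scale and (y > 0).all()
        yy = np.log(y) if use_log else y
        res = stats.linregress(tr.times[m], yy)
        out[f"{name}_slope"] = float(res.slope)
        out[f"{name}_log_scale"] = use_log
    out["excess_decay"] = bool(out["trace_slope"] < out["bleach_slope"])
    return out


def cumulative_track_rate(
    ts: TrackSet,
    block: float = 30.0,
) -> pd.DataFrame:
    """Appearance-rate time series from blocked cumulative track counts.

    Counts trajectory first-appearances per µm² of ROI, accumulates them,
    samples the cumulative curve at ``block``-second edges (30 s chunks
    avoid under-sampling) and differentiates with a central-difference
    gradient.  Returns a table of block time, cumulative count and rate
    (tracks µm⁻² s⁻¹).
    """
    if block <= 0:
        raise ValueError("block must be positive")
    duration = ts.duration or 0.0
    if duration < 2 * block:
        raise ValueError("acquisition shorter than two blocks")
    first = ts.data.groupby("traj")["t"].min().to_numpy()
    first.sort()
    edges = np.arange(0.0, duration + 0.5 * block, block)
    cum = np.searchsorted(first, edges, side="right") / ts.roi_area
    rate = np.gradient(cum, edges)
    return pd.DataFrame({"time": edges, "cumulative": cum, "rate": rate})
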