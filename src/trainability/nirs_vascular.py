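"""Microvascular responsiveness from a vascular occlusion test.

A cuff occludes the lower leg for 5 min while near-infrared
spectroscopy records tissue oxygen saturation (StO₂, %).  Three metrics
summarize the trace:

* baseline StO₂ — mean over the final 2 min before occlusion;
* reperfusion rate ("slope 2") — least-squares slope over the first
  10 s after cuff release, %·s⁻¹;
* reperfusion AUC — trapezoid area of the StO₂ signal *above baseline*
  over the first 4 min after release, %·s.  Sub-baseline excursions
  contribute zero (clamped), not negative area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "NirsTrace",
    "NirsMetrics",
    "baseline_sto2",
    "reperfusion_slope",
    "sto2_auc",
    "nirs_metrics",
]

BASELINE_WINDOW_S = 120.0
SLOPE_WINDOW_S = 10.0
AUC_WINDOW_S = 240.0


@dataclass(frozen=True)
class NirsTrace:
    """StO₂ time series with the two occlusion-protocol events (s)."""

    time: np.ndarray
    sto2: np.ndarray  # %, in [0, 100]
    occlusion_start: float
    cuff_release: float

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.sto2, dtype=float)
        if t.size != s.size or t.size < 2:
            raise ValueError("time and sto2 must be equal length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any((s < 0) | (s > 100)):
            raise ValueError("sto2 must lie in [0, 100] %")
        if not self.occlusion_start < self.cuff_release:
            raise ValueError("occlusion_start must precede cuff_release")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "sto2", s)


@dataclass(frozen=True)
class NirsMetrics:
    baseline_sto2: float  # %
    slope2: float  # %·s⁻¹
    auc: float  # %·s, above-baseline reperfusion area

    def __post_init__(self) -> None:
        if self.auc < 0:
            raise ValueError("auc cannot be negative")


def baseline_sto2(trace: NirsTrace) -> float:
    """Mean StO₂ over [occlusion_start − 120 s, occlusion_start)."""
    t0 = trace.occlusion_start - BASELINE_WINDOW_S
    if trace.time[0] > t0 + 1e-9:
        raise ValueError("need >= 120 s of pre-occlusion data")
    mask = (trace.time >= t0) & (trace.time < trace.occlusion_start)
    return float(trace.sto2[mask].mean())


def reperfusion_slope(trace: NirsTrace) -> float:
    """Least-squares StO₂ slope over the first 10 s after cuff release.

    The window is [release, release + 10); if no sample falls exactly at
    the release time, the first sample at or after it starts the window.
    """
    if trace.time[-1] < trace.cuff_release + SLOPE_WINDOW_S - 1e-9:
        raise ValueError("need >= 10 s of post-release data")
    mask = (trace.time >= trace.cuff_release) & (
        trace.time < trace.cuff_release + SLOPE_WINDOW_S
    )
    if mask.sum() < 2:
        raise ValueError("fewer than two samples in the 10-s reperfusion window")
    fit = stats.linregress(trace.time[mask], trace.sto2[mask])
    return float(fit.slope)


def _clamped_trapz(t: np.ndarray, y: np.ndarray) -> float:
    """∫ max(y, 0) dt for the piecewise-linear curve through (t, y).

    Handles sign changes inside a segment analytically, so the result is
    exact for piecewise-linear traces regardless of sampling rate.
    """
    area = 0.0
    for k in range(t.size - 1):
        dt = t[k + 1] - t[k]
        y0, y1 = y[k], y[k + 1]
        if y0 >= 0 and y1 >= 0:
            area += 0.5 * (y0 + y1) * dt
        elif y0 <= 0 and y1 <= 0:
            continue
        else:
            # one crossing inside the segment
            tc = dt * y0 / (y0 - y1)
            if y0 > 0:
                area += 0.5 * y0 * tc
            else:
                area += 0.5 * y1 * (dt - tc)
    return float(area)


def sto2_auc(trace: NirsTrace, baseline: float) -> float:
    """Above-baseline trapezoid area over the first 4 min of reperfusion.

    Values at exactly the release time and at release + 240 s are
    obtained by linear interpolation so the integration window is
    independent of where samples happen to fall.
    """
    t_end = trace.cuff_release + AUC_WINDOW_S
    if trace.time[-1] < t_end - 1e-9:
        raise ValueError("need >= 240 s of post-release data")
    inner = (trace.time > trace.cuff_release) & (trace.time < t_end)
    t = np.concatenate([[trace.cuff_release], trace.time[inner], [t_end]])
    y = np.interp(t, trace.time, trace.sto2) - baseline
    return _clamped_trapz(t, y)


def nirs_metrics(trace: NirsTrace) -> NirsMetrics:
    """All three occlusion-test metrics of one trace."""
    base = baseline_sto2(trace)
    return NirsMetrics(
        baseline_sto2=base,
        slope2=reperfusion_slope(trace),
        auc=sto2_auc(trace, base),
    )
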