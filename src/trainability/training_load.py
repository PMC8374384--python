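"""Per-session training-load quantification.

Power side: total work (Σ power·dt), kcal (total work / 4.184), both
absolute and relative to body mass, and the session mean power as a
percentage of the test's peak power — with "adjusted" variants computed
over the high-intensity interval windows only.

Heart-rate side: the session HR stream is edited like the breath data
(local-SD outlier removal, 1-s interpolation) and averaged into 5-s
bins; from it come mean HR, %HR_max, %HRR, and the individualized
training impulse

    iTRIMP = Σ_bins dt(min) · r(t) · a·exp(b·r(t)),
    r(t) = (HR − HR_rest) / (HR_max − HR_rest) clamped to [0, 1],

where (a, b) is the subject's exponential blood-lactate vs HR-ratio
model fitted from the incremental test: La = a·exp(b·r).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .gas_exchange import UniformSeries, _local_outlier_mask, bin_average

__all__ = [
    "TrainingSession",
    "LactateHrModel",
    "SessionLoad",
    "session_power_metrics",
    "session_hr_metrics",
    "preprocess_hr",
    "fit_lactate_hr_model",
    "itrimp",
    "weekly_summary",
    "adherence_pct",
]

J_PER_KCAL_KJ = 4.184  # kJ per kcal


@dataclass(frozen=True)
class TrainingSession:
    """Second-by-second record of one training session."""

    time: np.ndarray  # s
    power: np.ndarray  # W
    hr: np.ndarray  # bpm
    cadence: np.ndarray | None = None  # rpm
    kind: str = "MICT"  # "HIIT" | "MICT"
    interval_windows: tuple[tuple[float, float], ...] = ()  # [start, end) s

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        p = np.asarray(self.power, dtype=float)
        h = np.asarray(self.hr, dtype=float)
        if not (t.size == p.size == h.size) or t.size < 2:
            raise ValueError("time, power, hr must share length >= 2")
        if not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        if np.any(p < 0):
            raise ValueError("power must be non-negative")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "hr", h)
        if self.cadence is not None:
            c = np.asarray(self.cadence, dtype=float)
            if c.size != t.size:
                raise ValueError("cadence length mismatch")
            object.__setattr__(self, "cadence", c)
        object.__setattr__(
            self, "interval_windows", tuple(map(tuple, self.interval_windows))
        )


@dataclass(frozen=True)
class LactateHrModel:
    """Exponential lactate vs heart-rate-ratio model La = a·exp(b·r)."""

    a: float  # mmol·L⁻¹
    b: float  # dimensionless

    @property
    def valid(self) -> bool:
        """A physiological model needs a > 0 and a rising exponent b > 0."""
        return self.a > 0 and self.b > 0


@dataclass
class SessionLoad:
    """Summary metrics of one training session."""

    kind: str = ""
    week: int | None = None
    mean_power: float | None = None  # W (time-weighted)
    pct_po_peak: float | None = None  # %
    pct_po_peak_adjusted: float | None = None  # %, interval windows only
    total_work: float | None = None  # kJ
    rel_total_work: float | None = None  # kJ·kg⁻¹
    total_kcal: float | None = None
    rel_kcal: float | None = None  # kcal·kg⁻¹
    mean_hr: float | None = None  # bpm
    pct_hr_max: float | None = None  # %
    pct_hr_max_adjusted: float | None = None  # %
    pct_hrr: float | None = None  # %
    itrimp: float | None = None  # A.U.
    hr_flagged: bool = False  # %HR_max above the 110% soft bound


def _sample_dt(time: np.ndarray) -> np.ndarray:
    """Per-sample durations; the last sample inherits the median spacing."""
    d = np.diff(time)
    return np.append(d, np.median(d))


def _window_mask(time: np.ndarray, windows) -> np.ndarray:
    mask = np.zeros(time.size, dtype=bool)
    for lo, hi in windows:
        mask |= (time >= lo) & (time < hi)
    return mask


def session_power_metrics(
    session: TrainingSession, body_mass: float, po_peak: float
) -> SessionLoad:
    """Power-derived load metrics of one session."""
    if body_mass <= 0 or po_peak <= 0:
        raise ValueError("body_mass and po_peak must be positive")
    dt = _sample_dt(session.time)
    total_j = float(np.sum(session.power * dt))
    duration = float(dt.sum())
    mean_power = total_j / duration
    total_kj = total_j / 1000.0
    total_kcal = total_kj / J_PER_KCAL_KJ
    load = SessionLoad(
        kind=session.kind,
        mean_power=mean_power,
        pct_po_peak=100.0 * mean_power / po_peak,
        total_work=total_kj,
        rel_total_work=total_kj / body_mass,
        total_kcal=total_kcal,
        rel_kcal=total_kcal / body_mass,
    )
    if session.interval_windows:
        m = _window_mask(session.time, session.interval_windows)
        if m.any():
            mp_int = float(np.sum(session.power[m] * dt[m]) / np.sum(dt[m]))
            load.pct_po_peak_adjusted = 100.0 * mp_int / po_peak
    return load


def preprocess_hr(
    session: TrainingSession,
    window: int = 30,
    sd_multiplier: float = 2.0,
    bin_s: int = 5,
) -> UniformSeries:
    """Clean, 1-s interpolate, and 5-s bin a session's HR stream.

    Identical editing to the breath data: local-SD outlier removal,
    second-by-second linear interpolation, then fixed-width bins.
    """
    hr = session.hr
    keep = ~_local_outlier_mask(hr, window, sd_multiplier) if hr.size >= window else np.ones(hr.size, bool)
    t, h = session.time[keep], hr[keep]
    grid = t[0] + np.arange(int(np.floor(t[-1] - t[0])) + 1, dtype=float)
    interp = UniformSeries(
        start_time=float(t[0]), step=1.0, channels={"hr": np.interp(grid, t, h)}
    )
    return bin_average(interp, bin_s)


def session_hr_metrics(
    session: TrainingSession,
    hr_max: float,
    hr_rest: float,
    model: LactateHrModel | None = None,
    bin_s: int = 5,
) -> SessionLoad:
    """Heart-rate-derived load metrics (mean HR, %HR_max, %HRR, iTRIMP)."""
    if not hr_max > hr_rest > 0:
        raise ValueError("require hr_max > hr_rest > 0")
    bins = preprocess_hr(session, bin_s=bin_s)
    hr = bins["hr"]
    mean_hr = float(hr.mean())
    pct_hr_max = 100.0 * mean_hr / hr_max
    load = SessionLoad(
        kind=session.kind,
        mean_hr=mean_hr,
        pct_hr_max=pct_hr_max,
        pct_hrr=100.0 * (mean_hr - hr_rest) / (hr_max - hr_rest),
        hr_flagged=pct_hr_max > 110.0,
    )
    if session.interval_windows:
        t = bins.times
        m = _window_mask(t, session.interval_windows)
        if m.any():
            load.pct_hr_max_adjusted = 100.0 * float(hr[m].mean()) / hr_max
    if model is not None:
        load.itrimp = itrimp(hr, hr_rest, hr_max, model, bin_s=bin_s)
    return load


def fit_lactate_hr_model(
    pairs: Sequence, hr_rest: float, hr_max: float
) -> LactateHrModel:
    """Fit La = a·exp(b·r) on stage-end (HR, lactate) pairs.

    Linearized as ln(La) = ln(a) + b·r with r = (HR − HR_rest)/HRR and
    solved by least squares.  Flat lactate gives b = 0, which the
    returned model flags as invalid.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (hr, lactate) pairs")
    if not hr_max > hr_rest > 0:
        raise ValueError("require hr_max > hr_rest > 0")
    hr, la = arr[:, 0], arr[:, 1]
    if np.any(la <= 0):
        raise ValueError("lactate must be strictly positive for the log fit")
    r = (hr - hr_rest) / (hr_max - hr_rest)
    coef = np.polynomial.polynomial.polyfit(r, np.log(la), 1)
    return LactateHrModel(a=float(np.exp(coef[0])), b=float(coef[1]))


def itrimp(
    hr_bins: np.ndarray,
    hr_rest: float,
    hr_max: float,
    model: LactateHrModel,
    bin_s: float = 5.0,
    mode: str = "per_bin",
) -> float:
    """Individualized training impulse over binned session HR (A.U.).

    ``mode="per_bin"`` (default) sums the weight over every bin;
    ``mode="session_mean"`` evaluates the weight once at the session
    mean HR ratio, times the total duration.
    """
    if hr_max <= hr_rest:
        raise ValueError("hr_max must exceed hr_rest")
    if not model.valid:
        raise ValueError("invalid lactate-HR model (need a > 0 and b > 0)")
    hr = np.asarray(hr_bins, dtype=float)
    r = np.clip((hr - hr_rest) / (hr_max - hr_rest), 0.0, 1.0)
    dt_min = bin_s / 60.0
    if mode == "session_mean":
        rm = float(r.mean())
        return float(hr.size * dt_min * rm * model.a * np.exp(model.b * rm))
    if mode != "per_bin":
        raise ValueError(f"unknown iTRIMP mode {mode!r}")
    return float(np.sum(dt_min * r * model.a * np.exp(model.b * r)))


def adherence_pct(n_completed: int, n_prescribed: int = 18) -> float:
    """Percentage of prescribed sessions completed.

    The intervention prescribes 18 sessions; completing at least 15
    (83.3%) is the minimum adherence for inclusion.
    """
    if n_prescribed <= 0:
        raise ValueError("n_prescribed must be positive")
    if not 0 <= n_completed <= n_prescribed:
        raise ValueError("n_completed must lie in [0, n_prescribed]")
    return 100.0 * n_completed / n_prescribed


# weekly aggregation: intensity percentages average; dose measures sum
_WEEK_MEAN = ["pct_hr_max", "pct_hr_max_adjusted", "pct_po_peak", "pct_po_peak_adjusted"]
_WEEK_SUM = ["itrimp", "rel_total_work"]


def weekly_summary(loads: pd.DataFrame, weeks: Sequence[int] | None = None) -> pd.DataFrame:
    """Aggregate per-session loads into per-week rows.

    %HR_max and %PO_peak columns (plain and adjusted) are within-week
    means; iTRIMP and relative total work are within-week sums.  Weeks
    requested via ``weeks`` but absent from ``loads`` appear as all-NaN
    rows (missing, not zero).
    """
    if "week" not in loads.columns:
        raise ValueError("loads must carry a 'week' column")
    agg = {c: "mean" for c in _WEEK_MEAN if c in loads.columns}
    agg.update({c: "sum" for c in _WEEK_SUM if c in loads.columns})
    out = loads.groupby("week").agg(agg)
    out["n_sessions"] = loads.groupby("week").size()
    if weeks is not None:
        out = out.reindex(list(weeks))
        out["n_sessions"] = out["n_sessions"].fillna(0).astype(int)
    return out
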