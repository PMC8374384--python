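"""Outcomes of the step-incremental cycling test.

Covers: the step protocol, linearized peak power, the two lactate
turning points (LTP1/LTP2) via continuous two-breakpoint segmented
regression, mapping powers to V̇O2 through the stage-end V̇O2–PO line,
the three efficiency slopes (OUES, ΔV̇O2/ΔPO, ΔHR/ΔV̇O2), and the two
training prescriptions (HIIT at 90% HR_max, MICT at 90% LTP1) derived
from the test.

The segmented regression is the continuous three-segment model

    La(P) = c0 + c1·P + c2·(P − b1)+ + c3·(P − b2)+ ,   b1 < b2,

fitted by exhaustive search over breakpoint pairs on a 1-W lattice with
ordinary least squares at each candidate.  LTP1 = b1 (first rise above
baseline), LTP2 = b2 (second abrupt increase).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

__all__ = [
    "StepProtocol",
    "LactateCurve",
    "ThresholdResult",
    "EfficiencySlopes",
    "Prescription",
    "NoBreakpointError",
    "po_peak",
    "fit_lactate_breakpoints",
    "map_po_to_vo2",
    "oues",
    "vo2_po_slope",
    "hr_vo2_slope",
    "prescribe_hiit",
    "prescribe_mict",
]


class NoBreakpointError(ValueError):
    """The lactate curve carries no detectable breakpoint (degenerate fit)."""


@dataclass(frozen=True)
class StepProtocol:
    """Step-incremental protocol: rest on the bike, then fixed-width
    power steps until task failure.

    Defaults are the study protocol: 2-min rest, 25-W steps every 3 min,
    starting at 50 W for males and 25 W for females.
    """

    start_power: float = 50.0  # W (50 male / 25 female)
    increment: float = 25.0  # W per stage
    stage_duration: float = 180.0  # s
    rest_duration: float = 120.0  # s, pre-exercise rest on the ergometer

    def __post_init__(self) -> None:
        if self.increment <= 0 or self.stage_duration <= 0:
            raise ValueError("increment and stage_duration must be positive")
        if self.rest_duration < 0:
            raise ValueError("rest_duration must be non-negative")

    @classmethod
    def for_sex(cls, sex: str, **kwargs) -> "StepProtocol":
        start = 25.0 if str(sex).upper().startswith("F") else 50.0
        return cls(start_power=start, **kwargs)

    def stage_power(self, stage: int) -> float:
        """Power of 1-based stage ``stage`` (W)."""
        return self.start_power + (stage - 1) * self.increment

    def stage_start(self, stage: int) -> float:
        return self.rest_duration + (stage - 1) * self.stage_duration

    def stage_end(self, stage: int) -> float:
        return self.rest_duration + stage * self.stage_duration


@dataclass(frozen=True)
class LactateCurve:
    """Per-stage blood lactate vs end-stage power, with a pre-exercise
    baseline point (conventionally at 0 W) first."""

    power: np.ndarray  # W, strictly increasing
    lactate: np.ndarray  # mmol·L⁻¹

    def __post_init__(self) -> None:
        p = np.asarray(self.power, dtype=float)
        y = np.asarray(self.lactate, dtype=float)
        if p.size != y.size:
            raise ValueError("power and lactate lengths differ")
        if p.size >= 2 and not np.all(np.diff(p) > 0):
            raise ValueError("powers must be strictly increasing")
        if np.any(y < 0):
            raise ValueError("lactate must be non-negative")
        object.__setattr__(self, "power", p)
        object.__setattr__(self, "lactate", y)

    def __len__(self) -> int:
        return int(self.power.size)


@dataclass(frozen=True)
class ThresholdResult:
    """Two-breakpoint segmented-regression fit of the lactate curve."""

    ltp1_po: float  # W, first breakpoint
    ltp2_po: float  # W, second breakpoint
    slopes: tuple[float, float, float]  # mmol·L⁻¹·W⁻¹ per segment
    intercepts: tuple[float, float, float]  # mmol·L⁻¹ per segment
    rss: float  # (mmol·L⁻¹)²
    ltp1_vo2: float | None = None  # ml·min⁻¹ via the V̇O2–PO line
    ltp2_vo2: float | None = None

    def predict(self, power) -> np.ndarray:
        """Fitted lactate at ``power`` (continuous at both breakpoints)."""
        p = np.asarray(power, dtype=float)
        seg = np.searchsorted([self.ltp1_po, self.ltp2_po], p, side="right")
        s = np.asarray(self.slopes)[seg]
        c = np.asarray(self.intercepts)[seg]
        return c + s * p

    def with_vo2(self, stage_pairs) -> "ThresholdResult":
        """Attach V̇O2 at both breakpoints from stage-end (power, V̇O2) pairs."""
        return replace(
            self,
            ltp1_vo2=map_po_to_vo2(stage_pairs, self.ltp1_po),
            ltp2_vo2=map_po_to_vo2(stage_pairs, self.ltp2_po),
        )


@dataclass(frozen=True)
class EfficiencySlopes:
    """Efficiency indices of one test.

    oues is in ml·min⁻¹ per log10(L·min⁻¹); vo2_po_slope in
    ml·min⁻¹·W⁻¹; hr_vo2_slope in bpm per L·min⁻¹.
    """

    oues: float
    oues_intercept: float
    vo2_po_slope: float
    vo2_po_intercept: float
    hr_vo2_slope: float
    hr_vo2_intercept: float


@dataclass(frozen=True)
class Prescription:
    """One training-session prescription.

    HIIT: 10-min warm-up at the power matching 70% HR_max, four 4-min
    intervals at the power matching 90% HR_max separated by three 4-min
    recoveries at 30 W, and a 5-min cool-down at 30 W (43 min total).
    MICT: 60 min continuous at 90% of the LTP1 power.
    """

    kind: str  # "HIIT" | "MICT"
    warmup_power: float | None = None  # W
    interval_power: float | None = None  # W
    recovery_power: float | None = None  # W
    cooldown_power: float | None = None  # W
    mict_power: float | None = None  # W
    warmup_s: float = 0.0
    interval_s: float = 0.0
    n_intervals: int = 0
    recovery_s: float = 0.0
    cooldown_s: float = 0.0
    mict_s: float = 0.0

    @property
    def total_duration_s(self) -> float:
        if self.kind == "HIIT":
            return (
                self.warmup_s
                + self.n_intervals * self.interval_s
                + (self.n_intervals - 1) * self.recovery_s
                + self.cooldown_s
            )
        return self.mict_s

    def power_profile(self, step_s: float = 1.0) -> np.ndarray:
        """Planned power at each ``step_s`` sample of the session."""
        if self.kind == "MICT":
            n = int(round(self.mict_s / step_s))
            return np.full(n, float(self.mict_power))
        parts = [(self.warmup_power, self.warmup_s)]
        for k in range(self.n_intervals):
            parts.append((self.interval_power, self.interval_s))
            if k < self.n_intervals - 1:
                parts.append((self.recovery_power, self.recovery_s))
        parts.append((self.cooldown_power, self.cooldown_s))
        segs = [np.full(int(round(d / step_s)), float(p)) for p, d in parts]
        return np.concatenate(segs)

    def interval_windows(self) -> list[tuple[float, float]]:
        """[start, end) times (s) of the high-intensity intervals."""
        if self.kind != "HIIT":
            return []
        wins = []
        t = self.warmup_s
        for k in range(self.n_intervals):
            wins.append((t, t + self.interval_s))
            t += self.interval_s
            if k < self.n_intervals - 1:
                t += self.recovery_s
        return wins


def po_peak(
    protocol: StepProtocol,
    exhaustion_time_in_stage: float,
    last_completed_stage_power: float,
) -> float:
    """Linearized peak power output.

    The end of every stage corresponds to that stage's nominal power, so
    power is taken to rise linearly within the final incomplete stage:

        PO_peak = P_last + increment × t_in_stage / stage_duration.
    """
    if exhaustion_time_in_stage < 0:
        raise ValueError("exhaustion time cannot be negative")
    if exhaustion_time_in_stage > protocol.stage_duration:
        raise ValueError("exhaustion time exceeds the stage duration")
    frac = exhaustion_time_in_stage / protocol.stage_duration
    return float(last_completed_stage_power + protocol.increment * frac)


def _hinge_design(p: np.ndarray, b1: float, b2: float) -> np.ndarray:
    return np.column_stack(
        [np.ones_like(p), p, np.maximum(p - b1, 0.0), np.maximum(p - b2, 0.0)]
    )


def fit_lactate_breakpoints(
    curve: LactateCurve,
    lattice_w: float = 1.0,
    min_gap: float | None = None,
) -> ThresholdResult:
    """Fit the continuous three-segment lactate model by exhaustive search.

    Candidate breakpoints lie on a ``lattice_w``-spaced lattice strictly
    between the second and the second-to-last data powers, with
    ``b2 − b1 >= min_gap`` (default: one stage increment, taken as the
    smallest spacing between successive exercise-stage powers).  Each
    candidate pair is solved by least squares on the hinge basis
    {1, P, (P−b1)+, (P−b2)+}, which enforces continuity at both knots.
    Ties in RSS resolve to the smallest b1, then the smallest b2.

    Raises
    ------
    NoBreakpointError
        If the curve is flat or an exact straight line (no breakpoint
        information).
    ValueError
        If fewer than 6 points are supplied.
    """
    if len(curve) < 6:
        raise ValueError("at least 6 lactate points required for two breakpoints")
    p, y = curve.power, curve.lactate
    if np.ptp(y) == 0:
        raise NoBreakpointError("all lactate values equal: no breakpoint")
    # An exact straight line cannot localize a breakpoint.
    line = np.polynomial.polynomial.polyfit(p, y, 1)
    rss_line = float(np.sum((y - np.polynomial.polynomial.polyval(p, line)) ** 2))
    if rss_line <= 1e-18 * max(1.0, float(np.sum(y**2))):
        raise NoBreakpointError("lactate curve is a straight line: no breakpoint")
    if min_gap is None:
        min_gap = float(np.min(np.diff(p[1:]))) if len(curve) >= 3 else lattice_w
    lo, hi = p[1], p[-2]
    grid = np.arange(lo + lattice_w, hi + 0.5 * lattice_w, lattice_w)
    if grid.size < 2:
        raise ValueError("power range too narrow for the breakpoint lattice")

    # Batched normal equations over all admissible (b1, b2) pairs.
    n = p.size
    R = np.maximum(p[None, :] - grid[:, None], 0.0)  # (K, n) hinge columns
    ones = np.ones(n)
    s0, s1, s2 = float(n), float(p.sum()), float((p * p).sum())
    u = R @ ones  # Σ r_k
    v = R @ p  # Σ p·r_k
    W = R @ R.T  # Σ r_i·r_j
    ty = float(y.sum())
    tpy = float(p @ y)
    tr = R @ y
    yty = float(y @ y)

    i_idx, j_idx = np.meshgrid(
        np.arange(grid.size), np.arange(grid.size), indexing="ij"
    )
    admissible = grid[j_idx] - grid[i_idx] >= min_gap - 1e-9
    ii, jj = i_idx[admissible], j_idx[admissible]
    m = ii.size
    if m == 0:
        raise ValueError("no admissible breakpoint pair under min_gap")

    XtX = np.empty((m, 4, 4))
    XtX[:, 0, 0] = s0
    XtX[:, 0, 1] = XtX[:, 1, 0] = s1
    XtX[:, 1, 1] = s2
    XtX[:, 0, 2] = XtX[:, 2, 0] = u[ii]
    XtX[:, 0, 3] = XtX[:, 3, 0] = u[jj]
    XtX[:, 1, 2] = XtX[:, 2, 1] = v[ii]
    XtX[:, 1, 3] = XtX[:, 3, 1] = v[jj]
    XtX[:, 2, 2] = W[ii, ii]
    XtX[:, 3, 3] = W[jj, jj]
    XtX[:, 2, 3] = XtX[:, 3, 2] = W[ii, jj]
    Xty = np.stack([np.full(m, ty), np.full(m, tpy), tr[ii], tr[jj]], axis=1)

    # pinv-based solve tolerates near-collinear hinge columns at the grid edges
    coef = np.linalg.pinv(XtX, rcond=1e-10) @ Xty[:, :, None]
    coef = coef[:, :, 0]
    rss = yty - 2 * np.einsum("mk,mk->m", coef, Xty) + np.einsum(
        "mk,mkl,ml->m", coef, XtX, coef
    )
    rss = np.maximum(rss, 0.0)

    # smallest RSS; ties -> smallest b1 then smallest b2 (ii-major order
    # of the admissible enumeration already sorts that way)
    order = np.lexsort((grid[jj], grid[ii], np.round(rss, 12)))
    best = order[0]
    b1, b2 = float(grid[ii[best]]), float(grid[jj[best]])
    c = np.linalg.lstsq(_hinge_design(p, b1, b2), y, rcond=None)[0]
    rss_best = float(np.sum((_hinge_design(p, b1, b2) @ c - y) ** 2))
    s_1 = float(c[1])
    s_2 = float(c[1] + c[2])
    s_3 = float(c[1] + c[2] + c[3])
    i_1 = float(c[0])
    i_2 = i_1 - float(c[2]) * b1
    i_3 = i_2 - float(c[3]) * b2
    return ThresholdResult(
        ltp1_po=b1,
        ltp2_po=b2,
        slopes=(s_1, s_2, s_3),
        intercepts=(i_1, i_2, i_3),
        rss=rss_best,
    )


def _pairs(stage_pairs) -> tuple[np.ndarray, np.ndarray]:
    arr = np.asarray(stage_pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least two (x, y) pairs")
    return arr[:, 0], arr[:, 1]


def map_po_to_vo2(stage_pairs: Sequence, po: float) -> float:
    """V̇O2 (ml·min⁻¹) at power ``po`` from the stage-end V̇O2–PO line."""
    power, vo2 = _pairs(stage_pairs)
    fit = stats.linregress(power, vo2)
    return float(fit.intercept + fit.slope * po)


def oues(vo2, ve) -> tuple[float, float]:
    """Oxygen uptake efficiency slope: V̇O2 = a·log10(V̇E) + b.

    Returns (a, b) with V̇O2 in ml·min⁻¹ and V̇E in L·min⁻¹.
    """
    vo2 = np.asarray(vo2, dtype=float)
    ve = np.asarray(ve, dtype=float)
    if vo2.size != ve.size or vo2.size < 2:
        raise ValueError("paired series of length >= 2 required")
    if np.any(ve <= 0):
        raise ValueError("ve must be strictly positive")
    x = np.log10(ve)
    if np.ptp(x) == 0:
        raise ValueError("constant ventilation: OUES undefined")
    fit = stats.linregress(x, vo2)
    return float(fit.slope), float(fit.intercept)


def vo2_po_slope(stage_pairs: Sequence) -> tuple[float, float]:
    """ΔV̇O2/ΔPO: least-squares slope (ml·min⁻¹·W⁻¹) of stage-end V̇O2
    vs stage power; returns (slope, intercept)."""
    power, vo2 = _pairs(stage_pairs)
    fit = stats.linregress(power, vo2)
    return float(fit.slope), float(fit.intercept)


def hr_vo2_slope(stage_pairs: Sequence) -> tuple[float, float]:
    """ΔHR/ΔV̇O2: least-squares slope (bpm per L·min⁻¹) of stage-end HR
    vs stage-end V̇O2 given in ml·min⁻¹; returns (slope, intercept)."""
    vo2_ml, hr = _pairs(stage_pairs)
    fit = stats.linregress(vo2_ml / 1000.0, hr)
    return float(fit.slope), float(fit.intercept)


def prescribe_hiit(hr_po_pairs: Sequence, hr_max: float) -> Prescription:
    """Derive the HIIT session from the stage-end HR–PO line.

    The power at a given %HR_max is found by inverting the least-squares
    fit HR = m·PO + c: PO = (target − c)/m, with the warm-up at 70% and
    the intervals at 90% of HR_max.  Recovery and cool-down are fixed at
    30 W.
    """
    power, hr = _pairs(hr_po_pairs)
    fit = stats.linregress(power, hr)
    if fit.slope <= 0:
        raise ValueError("non-positive HR-PO slope: cannot invert prescription")
    warm = (0.70 * hr_max - fit.intercept) / fit.slope
    work = (0.90 * hr_max - fit.intercept) / fit.slope
    return Prescription(
        kind="HIIT",
        warmup_power=float(warm),
        interval_power=float(work),
        recovery_power=30.0,
        cooldown_power=30.0,
        warmup_s=600.0,
        interval_s=240.0,
        n_intervals=4,
        recovery_s=240.0,
        cooldown_s=300.0,
    )


def prescribe_mict(ltp1_po: float) -> Prescription:
    """60 min of continuous cycling at 90% of the LTP1 power."""
    if ltp1_po <= 0:
        raise ValueError("ltp1_po must be positive")
    return Prescription(kind="MICT", mict_power=0.9 * ltp1_po, mict_s=3600.0)
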