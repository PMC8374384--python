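"""Breath-by-breath gas-exchange processing for incremental cycling tests.

The metabolic cart reports one record per breath at irregular intervals
(~2-3 s).  Before any physiological quantity is derived, the series is
edited in three steps that mirror standard CPET practice:

1. outlier breaths are removed when V̇O2 deviates from a local
   (centered, candidate-excluded) mean by more than a stated number of
   local standard deviations,
2. every channel is linearly interpolated onto a 1-s grid, and
3. the 1-s series is averaged into fixed-width bins (30 s for V̇O2max,
   5 s for training heart-rate data).

V̇O2max is the highest 30-s bin; attainment of a true maximum is
confirmed by a 2-of-3 criterion on maximal heart rate, respiratory
exchange ratio, and end-exercise blood lactate.

Units throughout: time s, V̇O2/V̇CO2 ml·min⁻¹, V̇E L·min⁻¹, HR bpm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "BreathSeries",
    "UniformSeries",
    "MaximalValues",
    "AttainmentReport",
    "clean_breaths",
    "interpolate_1s",
    "bin_average",
    "vo2max_from_bins",
    "rer_max_from_bins",
    "check_attainment",
    "stage_end_averages",
]


@dataclass(frozen=True)
class BreathSeries:
    """Raw or cleaned breath-by-breath records of one test.

    Parameters
    ----------
    time : array
        Seconds from test start (including the pre-exercise rest on the
        ergometer); strictly increasing.
    vo2, vco2 : array
        Oxygen uptake and CO2 output, ml·min⁻¹; strictly positive.
    ve : array
        Minute ventilation, L·min⁻¹; strictly positive.
    hr : array, optional
        Heart rate, bpm.  Optional because some carts export gas
        channels only.
    """

    time: np.ndarray
    vo2: np.ndarray
    vco2: np.ndarray
    ve: np.ndarray
    hr: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("time", "vo2", "vco2", "ve"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
            if arr.ndim != 1:
                raise ValueError(f"{name} must be one-dimensional")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {name}")
        n = self.time.size
        if any(getattr(self, c).size != n for c in ("vo2", "vco2", "ve")):
            raise ValueError("channel lengths differ")
        if n >= 2 and not np.all(np.diff(self.time) > 0):
            raise ValueError("time must be strictly increasing")
        for name in ("vo2", "vco2", "ve"):
            if np.any(getattr(self, name) <= 0):
                raise ValueError(f"{name} must be strictly positive")
        if self.hr is not None:
            hr = np.asarray(self.hr, dtype=float)
            if hr.size != n or not np.all(np.isfinite(hr)):
                raise ValueError("hr must match length and be finite")
            object.__setattr__(self, "hr", hr)

    def __len__(self) -> int:
        return int(self.time.size)

    def channels(self) -> dict[str, np.ndarray]:
        out = {"vo2": self.vo2, "vco2": self.vco2, "ve": self.ve}
        if self.hr is not None:
            out["hr"] = self.hr
        return out


@dataclass(frozen=True)
class UniformSeries:
    """Uniformly sampled multichannel series.

    ``step`` is 1 s for interpolated data and the bin width for binned
    data; sample ``k`` of a binned series summarises
    ``[start_time + k*step, start_time + (k+1)*step)``.
    """

    start_time: float
    step: float
    channels: Mapping[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        chans = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        if not chans:
            raise ValueError("at least one channel required")
        lengths = {v.size for v in chans.values()}
        if len(lengths) != 1 or lengths == {0}:
            raise ValueError("channels must share a common nonzero length")
        object.__setattr__(self, "channels", chans)

    def __len__(self) -> int:
        return int(next(iter(self.channels.values())).size)

    @property
    def times(self) -> np.ndarray:
        """Sample (or bin-start) times in seconds."""
        return self.start_time + self.step * np.arange(len(self))

    def __getitem__(self, key: str) -> np.ndarray:
        return self.channels[key]


@dataclass(frozen=True)
class MaximalValues:
    """Maximal outcomes of one incremental test."""

    vo2max: float  # ml·min⁻¹, highest 30-s average
    hr_max: float  # bpm, highest value throughout the test
    rer_max: float  # dimensionless
    po_peak: float  # W, linearized within the final incomplete stage
    la_max: float | None = None  # mmol·L⁻¹; None when not sampled

    def __post_init__(self) -> None:
        if self.vo2max <= 0 or self.rer_max <= 0:
            raise ValueError("vo2max and rer_max must be positive")
        if self.la_max is not None and self.la_max < 0:
            raise ValueError("la_max must be non-negative")


@dataclass(frozen=True)
class AttainmentReport:
    """2-of-3 V̇O2max attainment check."""

    hr_criterion: bool
    rer_criterion: bool
    lactate_criterion: bool

    @property
    def attained(self) -> bool:
        return (self.hr_criterion + self.rer_criterion + self.lactate_criterion) >= 2


def _local_outlier_mask(
    values: np.ndarray, window: int, sd_multiplier: float
) -> np.ndarray:
    """True where a sample deviates from its candidate-excluded local mean
    by more than ``sd_multiplier`` local (sample) standard deviations.

    The window is centered on the candidate and clipped at the series
    edges, so edge samples are judged against a shorter one-sided window.
    Single pass: statistics are always computed on the input values.
    """
    n = values.size
    half = window // 2
    mask = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        neigh = np.concatenate([values[lo:i], values[i + 1 : hi]])
        if neigh.size < 2:
            continue
        mu = neigh.mean()
        sd = neigh.std(ddof=1)
        # sd == 0 gives a zero threshold: any deviation from perfectly
        # consistent neighbours is an outlier.  A non-finite threshold
        # (infinite multiplier) never flags.
        with np.errstate(invalid="ignore"):  # inf * 0 at zero local SD
            threshold = sd_multiplier * sd
        if np.isfinite(threshold) and abs(values[i] - mu) > threshold:
            mask[i] = True
    return mask


def clean_breaths(
    raw: BreathSeries, window_breaths: int = 30, sd_multiplier: float = 2.0
) -> BreathSeries:
    """Remove outlier breaths by the local-SD editing rule.

    A breath is discarded when its V̇O2 deviates from the mean of the
    surrounding ``window_breaths`` breaths (candidate excluded) by more
    than ``sd_multiplier`` local standard deviations.  All channels of a
    flagged breath are dropped together; survivors keep their order.

    Raises
    ------
    ValueError
        If the series has fewer records than ``window_breaths`` or the
        window is below 3 breaths.
    """
    if window_breaths < 3:
        raise ValueError("window_breaths must be at least 3")
    if len(raw) < window_breaths:
        raise ValueError(
            f"series has {len(raw)} breaths, fewer than window_breaths={window_breaths}"
        )
    drop = _local_outlier_mask(raw.vo2, window_breaths, sd_multiplier)
    keep = ~drop
    return BreathSeries(
        time=raw.time[keep],
        vo2=raw.vo2[keep],
        vco2=raw.vco2[keep],
        ve=raw.ve[keep],
        hr=None if raw.hr is None else raw.hr[keep],
    )


def interpolate_1s(series: BreathSeries) -> UniformSeries:
    """Linearly interpolate every channel onto a 1-s grid.

    The grid is anchored at the first breath time and extends in whole
    seconds up to the last breath time; both endpoints are sample points
    when they fall on the grid (the first always does).
    """
    if len(series) < 2:
        raise ValueError("at least two breaths required for interpolation")
    t0, t1 = series.time[0], series.time[-1]
    grid = t0 + np.arange(int(np.floor(t1 - t0)) + 1, dtype=float)
    chans = {
        name: np.interp(grid, series.time, vals)
        for name, vals in series.channels().items()
    }
    return UniformSeries(start_time=float(t0), step=1.0, channels=chans)


def bin_average(series: UniformSeries, bin_s: int) -> UniformSeries:
    """Average a 1-s series into consecutive non-overlapping bins.

    A trailing partial bin is kept and averaged over its available
    samples: the exhaustion-adjacent data it holds is precisely what
    defines V̇O2max, so it must not be discarded.
    """
    if bin_s < 1:
        raise ValueError("bin_s must be >= 1 s")
    if abs(series.step - 1.0) > 1e-9:
        raise ValueError("bin_average expects a 1-s interpolated series")
    n = len(series)
    if n == 0:
        raise ValueError("empty series")
    edges = np.arange(0, n, bin_s)
    counts = np.diff(np.append(edges, n)).astype(float)
    chans = {
        name: np.add.reduceat(vals, edges) / counts
        for name, vals in series.channels.items()
    }
    return UniformSeries(start_time=series.start_time, step=float(bin_s), channels=chans)


def vo2max_from_bins(series: UniformSeries) -> float:
    """Highest binned V̇O2 average (ml·min⁻¹)."""
    return float(np.max(series["vo2"]))


def rer_max_from_bins(series: UniformSeries) -> float:
    """Highest per-bin respiratory exchange ratio V̇CO2/V̇O2."""
    return float(np.max(series["vco2"] / series["vo2"]))


def check_attainment(
    max_vals: MaximalValues, age: float, symmetric_hr: bool = False
) -> AttainmentReport:
    """Apply the 2-of-3 V̇O2max attainment criteria.

    Criteria: (i) HR_max within 10 bpm of the age-predicted maximum
    (220 − age) — by default read one-sided, ``hr_max >= predicted − 10``,
    since exceeding the prediction cannot indicate a submaximal effort;
    set ``symmetric_hr=True`` for the literal |·| ≤ 10 reading;
    (ii) RER_max > 1.10; (iii) end-exercise lactate ≥ 8 mmol·L⁻¹.
    A missing lactate sample fails criterion (iii) without raising.
    """
    if age <= 0:
        raise ValueError("age must be positive")
    predicted = 220.0 - age
    if symmetric_hr:
        hr_ok = abs(max_vals.hr_max - predicted) <= 10.0
    else:
        hr_ok = max_vals.hr_max >= predicted - 10.0
    rer_ok = max_vals.rer_max > 1.10
    la_ok = max_vals.la_max is not None and max_vals.la_max >= 8.0
    return AttainmentReport(bool(hr_ok), bool(rer_ok), bool(la_ok))


def stage_end_averages(
    series: UniformSeries, protocol, window_s: float = 30.0
) -> pd.DataFrame:
    """Mean of each channel over the final ``window_s`` of every completed stage.

    Using only the last 30 s of a 3-min stage sidesteps the V̇O2 mean
    response time: by then uptake has essentially reached the stage's
    steady state, so the stage-end mean can be paired with the stage
    power for the V̇O2–PO, HR–PO and HR–V̇O2 regressions.

    The window is the half-open interval ``[stage_end − window_s,
    stage_end)`` in 0-based seconds.  Stages are counted as completed
    when their end time lies within the series span.

    Parameters
    ----------
    series : UniformSeries
        1-s interpolated test data (time 0 = test start, including the
        pre-exercise rest the protocol defines).
    protocol : StepProtocol
        Supplies stage boundaries and powers.

    Returns
    -------
    DataFrame with columns ``stage``, ``power_w`` and one column per
    channel; one row per completed stage.
    """
    if protocol.stage_duration < window_s:
        raise ValueError("stage shorter than the averaging window")
    t = series.times
    t_end = t[-1] + series.step
    rows = []
    stage = 1
    while protocol.stage_end(stage) <= t_end + 1e-9:
        end = protocol.stage_end(stage)
        mask = (t >= end - window_s) & (t < end)
        if not mask.any():
            raise ValueError(f"no samples in the final {window_s} s of stage {stage}")
        row = {"stage": stage, "power_w": protocol.stage_power(stage)}
        for name, vals in series.channels.items():
            row[name] = float(vals[mask].mean())
        rows.append(row)
        stage += 1
    return pd.DataFrame(rows)
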