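"""Synthetic physiological data with known ground truth.

Every input the pipeline consumes can be generated here: breath-by-breath
gas exchange of a step-incremental test, the per-stage lactate curve,
a StO₂ occlusion/reperfusion trace, HIIT/MICT training sessions, and a
PRE/POST cohort table mixing true responders and non-responders under a
stated measurement coefficient of variation.  All generators are
deterministic given their seed.

The generating models are deliberately simple enough to carry closed
forms (so every downstream estimator can be tested against the truth it
should recover) while matching the magnitudes of a sedentary adult
cohort: baseline V̇O2max ≈ 2.3 ± 0.4 L·min⁻¹, V̇O2–PO slope
9.5 ml·min⁻¹·W⁻¹, breath noise SD 80 ml·min⁻¹ with 1% spike outliers,
a 5.6% test-retest CV on V̇O2max, and a +400 ml·min⁻¹ true training
effect for responders vs 0 for non-responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gas_exchange import BreathSeries
from .incremental_test import LactateCurve, Prescription, StepProtocol
from .nirs_vascular import NirsTrace
from .training_load import TrainingSession

__all__ = [
    "SubjectProfile",
    "CohortSpec",
    "default_profile",
    "gen_profile",
    "exhaustion_from_po_peak",
    "gen_breath_series",
    "gen_lactate_curve",
    "gen_nirs_trace",
    "gen_training_session",
    "gen_cohort",
]


@dataclass(frozen=True)
class SubjectProfile:
    """Ground-truth physiological parameters of one synthetic subject."""

    subject_id: str = "S01"
    sex: str = "M"
    age: float = 30.0  # yr
    mass: float = 70.0  # kg
    height: float = 1.75  # m
    vo2max_true: float = 2280.0  # ml·min⁻¹ at baseline
    effect_true: float = 0.0  # ml·min⁻¹ true training effect
    hr_rest: float = 60.0  # bpm
    hr_max: float = 190.0  # bpm
    po_peak_w: float = 192.6  # W at exhaustion (linearized)
    ltp1_w: float = 100.0  # W, first lactate turning point
    ltp2_w: float = 150.0  # W, second lactate turning point
    vo2_po_slope: float = 9.5  # ml·min⁻¹·W⁻¹
    vo2_po_intercept: float = 450.0  # ml·min⁻¹ (unloaded cycling)
    oues_slope: float = 2100.0  # ml·min⁻¹ per log10(L·min⁻¹)
    oues_intercept: float = -1800.0  # ml·min⁻¹
    hr_po_intercept: float = 90.0  # bpm at 0 W riding
    hr_po_slope: float = 0.52  # bpm·W⁻¹
    baseline_la: float = 1.0  # mmol·L⁻¹
    la_slope_mid: float = 0.02  # mmol·L⁻¹·W⁻¹ between LTP1 and LTP2
    la_slope_high: float = 0.15  # mmol·L⁻¹·W⁻¹ above LTP2
    la_hr_a: float = 0.8  # lactate-HR model La = a·exp(b·r)
    la_hr_b: float = 2.4
    nirs_baseline: float = 70.0  # % StO₂
    nirs_floor: float = 40.0  # % StO₂ at end of occlusion
    nirs_slope2: float = 1.5  # %·s⁻¹ reperfusion rate
    nirs_overshoot: float = 10.0  # % peak above baseline
    nirs_auc: float = 800.0  # %·s above-baseline reperfusion area

    def __post_init__(self) -> None:
        if not 0 < self.ltp1_w < self.ltp2_w < self.po_peak_w:
            raise ValueError("require 0 < LTP1 < LTP2 < PO_peak")
        if self.hr_max <= self.hr_rest:
            raise ValueError("hr_max must exceed hr_rest")
        for name in ("vo2max_true", "mass", "nirs_slope2", "nirs_auc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def protocol(self) -> StepProtocol:
        return StepProtocol.for_sex(self.sex)

    def vo2_at(self, power) -> np.ndarray:
        """Steady-state V̇O2 (ml·min⁻¹) of the linear generator line."""
        return self.vo2_po_intercept + self.vo2_po_slope * np.asarray(power, float)

    def hr_at(self, power) -> np.ndarray:
        """Steady-state HR of the linear HR–PO generator line."""
        return self.hr_po_intercept + self.hr_po_slope * np.asarray(power, float)

    def ve_at(self, vo2) -> np.ndarray:
        """V̇E (L·min⁻¹) from the log-linear V̇E–V̇O2 coupling (exact
        inverse of the OUES relation V̇O2 = a·log10(V̇E) + b)."""
        return 10.0 ** ((np.asarray(vo2, float) - self.oues_intercept) / self.oues_slope)

    def lactate_at(self, power) -> np.ndarray:
        """Three-segment piecewise-linear lactate curve, continuous at
        the true LTP1/LTP2."""
        p = np.asarray(power, dtype=float)
        la = np.full_like(p, self.baseline_la)
        la += self.la_slope_mid * np.maximum(p - self.ltp1_w, 0.0)
        la += (self.la_slope_high - self.la_slope_mid) * np.maximum(p - self.ltp2_w, 0.0)
        return la


@dataclass(frozen=True)
class CohortSpec:
    """Conditions of the simulated training cohort.

    Defaults mirror the study cohort: n = 42 with 31 true responders
    (+400 ml·min⁻¹ true effect) and 11 true non-responders (no effect),
    baseline V̇O2max ~ Normal(2280, 400) ml·min⁻¹, and a 5.6%
    measurement CV applied independently to the PRE and POST tests.
    """

    n: int = 42
    responder_fraction: float = 31 / 42
    responder_effect: tuple[float, float] = (400.0, 0.0)  # (mean, SD) ml·min⁻¹
    non_responder_effect: tuple[float, float] = (0.0, 0.0)
    cv: float = 0.056
    baseline_mean: float = 2280.0  # ml·min⁻¹
    baseline_sd: float = 400.0
    female_fraction: float = 30 / 42
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.responder_fraction <= 1:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.cv <= 0:
            raise ValueError("cv must be positive")
        if self.n < 1:
            raise ValueError("n must be at least 1")


def default_profile(**overrides) -> SubjectProfile:
    """A deterministic typical subject (handy for examples and tests)."""
    return SubjectProfile(**overrides)


def _snap_to_stage(power: float, protocol: StepProtocol) -> float:
    """Nearest exercise-stage power (at least the second stage)."""
    k = round((power - protocol.start_power) / protocol.increment)
    return protocol.start_power + max(1, k) * protocol.increment


def gen_profile(
    subject_id: str,
    sex: str,
    age: float,
    vo2max_true: float,
    effect_true: float = 0.0,
    seed: int = 0,
) -> SubjectProfile:
    """Draw plausible correlated per-subject parameters.

    PO_peak follows from the subject's V̇O2max through the generator's
    V̇O2–PO line.  True LTP1/LTP2 are placed near 55% and 75% of
    PO_peak and snapped to the protocol's stage-power lattice: with
    lactate sampled only at stage ends, breakpoints are identifiable
    only at sampled powers, so the truth is defined there.  Placement
    additionally keeps at least one sampled stage strictly between the
    turning points and at least two lactate samples above LTP2 —
    otherwise the two-knot curve is not uniquely determined by its
    stage samples even without noise.
    """
    rng = np.random.default_rng(seed)
    protocol = StepProtocol.for_sex(sex)
    slope, icpt = 9.5, 450.0
    po_peak = (vo2max_true - icpt) / slope
    q = (po_peak - protocol.start_power) / protocol.increment
    last_completed = protocol.start_power + protocol.increment * int(np.floor(q))
    inc = protocol.increment
    extra_pt = 1 if q - np.floor(q) > 0 else 0  # end-exercise lactate sample
    ltp2_max = last_completed - inc * max(0, 2 - extra_pt)
    ltp1_min = protocol.start_power + inc
    ltp1 = max(_snap_to_stage(0.55 * po_peak, protocol), ltp1_min)
    ltp2 = min(_snap_to_stage(0.75 * po_peak, protocol), ltp2_max)
    if ltp2 - ltp1 < 2 * inc:
        ltp1 = ltp2 - 2 * inc
    if ltp1 < ltp1_min:
        raise ValueError(
            f"V̇O2max {vo2max_true:.0f} ml/min yields too few stages for "
            "identifiable lactate turning points under this protocol"
        )
    height = rng.normal(1.67 if sex.upper().startswith("F") else 1.79, 0.06)
    mass = rng.normal(23.5, 2.2) * height**2
    hr_max = 220.0 - age - rng.uniform(0.0, 8.0)
    hr_rest = rng.uniform(55.0, 70.0)
    hr_icpt = hr_rest + 30.0
    slope2 = rng.normal(1.5, 0.25)
    base_sto2 = rng.normal(70.0, 3.0)
    floor = rng.normal(40.0, 3.0)
    overshoot = rng.normal(10.0, 1.5)
    # keep the reperfusion overshoot resolvable inside the 4-min AUC window
    t_used = (base_sto2 - floor) / slope2 + overshoot / slope2
    auc_max = overshoot**2 / (2 * slope2) + 0.5 * overshoot * (240.0 - t_used)
    auc = min(rng.normal(800.0, 120.0), 0.85 * auc_max)
    return SubjectProfile(
        subject_id=subject_id,
        sex=sex,
        age=age,
        mass=float(mass),
        height=float(height),
        vo2max_true=float(vo2max_true),
        effect_true=float(effect_true),
        hr_rest=float(hr_rest),
        hr_max=float(hr_max),
        po_peak_w=float(po_peak),
        ltp1_w=float(ltp1),
        ltp2_w=float(ltp2),
        hr_po_intercept=float(hr_icpt),
        hr_po_slope=float((hr_max - hr_icpt) / po_peak),
        la_hr_a=float(rng.normal(0.8, 0.1)),
        la_hr_b=float(rng.normal(2.4, 0.2)),
        nirs_baseline=float(base_sto2),
        nirs_floor=float(floor),
        nirs_slope2=float(slope2),
        nirs_overshoot=float(overshoot),
        nirs_auc=float(max(auc, 100.0)),
    )


def exhaustion_from_po_peak(
    profile: SubjectProfile, protocol: StepProtocol | None = None
) -> tuple[int, float, float]:
    """Invert the PO_peak linearization.

    Returns (number of completed stages, seconds into the final
    incomplete stage, total test time including the pre-exercise rest).
    """
    protocol = protocol or profile.protocol
    q = (profile.po_peak_w - protocol.start_power) / protocol.increment
    n_completed = int(np.floor(q)) + 1
    frac = q - np.floor(q)
    t_total = protocol.rest_duration + n_completed * protocol.stage_duration
    t_in_stage = frac * protocol.stage_duration
    return n_completed, float(t_in_stage), float(t_total + t_in_stage)


def _piecewise_exp_response(
    t: np.ndarray,
    seg_starts: np.ndarray,
    seg_targets: np.ndarray,
    y0: float,
    tau: float,
) -> np.ndarray:
    """First-order (mono-exponential) tracking of a piecewise-constant
    target; tau = 0 gives instantaneous steps."""
    if tau <= 0:
        idx = np.searchsorted(seg_starts, t, side="right") - 1
        return seg_targets[np.clip(idx, 0, None)]
    y_start = np.empty(seg_starts.size)
    y = y0
    for k in range(seg_starts.size):
        y_start[k] = y
        seg_end = seg_starts[k + 1] if k + 1 < seg_starts.size else np.inf
        dt = seg_end - seg_starts[k]
        y = seg_targets[k] + (y - seg_targets[k]) * np.exp(-dt / tau)
    idx = np.clip(np.searchsorted(seg_starts, t, side="right") - 1, 0, None)
    dt = t - seg_starts[idx]
    return seg_targets[idx] + (y_start[idx] - seg_targets[idx]) * np.exp(-dt / tau)


def gen_breath_series(
    profile: SubjectProfile,
    protocol: StepProtocol | None = None,
    seed: int = 0,
    noise_sd: float = 80.0,
    spike_rate: float = 0.01,
    spike_amp_sds: float = 4.0,
    breath_interval: float = 2.5,
    jitter_s: float = 0.3,
    tau_s: float = 30.0,
) -> BreathSeries:
    """Breath-by-breath gas exchange of one incremental test.

    Per-stage steady states come from the linear V̇O2–PO and HR–PO
    generator lines; transitions at stage starts are mono-exponential
    (τ = 30 s).  V̇E couples log-linearly to the noise-free V̇O2 so the
    OUES relation holds exactly before noise.  Breath V̇O2 gets additive
    Gaussian noise (SD 80 ml·min⁻¹ by default, the magnitude of real
    breath-to-breath scatter) plus rare spike outliers of ±4 noise SDs
    at a 1% rate; timestamps fall every ~2.5 s with uniform jitter.
    """
    protocol = protocol or profile.protocol
    rng = np.random.default_rng(seed)
    n_completed, t_in_stage, t_total = exhaustion_from_po_peak(profile, protocol)

    # breath timestamps
    n_breaths = int(t_total / breath_interval) + 8
    gaps = breath_interval + rng.uniform(-jitter_s, jitter_s, size=n_breaths)
    times = np.cumsum(gaps)
    times = times[times < t_total]

    # piecewise-constant targets: rest, completed stages, final partial stage
    n_segments = n_completed + (2 if t_in_stage > 0 else 1)
    seg_starts = np.array(
        [0.0]
        + [protocol.stage_start(k) for k in range(1, n_segments)]
    )
    powers = np.array(
        [0.0] + [protocol.stage_power(k) for k in range(1, n_segments)]
    )
    # V̇O2 and HR plateau at the subject's true maxima: the final
    # (incomplete) stage's nominal steady state may exceed them
    vo2_targets = np.minimum(profile.vo2_at(powers), profile.vo2max_true)
    hr_targets = np.minimum(profile.hr_at(powers), profile.hr_max)
    vo2_t = _piecewise_exp_response(
        times, seg_starts, vo2_targets, profile.vo2_at(0.0), tau_s
    )
    hr_t = _piecewise_exp_response(
        times, seg_starts, hr_targets, profile.hr_at(0.0), tau_s
    )
    ve_t = profile.ve_at(vo2_t)

    # RER drifts from ~0.85 at rest above 1.10 near exhaustion
    exercise_frac = np.clip(
        (times - protocol.rest_duration) / max(t_total - protocol.rest_duration, 1.0),
        0.0,
        1.0,
    )
    rer_t = 0.85 + 0.45 * exercise_frac**1.5

    vo2 = vo2_t + rng.normal(0.0, noise_sd, times.size)
    spikes = rng.random(times.size) < spike_rate
    vo2 = vo2 + spikes * rng.choice([-1.0, 1.0], times.size) * spike_amp_sds * noise_sd
    vo2 = np.maximum(vo2, 50.0)
    rel_noise = 0.0 if noise_sd == 0 else 0.02
    vco2 = np.maximum(rer_t * vo2_t * (1 + rng.normal(0, rel_noise, times.size)), 50.0)
    ve = np.maximum(ve_t * (1 + rng.normal(0, rel_noise, times.size)), 1.0)
    hr = np.clip(hr_t + rng.normal(0, 25 * rel_noise, times.size), 40.0, None)
    return BreathSeries(time=times, vo2=vo2, vco2=vco2, ve=ve, hr=hr)


def gen_lactate_curve(
    profile: SubjectProfile,
    protocol: StepProtocol | None = None,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> LactateCurve:
    """Per-stage lactate curve of one test.

    Points: a pre-exercise baseline at 0 W, one per completed stage at
    the stage power, and an end-exercise point at PO_peak.  Values lie
    on the profile's continuous three-segment curve plus Gaussian noise
    (truncated at 0.3 mmol·L⁻¹ to stay physiological).
    """
    protocol = protocol or profile.protocol
    rng = np.random.default_rng(seed)
    n_completed, t_in_stage, _ = exhaustion_from_po_peak(profile, protocol)
    powers = [0.0] + [protocol.stage_power(k) for k in range(1, n_completed + 1)]
    if t_in_stage > 0:
        powers.append(profile.po_peak_w)
    powers = np.asarray(powers)
    la = profile.lactate_at(powers) + rng.normal(0.0, noise_sd, powers.size)
    return LactateCurve(power=powers, lactate=np.maximum(la, 0.3))


def nirs_truth_segments(
    profile: SubjectProfile, pre_s: float = 180.0, occ_s: float = 300.0
) -> dict[str, float]:
    """Closed-form timing of the noise-free StO₂ trace (times in s from
    recording start)."""
    release = pre_s + occ_s
    s2, h = profile.nirs_slope2, profile.nirs_overshoot
    rise_area = h**2 / (2 * s2)
    decay_area = profile.nirs_auc - rise_area
    if decay_area <= 0:
        raise ValueError("nirs_auc too small for the stated overshoot and slope")
    decay_rate = h**2 / (2 * decay_area)
    t_cross = release + (profile.nirs_baseline - profile.nirs_floor) / s2
    t_peak = t_cross + h / s2
    t_back = t_peak + h / decay_rate
    if t_back > release + 240.0:
        raise ValueError("reperfusion overshoot does not resolve inside the AUC window")
    return {
        "release": release,
        "t_cross": t_cross,
        "t_peak": t_peak,
        "t_back": t_back,
        "decay_rate": decay_rate,
    }


def gen_nirs_trace(
    profile: SubjectProfile,
    seed: int = 0,
    fs_hz: float = 10.0,
    noise_sd: float = 0.0,
    pre_s: float = 180.0,
    occ_s: float = 300.0,
    post_s: float = 480.0,
) -> NirsTrace:
    """StO₂ trace of the 5-min occlusion / 8-min reperfusion protocol.

    Baseline plateau, linear desaturation to a floor during occlusion,
    then a piecewise-linear reperfusion: a rise at exactly the profile's
    true slope-2 rate to a peak ``overshoot`` above baseline, and a
    linear return to baseline whose rate is set so the above-baseline
    area equals the profile's true AUC.  The linear segments give exact
    closed forms for every metric the analysis extracts.
    """
    seg = nirs_truth_segments(profile, pre_s, occ_s)
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, pre_s + occ_s + post_s, 1.0 / fs_hz)
    b, fl = profile.nirs_baseline, profile.nirs_floor
    knots_t = [
        0.0,
        pre_s,
        seg["release"],
        seg["t_peak"],
        seg["t_back"],
        pre_s + occ_s + post_s,
    ]
    knots_y = [b, b, fl, b + profile.nirs_overshoot, b, b]
    sto2 = np.interp(t, knots_t, knots_y)
    if noise_sd > 0:
        sto2 = sto2 + rng.normal(0.0, noise_sd, t.size)
    sto2 = np.clip(sto2, 0.0, 100.0)
    return NirsTrace(
        time=t, sto2=sto2, occlusion_start=pre_s, cuff_release=pre_s + occ_s
    )


def gen_training_session(
    prescription: Prescription,
    profile: SubjectProfile,
    seed: int = 0,
    hr_noise_sd: float = 2.0,
    drift_bpm_per_min: float = 0.08,
    tau_s: float = 35.0,
    cadence_mean: float = 85.0,
) -> TrainingSession:
    """One training session sampled at 1 Hz.

    Power follows the prescription exactly; cadence jitters around a
    constant; heart rate is a first-order response to the HR–PO line's
    steady state plus a slow cardiovascular drift and Gaussian noise,
    capped at the subject's HR_max.
    """
    rng = np.random.default_rng(seed)
    power = prescription.power_profile(1.0)
    t = np.arange(power.size, dtype=float)
    target = profile.hr_at(power) + drift_bpm_per_min * t / 60.0
    hr = np.empty_like(target)
    y = profile.hr_at(0.0)
    for k in range(t.size):  # first-order tracking, dt = 1 s
        y += (target[k] - y) / tau_s
        hr[k] = y
    hr = np.clip(hr + rng.normal(0.0, hr_noise_sd, t.size), 40.0, profile.hr_max)
    cadence = np.clip(cadence_mean + rng.normal(0.0, 3.0, t.size), 30.0, None)
    return TrainingSession(
        time=t,
        power=power,
        hr=hr,
        cadence=cadence,
        kind=prescription.kind,
        interval_windows=tuple(prescription.interval_windows()),
    )


def gen_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the PRE/POST V̇O2max cohort table plus its hidden truth.

    True baselines ~ Normal(baseline_mean, baseline_sd); each subject is
    a responder with probability ``responder_fraction`` and receives a
    class-specific true effect.  Observed values apply the measurement
    CV multiplicatively and independently to each test:
    PRE = truth·(1+ε₁), POST = (truth+effect)·(1+ε₂), ε ~ N(0, cv).

    Returns (cohort, truth); the cohort table carries only what a real
    study would observe.
    """
    rng = np.random.default_rng(spec.seed)
    ids = [f"S{k + 1:02d}" for k in range(spec.n)]
    sex = np.where(rng.random(spec.n) < spec.female_fraction, "F", "M")
    age = rng.uniform(20.0, 40.0, spec.n)
    is_resp = rng.random(spec.n) < spec.responder_fraction
    # Baselines are drawn conditionally on sex (males higher, as in any
    # adult cohort) with moments chosen so the sex mixture reproduces
    # the stated overall Normal(baseline_mean, baseline_sd); the floors
    # keep every subject's incremental test long enough for
    # identifiable lactate turning points (see gen_profile).
    shift = spec.baseline_mean - 2280.0
    scale = spec.baseline_sd / 400.0
    f_mean, m_mean = shift + 2280.0 - 130.0 * scale, shift + 2280.0 + 320.0 * scale
    within_sd = 350.0 * scale
    is_f = sex == "F"
    baseline_true = np.where(
        is_f,
        np.maximum(rng.normal(f_mean, within_sd, spec.n), 1700.0),
        np.maximum(rng.normal(m_mean, within_sd, spec.n), 2000.0),
    )
    eff_mean = np.where(is_resp, spec.responder_effect[0], spec.non_responder_effect[0])
    eff_sd = np.where(is_resp, spec.responder_effect[1], spec.non_responder_effect[1])
    effect = rng.normal(eff_mean, eff_sd)
    pre = baseline_true * (1.0 + rng.normal(0.0, spec.cv, spec.n))
    post = (baseline_true + effect) * (1.0 + rng.normal(0.0, spec.cv, spec.n))
    cohort = pd.DataFrame(
        {
            "subject_id": ids,
            "sex": sex,
            "age": np.round(age, 1),
            "baseline_vo2max_ml_min": pre,
            "post_vo2max_ml_min": post,
        }
    )
    truth = pd.DataFrame(
        {
            "subject_id": ids,
            "true_baseline": baseline_true,
            "true_effect": effect,
            "true_class": np.where(is_resp, "responder", "non-responder"),
        }
    )
    return cohort, truth
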