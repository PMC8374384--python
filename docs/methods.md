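# Methods

`trainability` re-implements, as a tested pipeline, the analysis chain used to
decide whether an individual *responded* to a short aerobic-training
intervention: processing of the step-incremental cardiopulmonary exercise test
(CPET), lactate-threshold detection, efficiency slopes, near-infrared
spectroscopy (NIRS) occlusion metrics, per-session training load, and the
Bayesian ROPE+HDI classification of each participant's ΔV̇O2max. A synthetic
data module generates every input with known ground truth so that each stage
can be validated end-to-end without access to raw laboratory data.

## Breath-by-breath editing

Metabolic carts report one record per breath at irregular ~2–3 s intervals
with heavy-tailed scatter. Editing proceeds in three steps:

1. **Outlier removal.** A breath is discarded when its V̇O2 deviates from the
   mean of the surrounding window (default 30 breaths, centered, candidate
   excluded) by more than `sd_multiplier` (default 2) local standard
   deviations. Statistics are always computed on the raw input (single pass).
   A zero local SD flags any deviating breath; an infinite multiplier flags
   none. The 2-SD convention follows common CPET practice; the window size is
   exposed in configuration because no standard exists.
2. **Interpolation** of all channels onto a 1-s grid anchored at the first
   breath (linear).
3. **Bin averaging** into fixed 30-s bins for V̇O2max (5-s bins for training
   heart rate). A trailing partial bin is averaged over its available samples
   rather than dropped — the exhaustion-adjacent data it holds is precisely
   what defines V̇O2max.

A limitation worth knowing: a fixed-multiplier SD rule is *not* idempotent on
broadband Gaussian scatter. Each pass truncates the local distribution,
shrinks the local SD and re-flags ~5% of the survivors, so repeated cleaning
would keep eroding the series. The pipeline therefore applies exactly one
pass; idempotence holds only once remaining scatter sits below the threshold
(e.g. isolated spikes on smooth data), and the test suite checks it there.

V̇O2max is the highest 30-s bin. Attainment uses the 2-of-3 criterion: HR_max
within 10 bpm of 220 − age, RER > 1.10, end-exercise lactate ≥ 8 mmol·L⁻¹.
"Within 10 bpm" is read one-sided (`hr_max ≥ predicted − 10`) by default,
since exceeding the prediction cannot indicate a submaximal effort; the
literal symmetric reading is available via `symmetric_hr`.

Stage-end summaries average the final 30 s of each completed stage over the
half-open window `[stage_end − 30 s, stage_end)` in 0-based seconds. By the
end of a 3-min stage, first-order V̇O2 kinetics (τ ≈ 30 s) have decayed to
< 0.5% of the step amplitude, which is why stage-end means can be paired with
stage powers in the linear regressions below.

## Incremental-test outcomes

* **Peak power** is linearized within the final incomplete stage:
  `PO_peak = P_last + increment · t_in_stage / stage_duration` (25-W steps
  every 3 min; start 50 W for males, 25 W for females; 2-min rest first).
* **Lactate turning points.** The blood-lactate vs power curve is fitted with
  a continuous three-segment model on the hinge basis
  `{1, P, (P−b1)+, (P−b2)+}`, which enforces continuity at both knots by
  construction. Breakpoint pairs are searched exhaustively on a 1-W lattice
  strictly between the second and second-to-last sampled powers, with
  `b2 − b1` at least one stage increment; each candidate is solved by ordinary
  least squares (batched normal equations with a pseudo-inverse, so
  near-collinear hinge columns at the grid edges stay harmless). Ties in RSS
  (rounded at 1e-12) resolve to the smallest `b1`, then `b2` — this matters on
  noise-free curves, where every knot placement above the true one on an
  unsampled stretch fits exactly and the tie-break pins the answer at the
  sampled truth. LTP1 = b1, LTP2 = b2; their V̇O2 values come from the
  stage-end V̇O2–PO line. Degenerate inputs (flat or exactly linear curves)
  raise `NoBreakpointError` rather than returning an arbitrary knot.
* **Efficiency slopes.** OUES is the slope of V̇O2 (ml·min⁻¹) on log10 V̇E
  (L·min⁻¹), fitted on the 1-s interpolated exercise data; ΔV̇O2/ΔPO and
  ΔHR/ΔV̇O2 are least-squares slopes through the stage-end pairs (the latter
  in bpm per L·min⁻¹). All fits use `scipy.stats.linregress`.
* **Prescriptions.** HIIT: 10-min warm-up at the power matching 70% HR_max,
  four 4-min intervals at the power matching 90% HR_max, three 4-min
  recoveries at 30 W, 5-min cool-down at 30 W — 43 min in total. The power at
  a %HR_max target inverts the stage-end HR–PO line. MICT: 60 min at 90% of
  the LTP1 power.

## NIRS occlusion metrics

From an StO₂ trace with a 5-min cuff occlusion: baseline (mean of the final
2 min before occlusion), reperfusion rate "slope 2" (least-squares slope over
`[release, release + 10 s)`), and the above-baseline area over the first
4 min of reperfusion. The area integrates `max(StO₂ − baseline, 0)` with a
trapezoid rule that handles baseline crossings inside a sampling interval
analytically and interpolates the window edges, so the result is exact for
piecewise-linear traces at any sampling rate and sub-baseline excursions
contribute zero, not negative area. No smoothing is applied before the slope
fit; an optional moving average exists in configuration but is off by
default.

## Training load

Power side: total work Σ power·dt (kJ), kcal = kJ/4.184, both also relative
to body mass, and mean power as %PO_peak — with "adjusted" variants restricted
to the high-intensity interval windows. Heart-rate side: the session HR stream
is edited exactly like breath data and averaged into 5-s bins; outputs are
mean HR, %HR_max, %HR reserve, and the individualized training impulse

    iTRIMP = Σ_bins dt(min) · r · a·e^{b·r},   r = (HR − HR_rest)/(HR_max − HR_rest),

with `r` clamped to [0, 1] so transient artifacts cannot produce negative or
explosive weights. The subject's (a, b) come from a log-linear least-squares
fit of stage-end lactate on the HR ratio, `La = a·e^{b·r}` (the Manzi-type
exponential weighting); a flat lactate profile yields b = 0 and is flagged
invalid. Per-bin summation is the default; a single evaluation at the session
mean HR is available (`mode="session_mean"`). Weekly summaries average the
intensity percentages and sum iTRIMP and relative work; an empty week is
reported missing (NaN), never zero.

## Responder classification (ROPE + HDI)

All quantities in ml·min⁻¹. For each participant with baseline `B` and change
`Δ = POST − PRE`:

1. **Measurement error** `e = B · CV · m` with CV = 5.6% (published
   test-retest variation of V̇O2max) and multiplier `m = √2` by default: Δ is
   the difference of two tests that each carry the CV, so its technical error
   scales by √2. The source formula renders ambiguously, so `m ∈ {√2, 1, ½}`
   is selectable; the choice shifts every HDI width by the same factor and is
   reported in the output. `Δsd = e/2` (a quarter of the ±e range).
2. **Per-subject distribution** Normal(Δ, Δsd), handled analytically (a
   sampling mode exists for cross-checks; simulating ~100 draws would only
   add noise to a known normal).
3. **89% HDI** of that normal — by symmetry its central interval
   `Δ ± 1.598·Δsd` — and the **ROPE** `±20%` of the cohort's baseline V̇O2max
   SD (sample SD; a fixed half-width can be supplied instead).
4. **Decision.** The percentage of the HDI's probability mass inside the ROPE
   (intersection mass / HDI mass, matching the sample-based definition used
   by Bayesian reporting tools) maps to five levels: >99% non-responder,
   >97.5% probably non-responder, <1% responder, <2% probably responder,
   otherwise undecided — the decision table leaves [2%, 2.5%) unassigned and
   the rule ordering sends it, conservatively, to "undecided". Any negative
   observed Δ overrides to non-responder. For group statistics the five
   levels collapse to a binary label: {responder, probably responder} →
   responder, all else → non-responder.

## Synthetic data: what it emulates, and what it does not

Generators are deterministic given (parameters, seed) and write the same CSV
schemas the readers consume.

* **Breath series.** Per-stage steady states from a linear V̇O2–PO line
  (9.5 ml·min⁻¹·W⁻¹ slope, 450 ml·min⁻¹ intercept — textbook cycling
  economy), mono-exponential transitions (τ = 30 s), V̇E coupled log-linearly
  to V̇O2 so the OUES relation holds exactly before noise, HR linear in power
  with the same kinetics, RER drifting from 0.85 past 1.10 near exhaustion.
  Breaths fall every ~2.5 ± 0.3 s; V̇O2 noise SD 80 ml·min⁻¹ with 1% spike
  outliers at ±4 SD. V̇O2 and HR plateau at the subject's true maxima during
  the final incomplete stage.
* **Lactate curves.** Continuous three-segment rise (flat baseline
  1.0 mmol·L⁻¹, then 0.02, then 0.15 mmol·L⁻¹·W⁻¹) sampled at the baseline,
  each completed stage power, and exhaustion, with truncated Gaussian noise
  (SD 0.1 mmol·L⁻¹ by default). True turning points are snapped to the
  stage-power lattice and placed so at least one stage falls strictly between
  them and at least two lactate samples lie above LTP2: lactate observed only
  at stage ends cannot uniquely localize knots that violate these conditions,
  even noise-free, so the generator only claims truths the data can encode.
* **NIRS traces.** Baseline plateau, linear desaturation to a floor over the
  5-min occlusion, then a *piecewise-linear* reperfusion: a rise at exactly
  the true slope-2 rate to a fixed overshoot and a linear return whose rate
  makes the above-baseline area equal the stated truth. A sigmoidal
  reperfusion would look more organic, but the linear construction gives
  exact closed forms for every extracted metric, which is what makes 0.1%
  oracle tests possible. 10 Hz sampling.
* **Training sessions.** Power follows the prescription exactly; HR is a
  first-order response (τ = 35 s) to the subject's HR–PO line plus a slow
  drift (0.08 bpm·min⁻¹) and 2-bpm noise, capped at HR_max; cadence jitters
  around 85 rpm.
* **Cohort.** n = 42 with a 31/42 responder fraction; true effects
  +400 ml·min⁻¹ (responders) vs 0 (non-responders); observed PRE/POST apply a
  5.6% CV multiplicatively and independently per test. True baselines are
  drawn conditionally on sex — F ~ N(2150, 350), M ~ N(2600, 350) with floors
  1700/2000 ml·min⁻¹ — a mixture whose overall moments (≈2280 ± 405) match
  the target marginal while keeping every male's test long enough for
  identifiable turning points under the 50-W-start protocol.

What passing tests on these data do **not** show: real breath noise is
neither Gaussian nor independent, real lactate kinetics are smooth rather
than piecewise linear, real reperfusion is sigmoidal, and real training
effects are continuous rather than two-point mixtures. The generators
validate the *estimators*, not the biology.

### An honest note on classification accuracy

With a 5.6% CV applied independently to PRE and POST, the observed Δ of a
~2300 ml·min⁻¹ subject carries a noise SD of ≈ √2 · 0.056 · 2400 ≈ 190–200
ml·min⁻¹. Separating true effects of 0 vs 400 ml·min⁻¹ through that noise is
information-limited: the optimal threshold on observed Δ achieves ≈ Φ(200/197)
≈ 84.5% agreement with the truth, and the ROPE+HDI rule (which effectively
requires Δ ≳ 210 ml·min⁻¹ for "responder") lands at ≈ 84%. No decision rule
operating on the observed changes can do materially better under these noise
conditions; the corresponding acceptance test documents this ceiling. The
negative-Δ override, by contrast, is exact and holds in 100% of cases.

## Numerical choices

* Normal quantiles/CDF via `scipy.stats.norm`; ordinary least squares via
  `scipy.stats.linregress` / `numpy.linalg.lstsq`.
* Breakpoint search: RSS compared after rounding to 12 decimals so that
  floating-point dust among exactly tying candidates cannot scramble the
  deterministic (smallest b1, then b2) tie-break.
* `pct_hdi_in_rope` divides by the HDI's *actual* normal mass rather than the
  nominal 0.89, so the ratio is exact for any interval pair; results are
  clipped to [0, 100].
* CSV reading uses pandas `float_precision="round_trip"` so generated files
  re-read bit-identically; manifests record the config hash, seed and library
  versions needed to replay a run.

## Problem sizes used in checks

The shipped test suite and `scripts/acceptance.py` use 200 replicates for
noisy breakpoint/slope recovery, 10⁶ Monte-Carlo draws per grid point for the
ROPE+HDI oracle, 50–200 seeds for the breath-series pipeline, and 100 seeded
cohorts (n = 42) for classification — sizes at which the Monte-Carlo error of
each reported mean is well below the tolerance being asserted.
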