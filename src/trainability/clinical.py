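"""Small derived clinical quantities and effect-size summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EffectSummary",
    "homa_ir",
    "bmi",
    "cohen_d_independent",
    "cohen_d_paired",
    "percent_change",
]


@dataclass(frozen=True)
class EffectSummary:
    """Cohen's d with its 95% normal-approximation CI and group stats."""

    cohen_d: float
    ci_lo: float
    ci_hi: float
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int

    def __post_init__(self) -> None:
        if not self.ci_lo <= self.cohen_d <= self.ci_hi:
            raise ValueError("cohen_d must lie inside its CI")


def homa_ir(fasting_insulin: float, fasting_glucose: float) -> float:
    """HOMA-IR = fasting insulin (mU/L) × fasting glucose (mmol/L) / 22.5."""
    if fasting_insulin < 0:
        raise ValueError("insulin must be non-negative")
    if fasting_glucose <= 0:
        raise ValueError("glucose must be positive")
    return fasting_insulin * fasting_glucose / 22.5


def bmi(mass_kg: float, height_m: float) -> float:
    """Body mass index, kg·m⁻²."""
    if height_m <= 0:
        raise ValueError("height must be positive")
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    return mass_kg / height_m**2


def cohen_d_independent(group_a, group_b) -> EffectSummary:
    """Cohen's d between two independent groups (pooled SD, no Hedges
    correction), with the usual variance approximation for the 95% CI:
    var(d) ≈ (na+nb)/(na·nb) + d²/(2(na+nb))."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2")
    sa, sb = a.std(ddof=1), b.std(ddof=1)
    pooled = np.sqrt(((na - 1) * sa**2 + (nb - 1) * sb**2) / (na + nb - 2))
    if pooled == 0:
        d = 0.0
    else:
        d = float((a.mean() - b.mean()) / pooled)
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb)))
    return EffectSummary(
        cohen_d=d,
        ci_lo=float(d - 1.959963984540054 * se),
        ci_hi=float(d + 1.959963984540054 * se),
        mean_a=float(a.mean()),
        sd_a=float(sa),
        n_a=int(na),
        mean_b=float(b.mean()),
        sd_b=float(sb),
        n_b=int(nb),
    )


def cohen_d_paired(pre, post) -> EffectSummary:
    """Within-group (paired) d: mean change divided by the SD of the
    change scores.  Alternative to the pooled independent-groups form."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.size != post.size or pre.size < 2:
        raise ValueError("paired samples of equal length >= 2 required")
    change = post - pre
    sd = change.std(ddof=1)
    n = change.size
    d = 0.0 if sd == 0 else float(change.mean() / sd)
    se = np.sqrt(1.0 / n + d**2 / (2 * n))
    return EffectSummary(
        cohen_d=d,
        ci_lo=float(d - 1.959963984540054 * se),
        ci_hi=float(d + 1.959963984540054 * se),
        mean_a=float(post.mean()),
        sd_a=float(post.std(ddof=1)),
        n_a=int(n),
        mean_b=float(pre.mean()),
        sd_b=float(pre.std(ddof=1)),
        n_b=int(n),
    )


def percent_change(pre: float, post: float) -> float:
    """Percent change from baseline."""
    if pre == 0:
        raise ValueError("baseline value of zero")
    return 100.0 * (post - pre) / pre
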