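"""Sensitivity power analyses for the two study designs.

Both analyses solve the inverse power problem: given the design, alpha
and a target power, find the smallest standardized effect the design can
detect ("minimal detectable effect").

Mixed-design ANOVA (items as the unit)
--------------------------------------
Three groups of items (n per group), two repeated measures (current and
normative ratings) with correlation rho between them.  Power for the
within-subject main effect (the lockdown shift, the default) uses the
noncentral F with

    df1 = m − 1,  df2 = (N − k)(m − 1),
    lambda = f^2 * N * m / (1 − rho),

and for the group-by-measure interaction df1 = (k − 1)(m − 1) with the
same df2 and lambda.  The effect-size conventions for this family are
not unique; by default the minimal detectable standardized effect is
reported on the f scale together with its eta^2_p = f^2/(1 + f^2) —
the pairing under which the original report's companion values
(d = .12, eta^2_p = .014) are mutually consistent.  The classical
two-level mapping d = 2f is available via ``d_convention="2f"``.

Crossed random-effects design (stimuli within condition)
--------------------------------------------------------
p participants each rate all q stimuli; stimuli are split between two
conditions (q_c per condition).  With random intercepts for participants
and stimuli and variance partitioning coefficients (VPCs) v_P, v_S, v_E
(fractions of total variance), participant intercepts cancel from the
condition contrast and the operative test is the two-sample t on
stimulus means:

    SE(d) = sqrt(2 * (v_S + v_E / p) / q_c),   df = q − 2,

so power at effect d is the noncentral-t tail beyond the two-sided
critical value with noncentrality d / SE(d).  For a balanced design this
is exactly the mixed-model test of the condition effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

__all__ = ["MixedAnovaSpec", "CrossedLMMSpec", "PowerResult",
           "power_mixed_anova", "sensitivity_mixed_anova",
           "power_crossed_lmm", "sensitivity_crossed_lmm"]


@dataclass
class MixedAnovaSpec:
    groups: int = 3
    measures: int = 2
    n_per_group: int = 20
    rm_correlation: float = 0.80
    alpha: float = 0.05
    target_power: float = 0.80
    effect: str = "within"          # "within" | "interaction"

    def __post_init__(self):
        for p in (self.alpha, self.target_power):
            if not 0 < p < 1:
                raise ValueError("alpha and target_power must lie in (0, 1)")
        if not -1 < self.rm_correlation < 1:
            raise ValueError("rm_correlation must lie in (-1, 1)")

    @property
    def n_total(self) -> int:
        return self.groups * self.n_per_group


@dataclass
class CrossedLMMSpec:
    participants: int = 71
    stimuli: int = 60
    vpc_participant: float = 0.10
    vpc_stimulus: float = 0.15
    vpc_residual: float = 0.75
    stimuli_per_condition: int | None = None   # default: stimuli // 2
    alpha: float = 0.05
    target_power: float = 0.80

    def __post_init__(self):
        vpcs = (self.vpc_participant, self.vpc_stimulus, self.vpc_residual)
        if any(v < 0 for v in vpcs) or sum(vpcs) > 1 + 1e-9:
            raise ValueError("VPCs must be nonnegative with sum <= 1")
        for p in (self.alpha, self.target_power):
            if not 0 < p < 1:
                raise ValueError("alpha and target_power must lie in (0, 1)")

    @property
    def q_c(self) -> int:
        return self.stimuli_per_condition or self.stimuli // 2


@dataclass
class PowerResult:
    design: str
    minimal_d: float
    power: float
    alpha: float
    details: dict = field(default_factory=dict)


# --------------------------------------------------------- mixed-design ANOVA

def _mixed_anova_dfs(spec: MixedAnovaSpec):
    k, m, n_tot = spec.groups, spec.measures, spec.n_total
    df2 = (n_tot - k) * (m - 1)
    df1 = (m - 1) if spec.effect == "within" else (k - 1) * (m - 1)
    return df1, df2


def power_mixed_anova(f_effect: float, spec: MixedAnovaSpec) -> float:
    """Power of the noncentral-F test at ANOVA effect size f."""
    df1, df2 = _mixed_anova_dfs(spec)
    lam = (f_effect ** 2) * spec.n_total * spec.measures \
        / (1.0 - spec.rm_correlation)
    crit = stats.f.ppf(1.0 - spec.alpha, df1, df2)
    if lam == 0:
        return float(spec.alpha)
    return float(stats.ncf.sf(crit, df1, df2, lam))


def sensitivity_mixed_anova(spec: MixedAnovaSpec | None = None,
                            d_convention: str = "f",
                            bracket=(1e-6, 5.0)) -> PowerResult:
    """Smallest detectable standardized effect for the mixed ANOVA.

    ``d_convention="f"`` (default) reports the minimal f as the
    standardized effect; ``"2f"`` reports the classical two-level
    mapping d = 2f instead.  The companion eta^2_p is always returned.
    """
    spec = spec or MixedAnovaSpec()
    lo, hi = bracket
    g = lambda f: power_mixed_anova(f, spec) - spec.target_power
    for _ in range(8):
        if g(hi) > 0:
            break
        hi *= 2
    else:
        raise RuntimeError("could not bracket the target power")
    f_min = brentq(g, lo, hi, xtol=1e-8)
    d = f_min if d_convention == "f" else 2.0 * f_min
    df1, df2 = _mixed_anova_dfs(spec)
    return PowerResult(
        design="mixed_anova",
        minimal_d=float(d),
        power=power_mixed_anova(f_min, spec),
        alpha=spec.alpha,
        details=dict(f=float(f_min),
                     eta_sq_partial=f_min ** 2 / (1 + f_min ** 2),
                     df1=df1, df2=df2, effect=spec.effect,
                     d_convention=d_convention),
    )


# ------------------------------------------------- crossed stimuli-in-condition

def crossed_se(spec: CrossedLMMSpec) -> float:
    """SE of the standardized condition difference (total variance = 1)."""
    return float(np.sqrt(
        2.0 * (spec.vpc_stimulus + spec.vpc_residual / spec.participants)
        / spec.q_c))


def _nct_cdf(t, df, nc):
    """Noncentral-t CDF with a normal-approximation fallback where scipy
    underflows to NaN in the deep tails."""
    v = stats.nct.cdf(t, df, nc)
    if np.isnan(v):
        z = (t * (1 - 1 / (4 * df)) - nc) / np.sqrt(1 + t * t / (2 * df))
        return float(stats.norm.cdf(z))
    return float(v)


def power_crossed_lmm(d: float, spec: CrossedLMMSpec) -> float:
    """Power of the crossed-design condition test at effect size d."""
    df = 2 * (spec.q_c - 1)
    crit = stats.t.ppf(1.0 - spec.alpha / 2.0, df)
    nc = d / crossed_se(spec)
    if nc == 0:
        return float(spec.alpha)
    return float((1.0 - _nct_cdf(crit, df, nc)) + _nct_cdf(-crit, df, nc))


def sensitivity_crossed_lmm(spec: CrossedLMMSpec | None = None,
                            bracket=(1e-6, 3.0)) -> PowerResult:
    """Smallest detectable d for the stimuli-within-condition design."""
    spec = spec or CrossedLMMSpec()
    lo, hi = bracket
    g = lambda d: power_crossed_lmm(d, spec) - spec.target_power
    for _ in range(8):
        if g(hi) > 0:
            break
        hi *= 2
    else:
        raise RuntimeError("could not bracket the target power")
    d_min = brentq(g, lo, hi, xtol=1e-8)
    return PowerResult(
        design="crossed_lmm",
        minimal_d=float(d_min),
        power=power_crossed_lmm(d_min, spec),
        alpha=spec.alpha,
        details=dict(se=crossed_se(spec), df=2 * (spec.q_c - 1),
                     q_c=spec.q_c),
    )
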