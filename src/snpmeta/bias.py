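"""Small-study / publication-bias diagnostics: funnel data, Egger, Begg.

*Egger's test* regresses the standardized effect ``log_or_i / se_i`` on the
precision ``1 / se_i`` by ordinary least squares; under no small-study
effect the intercept is zero, and it is tested two-sidedly against a
Student t with k-2 df.

*Begg's test* (rank-correlation) Kendall-correlates the variance-stabilized
deviates ``(log_or_i - mu_fe) / sqrt(v_i - 1/sum(1/v_j))`` with the
sampling variances ``v_i``; the S statistic is compared to its null normal
approximation with tie correction and a continuity correction of one unit.
With all variances tied the ranking is degenerate and p = 1 by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .contrasts import Z_95, EffectEstimate
from .errors import InsufficientStudiesError
from .pooling import iv_fixed_pool


@dataclass(frozen=True)
class EggerResult:
    intercept: float
    intercept_se: float
    t: float
    p: float
    slope: float
    df: int


@dataclass(frozen=True)
class BeggResult:
    kendall_tau: float
    z: float
    p: float


@dataclass(frozen=True)
class FunnelData:
    """Per-study funnel coordinates plus pseudo-95% guide lines."""

    points: tuple[tuple[float, float], ...]  # (log OR, se)
    study_ids: tuple[str, ...]
    pooled_log_or: float
    guide_se: tuple[float, ...]
    guide_low: tuple[float, ...]
    guide_high: tuple[float, ...]


def egger_test(effects: Sequence[EffectEstimate]) -> EggerResult:
    """Egger's linear-regression test for funnel-plot asymmetry."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Egger's test needs at least three studies")
    log_or = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    y = log_or / se
    x = sm.add_constant(1.0 / se)
    fit = sm.OLS(y, x).fit()
    intercept = float(fit.params[0])
    intercept_se = float(fit.bse[0])
    df = k - 2
    # an (numerically) exact fit leaves a 0/0 t-ratio; by convention it
    # carries no evidence of asymmetry
    if fit.ssr <= 1e-10 * max(1.0, float(np.sum(y**2))):
        t, p = 0.0, 1.0
    else:
        t = intercept / intercept_se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return EggerResult(
        intercept=intercept,
        intercept_se=intercept_se,
        t=t,
        p=p,
        slope=float(fit.params[1]),
        df=df,
    )


def _kendall_s_and_var(u: np.ndarray, v: np.ndarray) -> tuple[int, float, int]:
    """Kendall S statistic, its tie-corrected null variance, and pair count."""
    n = len(u)
    s = 0
    for i in range(n):
        for j in range(i + 1, n):
            s += int(np.sign(u[i] - u[j]) * np.sign(v[i] - v[j]))

    def tie_counts(x: np.ndarray) -> np.ndarray:
        _, counts = np.unique(x, return_counts=True)
        return counts[counts > 1]

    t_u = tie_counts(u)
    t_v = tie_counts(v)
    var = (
        n * (n - 1) * (2 * n + 5)
        - sum(t * (t - 1) * (2 * t + 5) for t in t_u)
        - sum(t * (t - 1) * (2 * t + 5) for t in t_v)
    ) / 18.0
    if n > 2:
        var += (
            sum(t * (t - 1) * (t - 2) for t in t_u)
            * sum(t * (t - 1) * (t - 2) for t in t_v)
        ) / (9.0 * n * (n - 1) * (n - 2))
    var += (
        sum(t * (t - 1) for t in t_u) * sum(t * (t - 1) for t in t_v)
    ) / (2.0 * n * (n - 1))
    return s, var, n * (n - 1) // 2


def begg_test(effects: Sequence[EffectEstimate]) -> BeggResult:
    """Begg–Mazumdar rank-correlation test for small-study effects."""
    k = len(effects)
    if k < 3:
        raise InsufficientStudiesError("Begg's test needs at least three studies")
    log_or = np.array([e.log_or for e in effects], dtype=float)
    v = np.array([e.se**2 for e in effects], dtype=float)
    fixed = iv_fixed_pool(list(effects))
    pooled_var = fixed.se**2
    resid_var = v - pooled_var
    # the variance of a deviation from the pooled mean is v_i - var(pooled);
    # numerical guard for a study dominating the pool
    resid_var = np.maximum(resid_var, 1e-12)
    deviates = (log_or - fixed.log_or) / np.sqrt(resid_var)
    s, var_s, n_pairs = _kendall_s_and_var(deviates, v)
    # tau-b normalization
    denom_u = n_pairs - sum(
        t * (t - 1) // 2 for t in np.unique(deviates, return_counts=True)[1] if t > 1
    )
    denom_v = n_pairs - sum(
        t * (t - 1) // 2 for t in np.unique(v, return_counts=True)[1] if t > 1
    )
    if denom_u <= 0 or denom_v <= 0 or var_s <= 0:
        return BeggResult(kendall_tau=0.0, z=0.0, p=1.0)
    tau = s / math.sqrt(denom_u * denom_v)
    z = max(abs(s) - 1.0, 0.0) / math.sqrt(var_s)
    p = float(2.0 * stats.norm.sf(z))
    return BeggResult(kendall_tau=float(tau), z=float(z), p=min(p, 1.0))


def funnel_coordinates(effects: Sequence[EffectEstimate], n_guide: int = 50) -> FunnelData:
    """Funnel-plot data: (log OR, se) per study plus pseudo-95% limits.

    The guide lines fan out from the fixed-effects pooled log OR at
    ``mu +/- 1.96 * se`` over a grid of standard errors from 0 to the
    largest observed se.
    """
    if not effects:
        raise InsufficientStudiesError("funnel plot needs at least one study")
    if len(effects) == 1:
        mu = effects[0].log_or
    else:
        mu = iv_fixed_pool(list(effects)).log_or
    se_max = max(e.se for e in effects)
    guide_se = tuple(float(s) for s in np.linspace(0.0, se_max * 1.05, n_guide))
    return FunnelData(
        points=tuple((e.log_or, e.se) for e in effects),
        study_ids=tuple(e.study_id for e in effects),
        pooled_log_or=mu,
        guide_se=guide_se,
        guide_low=tuple(mu - Z_95 * s for s in guide_se),
        guide_high=tuple(mu + Z_95 * s for s in guide_se),
    )
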