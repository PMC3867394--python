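"""Fixed- and random-effects pooling of study odds ratios.

Three estimators of the pooled odds ratio are provided:

* **Mantel–Haenszel fixed effects** on the 2x2 tables themselves:
  ``OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i)``, with the
  Robins–Breslow–Greenland variance for its log.
* **Inverse-variance fixed effects** on per-study log ORs, weights
  ``w_i = 1/se_i^2``.
* **DerSimonian–Laird random effects**: between-study variance tau^2 by the
  moment estimator ``max(0, (Q - df) / (S1 - S2/S1))`` with
  ``S_r = sum(w_i^r)``, then inverse-variance pooling with weights
  ``1/(se_i^2 + tau^2)``.  When Q <= df the estimator collapses exactly to
  inverse-variance fixed effects.

Heterogeneity is Cochran's Q around the fixed-effects mean (chi-square with
k-1 df under homogeneity) together with I^2 = max(0, (Q - df)/Q).  The
conventional decision rule pools with fixed effects when the Q test's
p-value exceeds 0.10 and with random effects otherwise (ties go to random
effects); :func:`select_model` implements it.  The pooled log OR is tested
against zero with a standard-normal Z test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .contrasts import Z_95, ContrastTable, EffectEstimate
from .errors import HeterogeneityUndefinedError, PoolingError

#: Q-test p-value at or below which heterogeneity is declared significant.
HET_THRESHOLD = 0.10


class PoolMethod(str, Enum):
    MH_FIXED = "mh_fixed"
    IV_FIXED = "iv_fixed"
    DL_RANDOM = "dl_random"


@dataclass(frozen=True)
class HeterogeneityResult:
    q: float
    df: int
    p_het: float
    i2: float
    tau2: float


@dataclass(frozen=True)
class PoolResult:
    method: PoolMethod
    k: int
    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    het: HeterogeneityResult
    weights: tuple[float, ...]

    @property
    def significant(self) -> bool:
        """Pooled association significant at the conventional 0.05 level."""
        return self.p < 0.05


def _finish(method: PoolMethod, k: int, log_or: float, se: float,
            het: HeterogeneityResult, weights: np.ndarray) -> PoolResult:
    z = log_or / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return PoolResult(
        method=method,
        k=k,
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        z=z,
        p=p,
        het=het,
        weights=tuple(float(x) for x in w),
    )


def _effect_arrays(effects: Sequence[EffectEstimate]) -> tuple[np.ndarray, np.ndarray]:
    if not effects:
        raise PoolingError("cannot pool an empty list of effects")
    log_or = np.array([e.log_or for e in effects], dtype=float)
    se = np.array([e.se for e in effects], dtype=float)
    if np.any(se <= 0):
        raise PoolingError("every effect must have a positive standard error")
    return log_or, se


def _no_heterogeneity(k: int) -> HeterogeneityResult:
    return HeterogeneityResult(q=0.0, df=max(k - 1, 0), p_het=1.0, i2=0.0, tau2=0.0)


def cochran_q(effects: Sequence[EffectEstimate]) -> HeterogeneityResult:
    """Cochran's Q with inverse-variance weights around the IV-fixed mean.

    Also returns I^2 and the DerSimonian–Laird moment estimate of tau^2
    (both floored at zero).  Requires at least two studies.
    """
    log_or, se = _effect_arrays(effects)
    k = len(effects)
    if k < 2:
        raise HeterogeneityUndefinedError("Cochran's Q requires at least two studies")
    w = 1.0 / se**2
    mu = float(np.sum(w * log_or) / np.sum(w))
    q = float(np.sum(w * (log_or - mu) ** 2))
    df = k - 1
    p_het = float(stats.chi2.sf(q, df))
    i2 = 0.0 if q <= 0 else max(0.0, (q - df) / q)
    s1 = float(np.sum(w))
    s2 = float(np.sum(w**2))
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    return HeterogeneityResult(q=q, df=df, p_het=p_het, i2=i2, tau2=tau2)


def iv_fixed_pool(effects: Sequence[EffectEstimate]) -> PoolResult:
    """Inverse-variance fixed-effects pooling of log odds ratios."""
    log_or, se = _effect_arrays(effects)
    k = len(effects)
    w = 1.0 / se**2
    mu = float(np.sum(w * log_or) / np.sum(w))
    pooled_se = float(1.0 / math.sqrt(np.sum(w)))
    het = cochran_q(effects) if k >= 2 else _no_heterogeneity(k)
    return _finish(PoolMethod.IV_FIXED, k, mu, pooled_se, het, w)


def dl_random_pool(effects: Sequence[EffectEstimate]) -> PoolResult:
    """DerSimonian–Laird random-effects pooling of log odds ratios.

    With a single study, or whenever Q <= df, tau^2 = 0 and the result
    coincides with :func:`iv_fixed_pool`.
    """
    log_or, se = _effect_arrays(effects)
    k = len(effects)
    het = cochran_q(effects) if k >= 2 else _no_heterogeneity(k)
    w_star = 1.0 / (se**2 + het.tau2)
    mu = float(np.sum(w_star * log_or) / np.sum(w_star))
    pooled_se = float(1.0 / math.sqrt(np.sum(w_star)))
    return _finish(PoolMethod.DL_RANDOM, k, mu, pooled_se, het, w_star)


def mh_fixed_pool(tables: Sequence[ContrastTable],
                  effects: Sequence[EffectEstimate] | None = None) -> PoolResult:
    """Mantel–Haenszel fixed-effects pooled odds ratio over 2x2 tables.

    The standard error of the log pooled OR uses the
    Robins–Breslow–Greenland variance, valid in both sparse-data and
    large-stratum limits.  When ``effects`` (per-study log ORs) are supplied
    they are used for the heterogeneity summary; otherwise heterogeneity is
    computed from Woolf effects of the same tables if all cells are positive.
    """
    if not tables:
        raise PoolingError("cannot pool an empty list of tables")
    a = np.array([t.a for t in tables], dtype=float)
    b = np.array([t.b for t in tables], dtype=float)
    c = np.array([t.c for t in tables], dtype=float)
    d = np.array([t.d for t in tables], dtype=float)
    n = a + b + c + d
    r = a * d / n
    s = b * c / n
    sum_r, sum_s = float(np.sum(r)), float(np.sum(s))
    if sum_r <= 0 or sum_s <= 0:
        raise PoolingError("Mantel-Haenszel OR undefined: zero cross-product sum in every stratum")
    log_or = math.log(sum_r / sum_s)
    p_term = (a + d) / n
    q_term = (b + c) / n
    var = (
        float(np.sum(p_term * r)) / (2.0 * sum_r**2)
        + float(np.sum(p_term * s + q_term * r)) / (2.0 * sum_r * sum_s)
        + float(np.sum(q_term * s)) / (2.0 * sum_s**2)
    )
    pooled_se = math.sqrt(var)
    k = len(tables)
    if effects is None and k >= 2 and float(np.min(np.array([min(t.cells) for t in tables]))) > 0:
        from .contrasts import study_effect

        effects = [study_effect(t) for t in tables]
    het = cochran_q(effects) if effects is not None and k >= 2 else _no_heterogeneity(k)
    return _finish(PoolMethod.MH_FIXED, k, log_or, pooled_se, het, s)


def select_model(het: HeterogeneityResult, threshold: float = HET_THRESHOLD) -> PoolMethod:
    """Fixed effects when the Q test is reassuring, random effects otherwise.

    Returns :attr:`PoolMethod.MH_FIXED` when ``p_het`` strictly exceeds
    ``threshold`` (default 0.10) and :attr:`PoolMethod.DL_RANDOM` otherwise;
    a p-value exactly at the threshold selects random effects.
    """
    return PoolMethod.MH_FIXED if het.p_het > threshold else PoolMethod.DL_RANDOM


def pool(tables: Sequence[ContrastTable], effects: Sequence[EffectEstimate],
         method: PoolMethod) -> PoolResult:
    """Dispatch to the requested pooling estimator."""
    if method is PoolMethod.MH_FIXED:
        return mh_fixed_pool(tables, effects)
    if method is PoolMethod.IV_FIXED:
        return iv_fixed_pool(effects)
    if method is PoolMethod.DL_RANDOM:
        return dl_random_pool(effects)
    raise PoolingError(f"unknown pooling method {method!r}")  # pragma: no cover
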