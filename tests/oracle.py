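"""Brute-force reference implementations used only as test oracles.

These re-derive the per-study odds ratio and the three pooled estimators
directly from their defining formulas, with exact rational arithmetic where
the quantity is rational (cross-product ratios, Mantel-Haenszel point
estimate) and ``decimal``/plain loops elsewhere.  They share no code with
the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction
from typing import Sequence


def oracle_or(a, b, c, d) -> Fraction:
    """Exact cross-product odds ratio of one 2x2 table."""
    return (Fraction(a) * Fraction(d)) / (Fraction(b) * Fraction(c))


def oracle_woolf_se(a, b, c, d) -> float:
    return math.sqrt(sum(1.0 / x for x in (a, b, c, d)))


def oracle_mh_or(tables: Sequence[tuple]) -> Fraction:
    """Exact Mantel-Haenszel pooled OR: sum(ad/n) / sum(bc/n)."""
    num = Fraction(0)
    den = Fraction(0)
    for a, b, c, d in tables:
        n = Fraction(a) + b + c + d
        num += Fraction(a) * d / n
        den += Fraction(b) * c / n
    return num / den


def oracle_iv_pool(log_ors: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Inverse-variance fixed-effects pooled log OR and its SE, by plain loops."""
    wsum = 0.0
    wy = 0.0
    for y, s in zip(log_ors, ses):
        w = 1.0 / (s * s)
        wsum += w
        wy += w * y
    return wy / wsum, 1.0 / math.sqrt(wsum)


def oracle_q_tau2(log_ors: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """Cochran's Q and the DerSimonian-Laird tau^2, by plain loops."""
    if len(log_ors) < 2:
        return 0.0, 0.0
    mu, _ = oracle_iv_pool(log_ors, ses)
    q = 0.0
    s1 = 0.0
    s2 = 0.0
    for y, s in zip(log_ors, ses):
        w = 1.0 / (s * s)
        q += w * (y - mu) ** 2
        s1 += w
        s2 += w * w
    df = len(log_ors) - 1
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    return q, tau2


def oracle_dl_pool(log_ors: Sequence[float], ses: Sequence[float]) -> tuple[float, float]:
    """DerSimonian-Laird pooled log OR and SE, by plain loops."""
    _, tau2 = oracle_q_tau2(log_ors, ses)
    wsum = 0.0
    wy = 0.0
    for y, s in zip(log_ors, ses):
        w = 1.0 / (s * s + tau2)
        wsum += w
        wy += w * y
    return wy / wsum, 1.0 / math.sqrt(wsum)


def oracle_hwe_chi2(aa: int, ag: int, gg: int) -> float:
    """HWE Pearson chi-square by direct evaluation with Fractions for the
    expectations (converted to float only at the final division)."""
    n = aa + ag + gg
    p = Fraction(2 * aa + ag, 2 * n)
    q = 1 - p
    exp = (n * p * p, 2 * n * p * q, n * q * q)
    obs = (Fraction(aa), Fraction(ag), Fraction(gg))
    return float(sum((o - e) ** 2 / e for o, e in zip(obs, exp)))
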