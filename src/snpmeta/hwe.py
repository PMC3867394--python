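"""Pearson chi-square test for Hardy–Weinberg equilibrium.

Deviation from HWE in *controls* is the standard genotyping-quality check in
genetic association studies: under random mating the genotype frequencies
should be (p^2, 2pq, q^2) for allele frequencies p + q = 1.  The test
compares observed AA/AG/GG counts to those expectations with the allele
frequency estimated from the sample, leaving one degree of freedom
(3 classes - 1 constraint - 1 estimated parameter).  No continuity
correction is applied.  Studies out of equilibrium are flagged, not
excluded: the bundled analysis keeps them in all pools.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .errors import ValidationError
from .studies import GenotypeCounts

#: Significance threshold below which a control series is declared out of HWE.
HWE_ALPHA = 0.05


@dataclass(frozen=True)
class HWEResult:
    chi2: float
    df: int
    p: float
    in_hwe: bool
    expected: tuple[float, float, float]
    monomorphic: bool = False


def hwe_test(genotypes: GenotypeCounts, alpha: float = HWE_ALPHA) -> HWEResult:
    """Pearson goodness-of-fit test of HWE on one genotype-count triple.

    Returns chi-square on 1 df and its upper-tail p-value; ``in_hwe`` is
    ``p >= alpha``.  A monomorphic sample (all A or all G) fits HWE exactly
    and is returned with chi2 = 0, p = 1 and the ``monomorphic`` flag set.
    """
    n = genotypes.total
    if n <= 0:
        raise ValidationError("HWE test requires at least one genotyped individual")
    p_a = genotypes.allele_a / (2.0 * n)
    q_g = 1.0 - p_a
    expected = (n * p_a * p_a, 2.0 * n * p_a * q_g, n * q_g * q_g)
    if p_a == 0.0 or q_g == 0.0:
        return HWEResult(chi2=0.0, df=1, p=1.0, in_hwe=True, expected=expected, monomorphic=True)
    observed = (genotypes.aa, genotypes.ag, genotypes.gg)
    chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
    p_value = float(stats.chi2.sf(chi2, df=1))
    return HWEResult(chi2=float(chi2), df=1, p=p_value, in_hwe=p_value >= alpha, expected=expected)
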