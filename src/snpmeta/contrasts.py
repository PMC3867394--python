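"""Genetic-model contrasts and per-study odds ratios.

Each of the four classical genetic models dichotomizes the three genotypes
into exposed/unexposed, giving a 2x2 table per study:

===============  ==================  =====================
model            exposed             unexposed
===============  ==================  =====================
homozygote       GG                  AA   (AG excluded)
heterozygote     AG                  AA   (GG excluded)
dominant         GG + AG             AA
recessive        GG                  AG + AA
===============  ==================  =====================

The per-study effect is the sample odds ratio ``ad/bc`` with the Woolf
(inverse-cell-count) variance of its logarithm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from enum import Enum

from .errors import DegenerateTableError
from .studies import GenotypeCounts

#: Normal quantile used for 95% confidence intervals.
Z_95 = 1.96


class GeneticModel(str, Enum):
    HOMOZYGOTE = "homozygote"
    HETEROZYGOTE = "heterozygote"
    DOMINANT = "dominant"
    RECESSIVE = "recessive"

    @property
    def label(self) -> str:
        return {
            GeneticModel.HOMOZYGOTE: "GG vs AA",
            GeneticModel.HETEROZYGOTE: "AG vs AA",
            GeneticModel.DOMINANT: "GG/AG vs AA",
            GeneticModel.RECESSIVE: "GG vs AG/AA",
        }[self]


@dataclass(frozen=True)
class ContrastTable:
    """2x2 exposure table (a=case exposed, b=case unexposed, c/d controls)."""

    a: float
    b: float
    c: float
    d: float
    model: GeneticModel
    study_id: str = ""
    corrected: bool = False

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise DegenerateTableError(f"table {self.study_id}: negative cell")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise DegenerateTableError(
                f"table {self.study_id} ({self.model.value}): empty case or control margin"
            )

    @property
    def n(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def cells(self) -> tuple[float, float, float, float]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class EffectEstimate:
    """Per-study log odds ratio with Woolf standard error and 95% CI."""

    log_or: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    study_id: str = ""


def build_two_by_two(cases: GenotypeCounts, controls: GenotypeCounts, model: GeneticModel,
                     study_id: str = "") -> ContrastTable:
    """Collapse genotype counts into the 2x2 table for ``model``.

    For the homozygote and heterozygote models the middle genotype column is
    *excluded* (those individuals drop out of the table), not merged.
    """
    if model is GeneticModel.HOMOZYGOTE:
        cells = (cases.gg, cases.aa, controls.gg, controls.aa)
    elif model is GeneticModel.HETEROZYGOTE:
        cells = (cases.ag, cases.aa, controls.ag, controls.aa)
    elif model is GeneticModel.DOMINANT:
        cells = (cases.gg + cases.ag, cases.aa, controls.gg + controls.ag, controls.aa)
    elif model is GeneticModel.RECESSIVE:
        cells = (cases.gg, cases.aa + cases.ag, controls.gg, controls.aa + controls.ag)
    else:  # pragma: no cover - closed enum
        raise ValueError(f"unknown genetic model {model!r}")
    return ContrastTable(*[float(x) for x in cells], model=model, study_id=study_id)


def continuity_correct(table: ContrastTable, increment: float = 0.5) -> ContrastTable:
    """Haldane–Anscombe correction: add ``increment`` to every cell iff some cell is zero."""
    if min(table.cells) > 0:
        return table
    return replace(
        table,
        a=table.a + increment,
        b=table.b + increment,
        c=table.c + increment,
        d=table.d + increment,
        corrected=True,
    )


def study_effect(table: ContrastTable) -> EffectEstimate:
    """Sample odds ratio ``ad/bc`` with the Woolf variance of the log OR.

    The table must be strictly positive in every cell; run
    :func:`continuity_correct` first when zeros are possible.
    """
    a, b, c, d = table.cells
    if min(a, b, c, d) <= 0:
        raise DegenerateTableError(
            f"table {table.study_id}: zero cell; apply continuity_correct before study_effect"
        )
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return EffectEstimate(
        log_or=log_or,
        se=se,
        or_=math.exp(log_or),
        ci_low=math.exp(log_or - Z_95 * se),
        ci_high=math.exp(log_or + Z_95 * se),
        study_id=table.study_id,
    )


def effect_for_study(cases: GenotypeCounts, controls: GenotypeCounts, model: GeneticModel,
                     study_id: str = "") -> EffectEstimate:
    """Convenience: table construction, zero-cell correction and effect in one call."""
    return study_effect(continuity_correct(build_two_by_two(cases, controls, model, study_id)))
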