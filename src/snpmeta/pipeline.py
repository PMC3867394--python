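"""Full meta-analysis orchestration: strata x genetic models, sensitivity,
and categorical meta-regression.

``run_meta_analysis`` reproduces the shape of a classical association
meta-analysis summary table: one row per stratum of a grouping factor
(overall, cancer group, ethnicity, control source or size class), one
column block per genetic model, each cell a pooled OR with its
heterogeneity summary.  The estimator per cell is chosen by the
``model_selection`` policy:

* ``paper_rule`` — Mantel–Haenszel fixed effects when the Q test's p-value
  exceeds ``het_threshold`` (0.10), DerSimonian–Laird random effects
  otherwise;
* ``force_fixed_mh`` / ``force_fixed_iv`` / ``force_random`` — pin one
  estimator for every cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .contrasts import (
    ContrastTable,
    EffectEstimate,
    GeneticModel,
    build_two_by_two,
    continuity_correct,
    study_effect,
)
from .errors import (
    ConfigError,
    DegenerateCovariateError,
    HeterogeneityUndefinedError,
    PoolingError,
)
from .pooling import (
    HET_THRESHOLD,
    PoolMethod,
    PoolResult,
    cochran_q,
    pool,
    select_model,
)
from .studies import StudyRecord, subgroup_members


class Grouping(str, Enum):
    OVERALL = "overall"
    CANCER_GROUP = "cancer_group"
    ETHNICITY_GROUP = "ethnicity_group"
    SOURCE_GROUP = "source_group"
    SIZE_CLASS = "size_class"


class ModelSelection(str, Enum):
    PAPER_RULE = "paper_rule"
    FORCE_FIXED_MH = "force_fixed_mh"
    FORCE_FIXED_IV = "force_fixed_iv"
    FORCE_RANDOM = "force_random"


_FORCED = {
    ModelSelection.FORCE_FIXED_MH: PoolMethod.MH_FIXED,
    ModelSelection.FORCE_FIXED_IV: PoolMethod.IV_FIXED,
    ModelSelection.FORCE_RANDOM: PoolMethod.DL_RANDOM,
}


@dataclass(frozen=True)
class AnalysisConfig:
    genetic_models: tuple[GeneticModel, ...] = tuple(GeneticModel)
    grouping: Grouping = Grouping.OVERALL
    model_selection: ModelSelection = ModelSelection.PAPER_RULE
    het_threshold: float = HET_THRESHOLD
    ci_level: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.genetic_models:
            raise ConfigError("at least one genetic model must be selected")
        if not (0.0 < self.het_threshold < 1.0):
            raise ConfigError("het_threshold must lie in (0, 1)")


@dataclass(frozen=True)
class StratumResult:
    """One cell of the summary table: a pooled result with its context."""

    group: str
    model: GeneticModel
    result: PoolResult
    study_ids: tuple[str, ...]
    single_study: bool = False

    @property
    def k(self) -> int:
        return self.result.k


@dataclass(frozen=True)
class MetaRegResult:
    """Categorical random-effects meta-regression of log ORs on one factor."""

    covariate: str
    levels: tuple[str, ...]
    coefficients: tuple[float, ...]
    se: tuple[float, ...]
    p_model: float
    tau2_residual: float


def _study_cell(record: StudyRecord, model: GeneticModel) -> tuple[ContrastTable, EffectEstimate]:
    table = continuity_correct(build_two_by_two(record.cases, record.controls, model, record.study_id))
    return table, study_effect(table)


def _pool_group(records: Sequence[StudyRecord], model: GeneticModel, config: AnalysisConfig,
                group: str) -> StratumResult:
    pairs = [_study_cell(r, model) for r in records]
    tables = [t for t, _ in pairs]
    effects = [e for _, e in pairs]
    k = len(records)
    if config.model_selection is ModelSelection.PAPER_RULE:
        method = (
            select_model(cochran_q(effects), config.het_threshold)
            if k >= 2
            else PoolMethod.MH_FIXED
        )
    else:
        method = _FORCED[config.model_selection]
    result = pool(tables, effects, method)
    return StratumResult(
        group=group,
        model=model,
        result=result,
        study_ids=tuple(r.study_id for r in records),
        single_study=(k == 1),
    )


def run_meta_analysis(studies: Sequence[StudyRecord],
                      config: AnalysisConfig = AnalysisConfig()) -> dict[tuple[str, GeneticModel], StratumResult]:
    """Pool every (stratum, genetic model) cell for the configured grouping.

    Strata with a single study are emitted flagged, not suppressed.  Keys are
    ``(group_level, model)``; for ``Grouping.OVERALL`` the single level is
    ``"overall"``.
    """
    if not studies:
        raise PoolingError("no studies to analyse")
    if config.grouping is Grouping.OVERALL:
        groups: dict[str, list[StudyRecord]] = {"overall": list(studies)}
    else:
        groups = subgroup_members(studies)[config.grouping.value]
    out: dict[tuple[str, GeneticModel], StratumResult] = {}
    for level, members in groups.items():
        for model in config.genetic_models:
            out[(level, model)] = _pool_group(members, model, config, level)
    return out


def leave_one_out(studies: Sequence[StudyRecord], model: GeneticModel,
                  config: AnalysisConfig = AnalysisConfig()) -> list[tuple[str, PoolResult]]:
    """Re-pool with each study removed in turn (one-way sensitivity analysis).

    Returns ``k`` pairs ``(excluded_study_id, PoolResult over the k-1
    remaining studies)`` using the same estimator policy as the full
    analysis.
    """
    if len(studies) < 2:
        raise HeterogeneityUndefinedError("leave-one-out needs at least two studies")
    results: list[tuple[str, PoolResult]] = []
    for omit in studies:
        remaining = [s for s in studies if s.study_id != omit.study_id]
        stratum = _pool_group(remaining, model, config, group="leave_one_out")
        results.append((omit.study_id, stratum.result))
    return results


def meta_regression(effects: Sequence[EffectEstimate], labels: Sequence[str],
                    covariate: str = "covariate") -> MetaRegResult:
    """Random-effects meta-regression of log ORs on one categorical factor.

    The design matrix is an intercept (reference = alphabetically first
    level, so the fit is invariant to study order) plus indicators for the
    remaining levels.  The residual
    between-study variance is the method-of-moments estimate
    ``max(0, (Q_E - (k - p)) / (tr(W) - tr((X'WX)^-1 X'W^2X)))`` computed
    from the fixed-effects fit, after which coefficients come from weighted
    least squares with weights ``1/(se_i^2 + tau2)``.  ``p_model`` is a joint
    Wald chi-square test that all non-reference coefficients vanish, i.e.
    that the factor explains none of the between-study spread.
    """
    if len(effects) != len(labels):
        raise ConfigError("effects and labels must align")
    k = len(effects)
    levels = sorted(set(labels))
    if len(levels) < 2:
        raise DegenerateCovariateError(f"covariate {covariate!r} has a single level")
    p = len(levels)
    if k < p + 1:
        raise PoolingError(
            f"meta-regression on {covariate!r} needs at least {p + 1} studies, got {k}"
        )
    y = np.array([e.log_or for e in effects], dtype=float)
    v = np.array([e.se**2 for e in effects], dtype=float)
    x = np.zeros((k, p))
    x[:, 0] = 1.0
    for i, lab in enumerate(labels):
        j = levels.index(lab)
        if j > 0:
            x[i, j] = 1.0

    w = 1.0 / v
    wx = x * w[:, None]
    xtwx = x.T @ wx
    xtwx_inv = np.linalg.inv(xtwx)
    beta_fe = xtwx_inv @ (wx.T @ y)
    resid = y - x @ beta_fe
    q_e = float(np.sum(w * resid**2))
    # moment estimator: E[Q_E] = (k - p) + tau2 * (tr W - tr((X'WX)^-1 X'W^2X))
    denom = float(np.sum(w)) - float(np.trace(xtwx_inv @ (x.T @ (x * (w**2)[:, None]))))
    tau2 = max(0.0, (q_e - (k - p)) / denom) if denom > 0 else 0.0

    w_star = 1.0 / (v + tau2)
    wx = x * w_star[:, None]
    cov = np.linalg.inv(x.T @ wx)
    beta = cov @ (wx.T @ y)
    se = np.sqrt(np.diag(cov))

    # joint Wald test on the p-1 non-reference coefficients
    idx = np.arange(1, p)
    c = beta[idx]
    c_cov = cov[np.ix_(idx, idx)]
    wald = float(c @ np.linalg.solve(c_cov, c))
    p_model = float(stats.chi2.sf(wald, df=p - 1))

    coefficients = [0.0] + [float(b) for b in beta[1:]]
    ses = [float(s) for s in se]
    return MetaRegResult(
        covariate=covariate,
        levels=tuple(levels),
        coefficients=tuple(coefficients),
        se=tuple(ses),
        p_model=p_model,
        tau2_residual=tau2,
    )


def meta_regression_by_factor(studies: Sequence[StudyRecord], model: GeneticModel,
                              factor: Grouping) -> MetaRegResult:
    """Univariate meta-regression of per-study log ORs on one grouping factor."""
    if factor is Grouping.OVERALL:
        raise ConfigError("meta-regression needs a stratifying factor, not 'overall'")
    from .studies import classify

    effects = [_study_cell(r, model)[1] for r in studies]
    labels = [getattr(classify(r), factor.value).value for r in studies]
    return meta_regression(effects, labels, covariate=factor.value)
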