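"""Report assembly and rendering (TSV for reading, JSON for full precision).

TSV cells follow the conventional print format of association
meta-analyses: OR and CI to 2 decimals as ``1.29(1.02,1.64)``, heterogeneity
p-values to 3 decimals.  The JSON sidecar carries every number at full
precision plus per-study weights, and a provenance block (config echo,
dataset identifier, seed) so identical invocations are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from enum import Enum
from typing import Any, Mapping, Sequence

from .bias import BeggResult, EggerResult, FunnelData
from .contrasts import GeneticModel
from .hwe import hwe_test
from .pipeline import (
    AnalysisConfig,
    Grouping,
    StratumResult,
    leave_one_out,
    run_meta_analysis,
)
from .pooling import PoolResult
from .studies import StudyRecord, classify

PACKAGE_VERSION = "0.1.0"


def fmt_or_ci(or_: float, low: float, high: float) -> str:
    return f"{or_:.2f}({low:.2f},{high:.2f})"


def fmt_p(p: float, dp: int = 3) -> str:
    floor = 10.0 ** (-dp)
    return f"<{floor:.{dp}f}" if p < floor else f"{p:.{dp}f}"


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, Mapping):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    return obj


def to_json(payload: Any, indent: int = 2) -> str:
    """Deterministic JSON: sorted keys, fixed separators, trailing newline."""
    return json.dumps(_to_jsonable(payload), indent=indent, sort_keys=True) + "\n"


def study_summary_rows(studies: Sequence[StudyRecord]) -> list[dict[str, Any]]:
    """Per-study characteristics row: metadata, subgroups, HWE in controls."""
    rows = []
    for rec in studies:
        labels = classify(rec)
        hwe = hwe_test(rec.controls)
        rows.append(
            {
                "study_id": rec.study_id,
                "first_author": rec.first_author,
                "year": rec.year,
                "country": rec.country,
                "ethnicity": rec.ethnicity.value,
                "cancer_type": rec.cancer_type,
                "cancer_group": labels.cancer_group.value,
                "control_source": rec.control_source.value,
                "size_class": labels.size_class.value,
                "n_cases": rec.cases.total,
                "n_controls": rec.controls.total,
                "case_aa": rec.cases.aa,
                "case_ag": rec.cases.ag,
                "case_gg": rec.cases.gg,
                "control_aa": rec.controls.aa,
                "control_ag": rec.controls.ag,
                "control_gg": rec.controls.gg,
                "hwe_chi2": hwe.chi2,
                "hwe_p": hwe.p,
                "hwe": "Yes" if hwe.in_hwe else "No",
            }
        )
    return rows


def render_tsv(rows: Sequence[Mapping[str, Any]], float_dp: int = 4) -> str:
    """Render homogeneous dict rows as a TSV block with a header."""
    if not rows:
        return ""
    cols = list(rows[0].keys())
    lines = ["\t".join(cols)]
    for row in rows:
        cells = []
        for c in cols:
            v = row[c]
            cells.append(f"{v:.{float_dp}f}" if isinstance(v, float) else str(v))
        lines.append("\t".join(cells))
    return "\n".join(lines) + "\n"


def main_table_rows(results: Mapping[tuple[str, GeneticModel], StratumResult],
                    hide_single_study: bool = False) -> list[dict[str, Any]]:
    """Summary-table rows: one per stratum, OR(CI) and P_h per genetic model."""
    groups: list[str] = []
    for (group, _model) in results:
        if group not in groups:
            groups.append(group)
    models = [m for m in GeneticModel if any((g, m) in results for g in groups)]
    rows = []
    for group in groups:
        any_cell = next(results[(group, m)] for m in models if (group, m) in results)
        if hide_single_study and any_cell.single_study:
            continue
        row: dict[str, Any] = {"group": group, "N": any_cell.k}
        for m in models:
            cell = results.get((group, m))
            if cell is None:
                continue
            r = cell.result
            row[f"{m.value}_or_ci"] = fmt_or_ci(r.or_, r.ci_low, r.ci_high)
            row[f"{m.value}_p_h"] = fmt_p(r.het.p_het)
            row[f"{m.value}_method"] = r.method.value
        if any_cell.single_study:
            row["note"] = "single-study stratum"
        rows.append(row)
    return rows


def sensitivity_rows(pairs: Sequence[tuple[str, PoolResult]]) -> list[dict[str, Any]]:
    return [
        {
            "excluded_study": sid,
            "k": res.k,
            "or_ci": fmt_or_ci(res.or_, res.ci_low, res.ci_high),
            "p": res.p,
            "p_h": res.het.p_het,
            "method": res.method.value,
        }
        for sid, res in pairs
    ]


def funnel_rows(funnel: FunnelData) -> list[dict[str, Any]]:
    rows = [
        {"kind": "study", "id": sid, "se": y, "log_or": x, "log_or_low": "", "log_or_high": ""}
        for sid, (x, y) in zip(funnel.study_ids, funnel.points)
    ]
    rows += [
        {"kind": "guide", "id": "pseudo95", "se": s, "log_or": "",
         "log_or_low": lo, "log_or_high": hi}
        for s, lo, hi in zip(funnel.guide_se, funnel.guide_low, funnel.guide_high)
    ]
    return rows


@dataclass(frozen=True)
class ReportBundle:
    """Everything one run of the full analysis produces."""

    study_summary: list[dict[str, Any]]
    main_table: dict[str, Any]
    sensitivity_table: list[dict[str, Any]]
    bias_results: dict[str, Any]
    provenance: dict[str, Any]


def build_report(studies: Sequence[StudyRecord], config: AnalysisConfig,
                 dataset: str, sensitivity_model: GeneticModel = GeneticModel.RECESSIVE,
                 bias: Mapping[str, EggerResult | BeggResult] | None = None) -> ReportBundle:
    """Assemble the full bundle: per-study summary, all-groupings summary
    table, leave-one-out sensitivity, bias tests and provenance."""
    all_results: dict[str, Any] = {}
    for grouping in Grouping:
        cfg = dataclasses.replace(config, grouping=grouping)
        res = run_meta_analysis(studies, cfg)
        all_results[grouping.value] = {
            f"{group}|{model.value}": stratum
            for (group, model), stratum in res.items()
        }
    sens = (
        sensitivity_rows(leave_one_out(studies, sensitivity_model, config))
        if len(studies) >= 2
        else []
    )
    return ReportBundle(
        study_summary=study_summary_rows(studies),
        main_table=all_results,
        sensitivity_table=sens,
        bias_results=dict(bias or {}),
        provenance={
            "package": "snpmeta",
            "version": PACKAGE_VERSION,
            "dataset": dataset,
            "n_studies": len(studies),
            "config": config,
            "seed": config.seed,
        },
    )
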