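# Methods

`snpmeta` implements a genotype-based odds-ratio meta-analysis for
case-control SNP association studies, applied to the bundled 19-study table
for the MCP-1 −2518A/G (rs1024611) promoter polymorphism and cancer risk.
This note records the statistical model, the numerical conventions, the
open design choices and the known limitations — including the places where
the bundled table is internally inconsistent as printed.

## Data model

Each study contributes genotype counts (AA, AG, GG) for cases and controls
plus metadata (author, year, country, ethnicity ∈ {Asian, Caucasian,
Mixed}, cancer type, control source ∈ {HB hospital-based, PB
population-based}). Four derived strata drive the subgroup analyses:

* **cancer group** — digestive (oral, gastric, colorectal, hepatocellular),
  bladder, prostate, other (unrecognised sites map to *other*);
* **size class** — *large* iff cases + controls > 500, strictly: a study
  with exactly 500 participants is *small* (no bundled study sits on the
  boundary);
* **ethnicity** and **control source** as recorded.

Study tables are plain CSV/TSV with a fixed 13-column schema; the bundled
table is package data in the same format, so synthetic tables written by
`snpmeta simulate` flow through the identical entry point.

## Genetic-model contrasts and per-study effects

The three genotypes are dichotomized four ways: homozygote GG vs AA,
heterozygote AG vs AA (the third genotype is *excluded*, not merged, in
these two), dominant GG+AG vs AA, recessive GG vs AG+AA. Each yields a 2×2
table per study; the per-study effect is the sample odds ratio ad/bc with
the Woolf variance of its log, Var(log OR) = 1/a + 1/b + 1/c + 1/d. 95%
intervals use the quantile 1.96 exactly; at the 2-decimal precision of the
reported tables the difference from a higher-precision quantile is below
rounding. Zero cells receive the Haldane–Anscombe correction (0.5 added to
all four cells, only when some cell is zero); no bundled table triggers it,
so the correction cannot perturb any reported value — it exists for
synthetic and user data.

## Pooling and heterogeneity

Three pooled estimators are implemented:

* **Mantel–Haenszel fixed effects** on the tables,
  OR = Σ(aᵢdᵢ/nᵢ) / Σ(bᵢcᵢ/nᵢ), with the Robins–Breslow–Greenland
  variance for its log;
* **inverse-variance fixed effects** on log ORs with weights 1/seᵢ²;
* **DerSimonian–Laird random effects** with the moment estimator
  τ² = max(0, (Q − df)/(S₁ − S₂/S₁)), Sᵣ = Σwᵢʳ, then weights
  1/(seᵢ² + τ²). When Q ≤ df this collapses exactly to inverse-variance
  fixed effects.

Cochran's Q is computed with fixed inverse-variance weights around the
fixed-effects mean; I² = max(0, (Q − df)/Q) is reported as an extra output.
The pooled log OR is tested by a standard-normal Z test (two-sided,
significance at 0.05). The conventional selection rule — fixed effects when
the Q test's p exceeds 0.10, random effects otherwise, with the boundary
going to random effects — is the pipeline default (`paper_rule`).

**Which estimator reproduces the published table.** The published summary
cells are reproduced (to the printed 2 decimals) by DerSimonian–Laird
random effects in every pinned stratum, *including* strata where the stated
fixed-when-homogeneous rule would choose Mantel–Haenszel (e.g. digestive
recessive, P_h = 0.141, printed 1.29 (1.02, 1.64) = the DL result; MH gives
1.32 (1.12, 1.54)). The package therefore exposes `force_random` to
reproduce the published cells, keeps `paper_rule` as the default policy,
and reports both in the analysis drivers. In homogeneous strata the two
coincide (prostate heterozygote: τ² = 0, so 0.81 (0.62, 1.07) is
simultaneously the fixed- and random-effects answer).

## Hardy–Weinberg screening

Controls are tested with the Pearson χ² goodness-of-fit statistic on one
degree of freedom (three genotype classes, one estimated allele frequency),
no continuity correction; p < 0.05 flags disequilibrium. This variant
reproduces the two published flags exactly (Gu p = 0.007 < 0.01, Attar
p = 0.042 → 0.04); df = 2 or a continuity-corrected statistic would not.
Flagged studies are *retained* in all pools, matching the published
analysis. Monomorphic samples fit HWE trivially and are flagged as such.

## Sensitivity, meta-regression, publication bias

*Leave-one-out*: each study is removed in turn and the stratum re-pooled
under the same selection policy; for inverse-variance pooling the full
estimate is always bracketed by the k leave-one-out estimates.

*Meta-regression*: the published analysis names the procedure but not the
estimator, so the choice was open. We use a categorical random-effects
meta-regression: indicator design matrix (reference = alphabetically first
level, making the fit invariant to study order), residual τ² by the method
of moments from the fixed-effects fit, weighted least squares with weights
1/(vᵢ + τ²), and a joint Wald χ² test of all non-reference coefficients.
Because the estimator is not identifiable from the published text, its
p-values are reported but deliberately not treated as reproduction targets
(our univariate tests give cancer group p = 0.97 and ethnicity p = 0.007 on
the recessive contrast, versus the published "cancer type P = 0.02").

*Publication bias*: Egger's classical test (unweighted OLS of the
standardized effect log ORᵢ/seᵢ on precision 1/seᵢ; two-sided t test of the
intercept on k − 2 df) and the Begg–Mazumdar rank-correlation test
(variance-stabilized deviates from the fixed-effects mean, Kendall
correlation with the sampling variances, tie-corrected null variance,
continuity correction of one unit on |S|). Ties in the ranking degrade
gracefully: with all variances equal the test returns p = 1. A numerically
exact Egger fit (zero residual) returns p = 1 by convention rather than a
0/0 t-ratio.

## Synthetic-data generator

The generator mirrors the bundled table's structure: per study it draws a
control G-allele frequency uniformly (default 0.2–0.65, the observed
range), control genotypes from the HWE multinomial, and case genotypes from
the control distribution tilted by genotype odds ratios,
P_case(g) ∝ P_ctrl(g)·ψ_g with ψ_AA = 1. The tilt is the exact
retrospective-sampling consequence of a logistic disease model, so ψ_gg is
*exactly* the homozygote estimand — no rare-disease approximation.
Between-study heterogeneity adds b ~ N(0, τ²) to log ψ_gg and b/2 to
log ψ_ag (log-additive dosage scaling; exact proportionality when
ψ_ag = √ψ_gg). Per-arm sizes default to 50–600 cases and 80–600 controls,
the scale of the bundled studies. Reproducibility: one `SeedSequence` per
experiment, one spawned child generator per study, so any study is
reproducible independently of how many precede it.

What the generator does **not** emulate: population stratification,
genotyping error, shared control series across studies, covariate
confounding, or publication selection. Passing recovery tests therefore
shows the estimators are correctly implemented and calibrated for clean
multinomial sampling — not that real published literatures are bias-free.

Recovery experiments (driver `analysis/05_simulation_checks.py`; sizes
chosen to give stable rates at desk scale): 1000 replicates of k = 10 null
studies give a rejection rate of 0.039 and coverage 0.961; 200 replicates
of k = 30 studies at ψ_gg = 1.5 give |bias| < 0.01 on the log-OR scale; at
τ = 0.3 DL coverage (0.93) dominates fixed-effects coverage (0.76) on the
same seeds. Truth for the dominant/recessive contrasts depends on the
allele frequency, so recovery experiments accept only the homozygote and
heterozygote models.

## Fidelity to the printed table, and its internal inconsistencies

The bundled table preserves the published genotype counts *exactly as
printed*, including the following verified inconsistencies. They are
documented, not repaired, because the pooled cells only reproduce from the
printed counts:

* **Arshad row**: control genotypes (60, 87, 8) sum to 155, not the
  declared 190, and fail the HWE χ² at p ≈ 0.001 despite a printed "Yes".
  Restoring the declared total (e.g. GG = 43) breaks every published pooled
  cell that includes the study, so the printed counts are what was pooled.
  Summing genotype counts, the control total is 5,173 (matching the
  published abstract), while the declared per-study totals sum to 5,208.
* **HWE flags**: on the printed counts four control series fall below 0.05
  (Arshad 0.001, Gu 0.007, Sáenz-López 0.039, Attar 0.042), not the two the
  publication reports; the Gu and Attar values themselves reproduce
  exactly.
* **Publication-bias p-values**: the printed Egger/Begg p-values (0.96,
  0.67) are not reproduced from the printed counts (we obtain 0.93, 0.73);
  every pinned stratum that excludes the Arshad row reproduces exactly,
  so the printed bias p-values appear to rest on a slightly different
  underlying row.
* **Control source**: the printed per-study labels give 11 HB / 9 PB minus
  one — 11 HB / 8 PB — while the publication's prose and summary table say
  10 / 9; the source-of-control strata consequently do not reproduce and
  are not pinned anywhere.
* The published summary table's "Total N = 20" is a typo for 19, and the
  prose CI "0.74–2.05" for the large-studies homozygote cell is a typo for
  the table's (1.29, 1.96); computation supports the table in both cases.
* Excluding Yang 2010 or Vazquez-Lavista 2009 tips the overall GG-vs-AA CI
  just off 1 — the published claim that no exclusion changes the conclusion
  is nearly, but not exactly, true on the printed counts.

## Numerical conventions and degenerate inputs

* τ², I² floored at zero; Q-test boundary p = 0.10 selects random effects.
* Report rounding: OR/CI to 2 dp, heterogeneity p to 3 dp (JSON sidecars
  keep full precision); p-values below 10⁻³ print as `<0.001`.
* Single-study strata are emitted flagged (never silently dropped);
  rendering can hide them to mirror the published table, which omits the
  one-study Mixed-ethnicity stratum.
* Degenerate 2×2 tables (an empty case or control margin) raise a typed
  error; zero cells without correction raise rather than return ±inf.
* Mantel–Haenszel weights reported are the normalized bᵢcᵢ/nᵢ terms (the
  weights that make the MH estimate a weighted average of stratum ORs).

## Limitations

Allele-based (G vs A) contrasts, exact HWE tests, REML/Paule–Mandel τ²,
Hartung–Knapp adjustment, Peto pooling, trim-and-fill and selection models
are out of scope. The meta-regression estimator is one defensible choice
among several and its p-values should not be compared against the published
ones. Shared control series (the two Qin entries; the overlapping Taiwan
controls) are pooled as independent rows, exactly as in the published
analysis — no deduplication is attempted.
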