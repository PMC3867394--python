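"""Fixed-effects, random-effects and heterogeneity machinery."""

import math
import shutil
import subprocess
import textwrap

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpmeta as sm
from snpmeta.errors import HeterogeneityUndefinedError, PoolingError

from conftest import effects_for, tables_for
from oracle import oracle_dl_pool, oracle_iv_pool, oracle_mh_or, oracle_q_tau2

GM = sm.GeneticModel


def make_effect(log_or, se, sid="x"):
    return sm.EffectEstimate(
        log_or=log_or, se=se, or_=math.exp(log_or),
        ci_low=math.exp(log_or - 1.96 * se), ci_high=math.exp(log_or + 1.96 * se),
        study_id=sid,
    )


effect_lists = st.lists(
    st.tuples(
        st.floats(-2.0, 2.0, allow_nan=False),
        st.floats(0.05, 1.5, allow_nan=False),
    ),
    min_size=2,
    max_size=12,
).map(lambda pairs: [make_effect(lo, se, f"s{i}") for i, (lo, se) in enumerate(pairs)])


class TestMantelHaenszel:
    def test_prostate_heterozygote_pair(self, groups):
        prostate = groups["cancer_group"]["prostate"]
        res = sm.mh_fixed_pool(tables_for(prostate, GM.HETEROZYGOTE))
        assert round(res.or_, 2) == 0.81
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.62, 1.07)

    def test_single_study_returns_study_or(self, by_id):
        t = tables_for([by_id["gu2011"]], GM.RECESSIVE)
        e = sm.study_effect(t[0])
        res = sm.mh_fixed_pool(t)
        assert res.or_ == pytest.approx(e.or_, rel=1e-12)

    def test_duplicated_stratum_preserves_or(self, by_id):
        t = tables_for([by_id["gu2011"]], GM.RECESSIVE)[0]
        res = sm.mh_fixed_pool([t, t])
        assert res.or_ == pytest.approx(sm.study_effect(t).or_, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(PoolingError):
            sm.mh_fixed_pool([])

    def test_point_estimate_matches_rational_oracle(self, fixture_studies):
        for model in GM:
            tables = tables_for(fixture_studies, model)
            res = sm.mh_fixed_pool(tables)
            assert res.or_ == pytest.approx(
                float(oracle_mh_or([t.cells for t in tables])), rel=1e-12
            )

    def test_agrees_with_inverse_variance_on_fixture_strata(self, groups, fixture_studies):
        """MH and IV fixed effects nearly coincide in the moderate-count
        regime; the bladder stratum holds very sparse cells (GG counts of 3)
        plus one internally inconsistent published row, where the two
        estimators legitimately drift apart."""
        strata = {"overall": fixture_studies}
        for factor, levels in groups.items():
            for lvl, members in levels.items():
                strata[f"{factor}:{lvl}"] = members
        for name, members in strata.items():
            if len(members) < 2:
                continue
            tol = 0.09 if name == "cancer_group:bladder" else 0.03
            for model in GM:
                mh = sm.mh_fixed_pool(tables_for(members, model))
                iv = sm.iv_fixed_pool(effects_for(members, model))
                assert abs(mh.or_ - iv.or_) / iv.or_ < tol, (name, model)


class TestInverseVariance:
    def test_prostate_heterozygote_pair(self, groups):
        res = sm.iv_fixed_pool(effects_for(groups["cancer_group"]["prostate"], GM.HETEROZYGOTE))
        assert round(res.or_, 2) == 0.81
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (0.62, 1.07)

    def test_identical_effects_shrink_se_by_sqrt_k(self):
        effects = [make_effect(0.4, 0.2, f"s{i}") for i in range(4)]
        res = sm.iv_fixed_pool(effects)
        assert res.log_or == pytest.approx(0.4)
        assert res.se == pytest.approx(0.2 / 2.0)

    def test_single_effect_returned_unchanged(self):
        e = make_effect(0.3, 0.15)
        res = sm.iv_fixed_pool([e])
        assert (res.log_or, res.se) == (pytest.approx(0.3), pytest.approx(0.15))
        assert res.k == 1

    @settings(max_examples=100, deadline=None)
    @given(effects=effect_lists)
    def test_pooled_estimate_within_study_range(self, effects):
        res = sm.iv_fixed_pool(effects)
        los = [e.log_or for e in effects]
        assert min(los) - 1e-9 <= res.log_or <= max(los) + 1e-9

    @settings(max_examples=100, deadline=None)
    @given(effects=effect_lists)
    def test_matches_plain_loop_oracle(self, effects):
        res = sm.iv_fixed_pool(effects)
        mu, se = oracle_iv_pool([e.log_or for e in effects], [e.se for e in effects])
        assert res.log_or == pytest.approx(mu, rel=1e-10, abs=1e-10)
        assert res.se == pytest.approx(se, rel=1e-10)

    def test_weights_normalized(self, fixture_studies):
        res = sm.iv_fixed_pool(effects_for(fixture_studies, GM.RECESSIVE))
        assert sum(res.weights) == pytest.approx(1.0)
        assert all(w >= 0 for w in res.weights)


class TestCochranQ:
    def test_digestive_recessive_heterogeneity(self, groups):
        het = sm.cochran_q(effects_for(groups["cancer_group"]["digestive"], GM.RECESSIVE))
        assert round(het.p_het, 2) == 0.14
        assert het.df == 5

    def test_large_studies_homozygote_heterogeneity(self, groups):
        het = sm.cochran_q(effects_for(groups["size_class"]["large"], GM.HOMOZYGOTE))
        assert round(het.p_het, 2) == 0.17
        assert het.df == 6

    def test_identical_effects_give_zero_q(self):
        het = sm.cochran_q([make_effect(0.5, 0.2, f"s{i}") for i in range(5)])
        assert het.q == pytest.approx(0.0, abs=1e-12)
        assert het.i2 == 0.0
        assert het.tau2 == 0.0

    def test_single_study_undefined(self):
        with pytest.raises(HeterogeneityUndefinedError):
            sm.cochran_q([make_effect(0.5, 0.2)])

    @settings(max_examples=100, deadline=None)
    @given(effects=effect_lists)
    def test_matches_plain_loop_oracle(self, effects):
        het = sm.cochran_q(effects)
        q, tau2 = oracle_q_tau2([e.log_or for e in effects], [e.se for e in effects])
        assert het.q == pytest.approx(q, rel=1e-9, abs=1e-9)
        assert het.tau2 == pytest.approx(tau2, rel=1e-9, abs=1e-9)
        assert 0.0 <= het.i2 < 1.0


class TestDerSimonianLaird:
    def test_digestive_recessive_reproduces_published_cell(self, groups):
        res = sm.dl_random_pool(effects_for(groups["cancer_group"]["digestive"], GM.RECESSIVE))
        assert round(res.or_, 2) == 1.29
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.02, 1.64)

    def test_large_recessive_reproduces_published_cell(self, groups):
        res = sm.dl_random_pool(effects_for(groups["size_class"]["large"], GM.RECESSIVE))
        assert round(res.or_, 2) == 1.38
        assert (round(res.ci_low, 2), round(res.ci_high, 2)) == (1.15, 1.66)

    def test_collapses_to_fixed_effects_when_q_below_df(self):
        effects = [make_effect(0.30, 0.5, "a"), make_effect(0.32, 0.5, "b"),
                   make_effect(0.31, 0.5, "c")]
        dl = sm.dl_random_pool(effects)
        iv = sm.iv_fixed_pool(effects)
        assert dl.het.tau2 == 0.0
        assert dl.log_or == pytest.approx(iv.log_or, rel=1e-12)
        assert dl.se == pytest.approx(iv.se, rel=1e-12)

    @settings(max_examples=100, deadline=None)
    @given(effects=effect_lists)
    def test_never_narrower_than_fixed_effects(self, effects):
        dl = sm.dl_random_pool(effects)
        iv = sm.iv_fixed_pool(effects)
        assert dl.se >= iv.se - 1e-12

    @settings(max_examples=100, deadline=None)
    @given(effects=effect_lists)
    def test_matches_plain_loop_oracle(self, effects):
        res = sm.dl_random_pool(effects)
        mu, se = oracle_dl_pool([e.log_or for e in effects], [e.se for e in effects])
        assert res.log_or == pytest.approx(mu, rel=1e-9, abs=1e-9)
        assert res.se == pytest.approx(se, rel=1e-9)

    def test_z_and_p_consistent(self, fixture_studies):
        res = sm.dl_random_pool(effects_for(fixture_studies, GM.HOMOZYGOTE))
        assert res.z == pytest.approx(res.log_or / res.se)
        assert 0.0 < res.p <= 1.0


class TestSelectModel:
    @pytest.mark.parametrize(
        "p_het, expected",
        [
            (0.808, sm.PoolMethod.MH_FIXED),
            (0.004, sm.PoolMethod.DL_RANDOM),
            (0.10, sm.PoolMethod.DL_RANDOM),   # boundary goes to random effects
            (0.101, sm.PoolMethod.MH_FIXED),
        ],
    )
    def test_threshold_rule(self, p_het, expected):
        het = sm.HeterogeneityResult(q=1.0, df=1, p_het=p_het, i2=0.0, tau2=0.0)
        assert sm.select_model(het) is expected


class TestAgainstMetafor:
    def test_dl_matches_r_metafor_on_fixture(self, fixture_studies, tmp_path):
        """Independent cross-check: R's metafor (rma, method='DL') on the
        19-study recessive contrast must agree with our DL pooling."""
        assert shutil.which("Rscript"), "Rscript expected on PATH"
        effects = effects_for(fixture_studies, GM.RECESSIVE)
        data = tmp_path / "effects.tsv"
        data.write_text(
            "yi\tvi\n"
            + "".join(f"{e.log_or:.15g}\t{e.se**2:.15g}\n" for e in effects)
        )
        script = tmp_path / "dl.R"
        script.write_text(
            textwrap.dedent(
                """
                suppressMessages(library(metafor))
                d <- read.table(commandArgs(TRUE)[1], header = TRUE)
                f <- rma(yi = d$yi, vi = d$vi, method = "DL")
                cat(sprintf("%.12f %.12f %.12f %.12f\\n", f$b[1], f$se, f$tau2, f$QE))
                """
            )
        )
        out = subprocess.run(
            ["Rscript", str(script), str(data)],
            capture_output=True, text=True, check=True, timeout=300,
        )
        b, se, tau2, qe = map(float, out.stdout.split()[-4:])
        res = sm.dl_random_pool(effects)
        assert res.log_or == pytest.approx(b, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)
        assert res.het.tau2 == pytest.approx(tau2, abs=1e-8)
        assert res.het.q == pytest.approx(qe, abs=1e-8)
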