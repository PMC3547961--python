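import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bmigrowth.assoc import (
    bonferroni,
    compute_allele_score,
    global_lrt_assoc,
    per_age_effect,
    sitar_param_assoc,
)
from bmigrowth.bases import BasisSpec
from bmigrowth.cohort import GenotypeTable
from bmigrowth.lmm import GrowthLMM, ModelSpec, preset_spec
from bmigrowth.simulate import (
    SNP_PANEL,
    SimulationConfig,
    TrueParams,
    make_scenario,
    simulate_bmi,
    simulate_genotypes,
    simulate_schedule,
)

from conftest import reduced_null_truth

REDUCED_SPEC = ModelSpec(
    scale="ln",
    fixed=BasisSpec(kind="polynomial", degree=3, center=8.0),
    random="linear",
    error="independent",
)


def reduced_scenario(n=150, seed=0, score_effects=None):
    cfg = SimulationConfig(
        n_male=0, n_female=n,
        wave_ages=(1.0, 6.0, 10.0, 17.0),
        attendance=(1.0,) * 4,
        age_jitter_sd=(0.1, 0.2, 0.2, 0.25),
        seed=seed,
    )
    sk = simulate_schedule(cfg)
    genotypes = simulate_genotypes(sk["subject_id"].unique(), SNP_PANEL, seed=seed + 1)
    true = reduced_null_truth(score_effects=score_effects or {})
    cohort = simulate_bmi(sk, genotypes, true, seed=seed + 2)
    return cohort, genotypes


class TestAlleleScore:
    def test_all_zero_dosages(self):
        table = GenotypeTable(pd.DataFrame(
            {s.snp_id: [0.0, 0.0] for s in SNP_PANEL}, index=[1, 2]))
        assert (compute_allele_score(table, SNP_PANEL) == 0).all()

    def test_upper_bound_thirty_four(self):
        table = GenotypeTable(pd.DataFrame(
            {s.snp_id: [2.0] for s in SNP_PANEL}, index=[1]))
        assert compute_allele_score(table, SNP_PANEL).iloc[0] == 34

    def test_missing_locus_excludes_subject(self):
        data = {s.snp_id: [1.0, 1.0] for s in SNP_PANEL}
        table = GenotypeTable(pd.DataFrame(data, index=[1, 2]))
        df = table.df.copy()
        df.loc[2, SNP_PANEL[0].snp_id] = np.nan
        score = compute_allele_score(GenotypeTable(df))
        assert list(score.index) == [1]

    def test_locus_order_invariance(self):
        rng = np.random.default_rng(0)
        table = simulate_genotypes(range(50), SNP_PANEL, seed=1)
        s1 = compute_allele_score(table, SNP_PANEL)
        s2 = compute_allele_score(table, list(SNP_PANEL)[::-1])
        pd.testing.assert_series_equal(s1, s2)

    def test_absent_locus_raises(self):
        table = simulate_genotypes(range(10), SNP_PANEL[:5], seed=2)
        with pytest.raises(KeyError):
            compute_allele_score(table, SNP_PANEL)


class TestDesignAugmentation:
    def test_interaction_zero_adds_one_column(self):
        cohort, genotypes = reduced_scenario(seed=5)
        g = genotypes.dosage(SNP_PANEL[0].snp_id)
        from bmigrowth.assoc import add_genetic_terms

        spec0 = add_genetic_terms(REDUCED_SPEC, g, "fto", interactions=0)
        spec3 = add_genetic_terms(REDUCED_SPEC, g, "fto", interactions=3)
        m0 = GrowthLMM(cohort, spec0)
        m3 = GrowthLMM(cohort, spec3)
        assert m0.data.p == m3.data.p - 3 == 5

    def test_constant_g_raises_collinearity(self):
        cohort, genotypes = reduced_scenario(seed=6)
        g = pd.Series(1.0, index=genotypes.df.index)
        from bmigrowth.assoc import add_genetic_terms

        with pytest.raises(ValueError, match="constant"):
            GrowthLMM(cohort, add_genetic_terms(REDUCED_SPEC, g, "const_g"))

    def test_null_estimates_cover_zero(self):
        # genetics-free truth: all four genetic terms near zero
        cohort, genotypes = reduced_scenario(n=300, seed=7)
        score = compute_allele_score(genotypes)
        res = global_lrt_assoc(cohort, REDUCED_SPEC, score, engine="lmm")
        cover = (res.terms["ci_low"] <= 0) & (0 <= res.terms["ci_high"])
        assert cover.sum() >= 3  # 95% CIs; allow one miss among four


class TestGlobalLRT:
    def test_statistic_is_twice_delta_loglik(self):
        cohort, genotypes = reduced_scenario(n=200, seed=8)
        score = compute_allele_score(genotypes)
        res = global_lrt_assoc(cohort, REDUCED_SPEC, score, engine="lmm")
        assert res.lrt_stat == pytest.approx(
            2 * (res.llf_full - res.llf_null), abs=1e-8
        )
        assert res.lrt_df == 4

    def test_injected_score_effect_detected(self):
        cohort, genotypes = reduced_scenario(
            n=400, seed=9, score_effects={"level": 0.006, "slope": 0.0015}
        )
        score = compute_allele_score(genotypes)
        res = global_lrt_assoc(cohort, REDUCED_SPEC, score, engine="lmm")
        assert res.lrt_p < 0.01
        assert res.terms.loc["score", "beta"] > 0

    def test_permutation_null_p_uniform(self):
        cohort, genotypes = reduced_scenario(n=400, seed=10)
        score = compute_allele_score(genotypes)
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(60):
            perm = pd.Series(
                rng.permutation(score.to_numpy()), index=score.index
            )
            res = global_lrt_assoc(cohort, REDUCED_SPEC, perm, engine="lmm")
            pvals.append(res.lrt_p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_unknown_engine(self):
        with pytest.raises(ValueError):
            global_lrt_assoc(None, REDUCED_SPEC, pd.Series(dtype=float), engine="gam")


class TestSitarParamAssoc:
    def _params_frame(self, rng, score, tempo_slope=0.0):
        n = len(score)
        return pd.DataFrame(
            {
                "size": rng.normal(0, 0.1, n),
                "tempo": tempo_slope * score.to_numpy() + rng.normal(0, 0.03, n),
                "velocity": rng.normal(0, 0.1, n),
            },
            index=score.index,
        )

    def test_independent_g_null_slopes(self):
        rng = np.random.default_rng(12)
        score = pd.Series(rng.integers(10, 25, 400), index=range(400))
        table = self._params_frame(rng, score)
        out = sitar_param_assoc(table, score)
        assert (out["p"] > 0.001).all()
        assert np.abs(out["beta"]).max() < 0.01

    def test_injected_negative_tempo_slope_recovered(self):
        rng = np.random.default_rng(13)
        score = pd.Series(rng.integers(10, 25, 500), index=range(500))
        table = self._params_frame(rng, score, tempo_slope=-0.009)
        out = sitar_param_assoc(table, score)
        assert out.loc["tempo", "beta"] == pytest.approx(-0.009, abs=0.002)
        assert out.loc["tempo", "p"] < 1e-6

    def test_duplicating_subjects_same_slope_smaller_se(self):
        rng = np.random.default_rng(14)
        score = pd.Series(rng.integers(10, 25, 200), index=range(200))
        table = self._params_frame(rng, score, tempo_slope=-0.005)
        out1 = sitar_param_assoc(table, score)
        table2 = pd.concat([table, table.set_index(table.index + 1000)])
        score2 = pd.concat([score, score.set_axis(score.index + 1000)])
        out2 = sitar_param_assoc(table2, score2)
        assert out2.loc["tempo", "beta"] == pytest.approx(out1.loc["tempo", "beta"])
        assert out2.loc["tempo", "se"] < out1.loc["tempo", "se"]

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            sitar_param_assoc(
                pd.DataFrame({"size": [0.1], "tempo": [0.0], "velocity": [0.0]},
                             index=[1]),
                pd.Series([12], index=[1]),
            )


class TestPerAgeEffect:
    @pytest.fixture(scope="class")
    def fitted(self):
        cohort, genotypes = reduced_scenario(
            n=300, seed=15, score_effects={"level": 0.005, "slope": 0.001}
        )
        score = compute_allele_score(genotypes)
        return global_lrt_assoc(cohort, REDUCED_SPEC, score, engine="lmm")

    def test_effect_at_centre_equals_main_coefficient(self, fitted):
        out = per_age_effect(fitted.fit_full, [8.0])
        assert out["effect"].iloc[0] == fitted.terms.loc["score", "beta"]
        assert out["se"].iloc[0] == pytest.approx(fitted.terms.loc["score", "se"])

    def test_effect_polynomial_evaluation(self, fitted):
        gnames = ["score", "score*a", "score*a^2", "score*a^3"]
        coefs = fitted.fit_full.params[gnames].to_numpy()
        out = per_age_effect(fitted.fit_full, [3.0, 12.0])
        for age, eff in zip(out["age"], out["effect"]):
            a = age - 8.0
            assert eff == pytest.approx(np.polyval(coefs[::-1], a))

    def test_warns_outside_observed_range(self, fitted):
        with pytest.warns(UserWarning, match="outside"):
            per_age_effect(fitted.fit_full, [24.0])

    def test_missing_genetic_terms_rejected(self, fitted):
        with pytest.raises(ValueError, match="genetic"):
            per_age_effect(fitted.fit_null, [8.0])


def test_bonferroni_adjustment():
    adj, rej = bonferroni([0.001, 0.02, 0.5], alpha=0.05)
    np.testing.assert_allclose(adj, [0.003, 0.06, 1.0])
    assert list(rej) == [True, False, False]
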