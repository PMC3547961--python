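import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.integrate import quad

from bmigrowth.bases import BasisSpec, car1_correlation
from bmigrowth.cohort import Cohort
from bmigrowth.lmm import (
    GrowthLMM,
    ModelSpec,
    lrt_nested,
    preset_spec,
    select_spline_model,
)
from bmigrowth.simulate import SimulationConfig, TrueParams, simulate_bmi, simulate_schedule

from conftest import reduced_null_truth


def dense_loglik(res):
    """Independent oracle: per-subject dense multivariate-normal density."""
    gd = res.model.data
    beta = res.params.to_numpy()
    phi = res.phi if res.phi is not None else 0.0
    ll = 0.0
    for g in gd.groups:
        for i in range(g["m"]):
            C = car1_correlation(g["ages"][i], phi)
            V = g["Z"][i] @ res.G @ g["Z"][i].T + res.sigma2 * C
            ll += stats.multivariate_normal.logpdf(g["y"][i], g["X"][i] @ beta, V)
    return ll


@pytest.fixture(scope="module")
def reduced_fit(request):
    cfg = SimulationConfig(
        n_male=0, n_female=150,
        wave_ages=(1.0, 6.0, 10.0, 17.0),
        attendance=(1.0,) * 4,
        age_jitter_sd=(0.1, 0.2, 0.2, 0.25),
        seed=31,
    )
    sk = simulate_schedule(cfg)
    true = reduced_null_truth()
    cohort = simulate_bmi(sk, None, true, seed=32)
    spec = ModelSpec(scale="ln", fixed=true.basis, random="linear", error="independent")
    return cohort, true, GrowthLMM(cohort, spec).fit()


class TestFit:
    def test_noise_free_recovers_fixed_effects(self):
        cfg = SimulationConfig(n_male=0, n_female=40, seed=41,
                               attendance=(1.0,) * 8)
        sk = simulate_schedule(cfg)
        true = reduced_null_truth(G=np.zeros((2, 2)), sigma=1e-9)
        cohort = simulate_bmi(sk, None, true, seed=42)
        spec = ModelSpec(scale="ln", fixed=true.basis, random="linear", error="independent")
        res = GrowthLMM(cohort, spec).fit()
        np.testing.assert_allclose(
            res.params.to_numpy(), true.beta_female, rtol=1e-5, atol=1e-8
        )

    def test_loglik_matches_dense_oracle_independent(self, reduced_fit):
        _, _, res = reduced_fit
        assert abs(res.llf - dense_loglik(res)) < 1e-6

    def test_loglik_matches_dense_oracle_car1(self):
        cfg = SimulationConfig(n_male=0, n_female=20, seed=43, attendance=(1.0,) * 8)
        sk = simulate_schedule(cfg)
        true = reduced_null_truth(phi=0.6)
        cohort = simulate_bmi(sk, None, true, seed=44)
        spec = ModelSpec(scale="ln", fixed=true.basis, random="linear", error="car1")
        res = GrowthLMM(cohort, spec).fit()
        assert abs(res.llf - dense_loglik(res)) < 1e-6

    def test_matches_statsmodels_mixedlm(self):
        # independent-package oracle on well-conditioned data (8 visits,
        # sizeable random-slope variance keeps MixedLM off the boundary)
        sm = pytest.importorskip("statsmodels.api")
        cfg = SimulationConfig(n_male=0, n_female=120, seed=45, attendance=(1.0,) * 8)
        sk = simulate_schedule(cfg)
        true = reduced_null_truth(
            G=np.array([[0.02, 0.001], [0.001, 0.0016]]), sigma=0.05
        )
        cohort = simulate_bmi(sk, None, true, seed=46)
        spec = ModelSpec(scale="ln", fixed=true.basis, random="linear",
                         error="independent")
        res = GrowthLMM(cohort, spec).fit()
        d = cohort.df.copy()
        d["y"] = np.log(d["bmi"])
        d["a"] = d["age_years"] - 8.0
        d["a2"] = d["a"] ** 2
        d["a3"] = d["a"] ** 3
        mf = sm.MixedLM.from_formula(
            "y ~ a + a2 + a3", groups="subject_id", re_formula="~a", data=d
        ).fit(reml=False)
        assert abs(mf.llf - res.llf) < 1e-3
        np.testing.assert_allclose(res.params.to_numpy(), mf.fe_params.values, atol=1e-5)

    def test_estimates_invariant_to_subject_relabeling(self, reduced_fit):
        cohort, true, res = reduced_fit
        relabeled = cohort.df.copy()
        relabeled["subject_id"] = relabeled["subject_id"].map(
            lambda s: f"zz{1000 - s}"
        )
        spec = res.model.spec
        res2 = GrowthLMM(Cohort(relabeled), spec).fit()
        np.testing.assert_allclose(res2.params.to_numpy(), res.params.to_numpy(), atol=1e-6)
        assert abs(res2.llf - res.llf) < 1e-5

    def test_quad_and_quad_half_random_designs_equivalent(self, small_female_cohort):
        cohort, _, _ = small_female_cohort
        base = preset_spec("splmm")
        res_half = GrowthLMM(cohort, base).fit()
        from dataclasses import replace

        # start the unscaled fit from the mapped optimum: Z_half = Z_quad S
        # with S = diag(1, 1, 0.5), so Gamma_quad = S Gamma_half S
        S = np.diag([1.0, 1.0, 0.5])
        res_full = GrowthLMM(cohort, replace(base, random="quad")).fit(
            start_params=(S @ res_half._ml.Gamma @ S, 0.0)
        )
        assert abs(res_half.llf - res_full.llf) < 1e-4
        # agreement to optimizer tolerance (finite-difference gradients)
        np.testing.assert_allclose(
            res_half.params.to_numpy(), res_full.params.to_numpy(), atol=5e-5
        )
        np.testing.assert_allclose(S @ res_half.G @ S, res_full.G, rtol=0.02, atol=1e-8)

    def test_singular_design_names_collinear_columns(self, reduced_fit):
        cohort, true, _ = reduced_fit
        # duplicated age column via covariates
        dup = pd.DataFrame(index=pd.Index(cohort.subjects))
        dup["dup_const"] = 1.0
        spec = ModelSpec(scale="ln", fixed=true.basis, random="linear",
                         error="independent", covariates=dup)
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            GrowthLMM(cohort, spec)

    def test_too_few_subjects_rejected(self):
        one = pd.DataFrame(
            {
                "subject_id": ["s1"] * 8,
                "sex": ["F"] * 8,
                "age_years": [1, 2, 3, 6, 8, 10, 14, 17.0],
                "bmi": [17, 16, 16, 15.9, 17, 18.7, 21.7, 23.2],
            }
        )
        with pytest.raises(ValueError, match="subjects"):
            GrowthLMM(Cohort(one), preset_spec("splmm")).fit()

    def test_rank_deficient_design_names_columns(self, tiny_visits):
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            GrowthLMM(Cohort(tiny_visits), preset_spec("splmm"))


class TestPredictionAndBlup:
    def test_zero_random_effects_subject_equals_population(self, reduced_fit):
        _, _, res = reduced_fit
        ages = np.array([2.0, 8.0, 15.0])
        pop = res.predict(ages, level="population")
        u = res.random_effects
        nearest = (u.abs().sum(axis=1)).idxmin()
        subj = res.predict(ages, level="subject", subject=nearest)
        np.testing.assert_allclose(subj - pop, u.loc[nearest, "u_const"]
                                   + u.loc[nearest, "u_a"] * (ages - 8.0), atol=1e-10)

    def test_ln_scale_exponentiates_on_request(self, reduced_fit):
        _, _, res = reduced_fit
        ages = np.array([5.0, 10.0])
        np.testing.assert_allclose(
            res.predict(ages, response_scale="bmi"), np.exp(res.predict(ages))
        )

    def test_extrapolation_warns(self, reduced_fit):
        _, _, res = reduced_fit
        with pytest.warns(UserWarning, match="observed age range"):
            res.predict([24.0])

    def test_single_visit_blup_shrinkage(self):
        # closed form: for one observation, u = G z (zGz' + s2)^{-1} r, so the
        # subject prediction lies strictly between observation and population
        cfg = SimulationConfig(n_male=0, n_female=120,
                               wave_ages=(1.0, 6.0, 10.0, 17.0),
                               attendance=(1.0,) * 4,
                               age_jitter_sd=(0.1, 0.2, 0.2, 0.25), seed=61)
        sk = simulate_schedule(cfg)
        # make subject 0 a single-visit subject
        sk = pd.concat([sk[sk.subject_id == 0].iloc[[0]], sk[sk.subject_id != 0]])
        true = reduced_null_truth()
        cohort = simulate_bmi(sk.reset_index(drop=True), None, true, seed=62)
        spec = ModelSpec(scale="ln", fixed=true.basis, random="linear", error="independent")
        res = GrowthLMM(cohort, spec).fit()
        row = cohort.df[cohort.df.subject_id == 0].iloc[0]
        age, yobs = row["age_years"], np.log(row["bmi"])
        pop = res.predict([age])[0]
        fit_subj = res.predict([age], level="subject", subject=0)[0]
        lo, hi = sorted([pop, yobs])
        assert lo < fit_subj < hi
        # closed-form check of the shrinkage factor
        z = np.array([1.0, age - 8.0])
        lam = float(z @ res.G @ z / (z @ res.G @ z + res.sigma2))
        assert fit_subj - pop == pytest.approx(lam * (yobs - pop), rel=1e-6)


class TestLRT:
    def test_identical_models_statistic_zero(self, reduced_fit):
        _, _, res = reduced_fit
        stat, df, p = lrt_nested(res, res)
        assert stat == 0 and p == 1.0

    def test_chi2_tail_against_quadrature(self):
        # oracle: numerically integrate the chi^2_4 density
        tail, _ = quad(lambda x: stats.chi2.pdf(x, 4), 9.49, np.inf)
        assert stats.chi2.sf(9.49, 4) == pytest.approx(tail, rel=1e-8)
        assert tail == pytest.approx(0.0499, abs=2e-4)

    def test_non_nested_rejected(self, reduced_fit):
        cohort, true, res = reduced_fit
        spec2 = ModelSpec(
            scale="ln",
            fixed=BasisSpec(kind="truncated_power_cubic", knots=(6.0,), center=8.0),
            random="linear", error="independent",
        )
        res2 = GrowthLMM(cohort, spec2).fit()
        with pytest.raises(ValueError, match="not nested"):
            lrt_nested(res, res2)

    def test_likelihood_nondecreasing_with_added_knot(self, reduced_fit):
        cohort, true, res_null = reduced_fit
        spec_full = ModelSpec(
            scale="ln",
            fixed=BasisSpec(kind="truncated_power_cubic", knots=(6.0,), center=8.0),
            random="linear", error="independent",
        )
        res_full = GrowthLMM(cohort, spec_full).fit()
        stat, df, p = lrt_nested(res_full, res_null)
        assert stat >= 0
        assert df == 1


class TestModelSelection:
    def test_single_candidate_returned(self, reduced_fit):
        cohort, _, _ = reduced_fit
        spec, table = select_spline_model(
            cohort, [(2.0, 8.0, 12.0)],
            base_spec=ModelSpec(scale="ln",
                                fixed=BasisSpec(kind="truncated_power_cubic",
                                                knots=(2, 8, 12), center=8.0),
                                random="linear", error="independent"),
        )
        assert spec.fixed.knots == (2.0, 8.0, 12.0)
        assert len(table) == 1

    def test_aic_identity(self, small_female_cohort):
        cohort, _, _ = small_female_cohort
        _, table = select_spline_model(cohort, [(2, 8, 12), (3, 8, 12)])
        for _, row in table.iterrows():
            assert row["aic"] == pytest.approx(-2 * row["llf"] + 2 * row["k"])

    def test_returns_aic_argmin(self, small_female_cohort):
        cohort, _, _ = small_female_cohort
        best, table = select_spline_model(
            cohort, [(2, 8, 12), (4.5, 9.5, 14.5), (3, 5, 7)]
        )
        winner = table.loc[table["aic"].idxmin(), "knots"]
        assert best.fixed.knots == tuple(float(k) for k in winner)

    def test_knots_beat_plain_cubic_on_spline_data(self, default_cohort):
        # full-size stratum generated from the knotted spline curve: the
        # knotted model must beat the knot-free cubic decisively
        cohort, _, _ = default_cohort
        from bmigrowth.cohort import stratify_by_sex

        _, female = stratify_by_sex(cohort)
        best, table = select_spline_model(female, [(2, 8, 12), ()])
        assert best.fixed.knots == (2.0, 8.0, 12.0)
        aics = dict(zip(table["knots"], table["aic"]))
        assert aics[(2.0, 8.0, 12.0)] < aics[()] - 5

    def test_empty_candidates_rejected(self, small_female_cohort):
        cohort, _, _ = small_female_cohort
        with pytest.raises(ValueError):
            select_spline_model(cohort, [])


class TestDiagnostics:
    def test_perfect_fit_zero_residuals(self):
        cfg = SimulationConfig(n_male=0, n_female=30, seed=71, attendance=(1.0,) * 8)
        sk = simulate_schedule(cfg)
        true = reduced_null_truth(G=np.zeros((2, 2)), sigma=1e-9)
        cohort = simulate_bmi(sk, None, true, seed=72)
        spec = ModelSpec(scale="ln", fixed=true.basis, random="linear", error="independent")
        res = GrowthLMM(cohort, spec).fit()
        assert np.max(np.abs(res.resid)) < 1e-6

    def test_gaussian_qq_within_band(self, reduced_fit):
        _, _, res = reduced_fit
        qq = res.diagnostics()["qq"]
        # simultaneous envelope via the DKW-type bound on uniforms
        n = len(qq)
        eps = np.sqrt(np.log(2 / 0.05) / (2 * n))
        u = stats.norm.cdf(qq["sample"])
        ecdf = (np.arange(1, n + 1) - 0.5) / n
        assert np.max(np.abs(u - ecdf)) < eps + 1 / n

    def test_heavy_tailed_errors_excess_tail_mass(self):
        cfg = SimulationConfig(n_male=0, n_female=400,
                               wave_ages=(1.0, 6.0, 10.0, 17.0),
                               attendance=(1.0,) * 4,
                               age_jitter_sd=(0.1,) * 4, seed=73)
        sk = simulate_schedule(cfg)
        true = reduced_null_truth(error="t", nu=3.0, G=np.zeros((2, 2)))
        cohort = simulate_bmi(sk, None, true, seed=74)
        spec = ModelSpec(scale="ln", fixed=true.basis, random="intercept",
                         error="independent")
        res = GrowthLMM(cohort, spec).fit()
        r = res.resid_std()
        frac_beyond_3 = np.mean(np.abs(r) > 3)
        assert frac_beyond_3 > 2 * (2 * stats.norm.sf(3))
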