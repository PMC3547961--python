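# bmigrowth

Longitudinal growth-curve models for childhood BMI and genetic
trajectory association.

Childhood BMI follows a characteristic non-linear course: a rapid rise to
an adiposity peak in infancy, a decline to the *adiposity rebound* around
age 5–6, then a steady increase through adolescence. Detecting the modest
effects of common obesity-risk variants on this trajectory requires
statistical models that capture the curve shape, the within-child
correlation of repeated measures, and the growing between-child
dispersion with age. `bmigrowth` implements four such models as
statsmodels-style `Model.fit() -> Results` pairs, a genetic association
layer, and a cluster-bootstrap comparison framework, together with a
synthetic-cohort generator that emulates an eight-wave pregnancy-cohort
follow-up design (visits near ages 1, 2, 3, 6, 8, 10, 14 and 17 years,
median 6 visits per child) so every stage is testable without access to
restricted cohort data.

## Models

For child *j* with BMI `y_jt` at age `t` (sex-stratified throughout,
age centred at 8 years):

- **LMM** (`GrowthLMM`, preset `lmm`) — `ln(BMI)` on a cubic age
  polynomial with quadratic random effects and continuous-AR(1)
  within-child correlation `corr(e_s, e_t) = phi^|s-t|`;
  `y_jt = Σ β_i a^i + Σ u_kj a^k + e_jt`, `u_j ~ N(0, G)`.
- **SPLMM** (`GrowthLMM`, preset `splmm`) — same engine with a cubic
  truncated-power spline `{1, a, a², a³, (t−κ)³₊}` with knots at 2, 8 and
  12 years and `(1, a, 0.5a²)` random effects.
- **STLMM** (`SkewTLMM`) — untransformed BMI; multivariate skew-normal
  random intercept/slope and multivariate-t errors sharing one mixing
  variable, giving a marginal skew-t response. Estimated by an exact
  closed-form EM (monotone in the observed log-likelihood), with the t
  degrees of freedom profiled on a log grid.
- **SITAR / NLMM** (`SITAR`) — `ln BMI = α_j + h((ln age − β_j) e^{γ_j})`
  with `h` a shared natural cubic spline (df 3–8 chosen by AIC): each
  child differs from the common curve by *size* (α), *tempo* (β) and
  *velocity* (γ). Fitted by Lindstrom–Bates alternating linearization.

All models use maximum likelihood (not REML) so log-likelihoods, AIC and
likelihood-ratio tests are comparable across methods.

Genetic association (`bmigrowth.assoc`) codes each SNP additively
(risk-allele dosage 0/1/2) or as an unweighted 17-locus allele score, adds
fixed terms `g, g·a, g·a², g·a³` to the chosen model, and tests them
jointly by a 4-df global likelihood-ratio test; for SITAR, dosage is
regressed on the per-child size/tempo/velocity predictions (three tests
per SNP). `bmigrowth.compare` provides subject-level `R²`,
cluster-bootstrap `R²` distributions, squared-error summaries, detection
tallies and non-parametric bootstrap power.

## Worked example

```python
import numpy as np
from bmigrowth import (make_scenario, stratify_by_sex, compute_allele_score,
                       preset_spec, global_lrt_assoc, per_age_effect)

# synthetic cohort of 1,506 children with per-allele effects on level
# (0.0049 ln-units) and slope (0.0012 ln-units/yr) injected via the score
cohort, genotypes, truth = make_scenario("allele_score", seed=42)
(male, gm), (female, gf) = stratify_by_sex(cohort, genotypes)

score = compute_allele_score(gf)          # complete-case 17-locus score
res = global_lrt_assoc(female, preset_spec("splmm"), score, engine="splmm")
print(res.terms[["beta", "se", "p"]])
print(f"global LRT: stat={res.lrt_stat:.1f}, df={res.lrt_df}, p={res.lrt_p:.2e}")
print(per_age_effect(res.fit_full, [1, 8, 17]).round(4))
```

which prints (machine output, seed 42):

```
               beta        se         p
score      0.005904  0.001673  0.000418
score*a    0.001177  0.000280  0.000026
score*a^2 -0.000035  0.000021  0.100044
score*a^3  0.000004  0.000003  0.210330
global LRT: stat=34.0, df=4, p=7.29e-07
    age  effect      se  ci_low  ci_high
0   1.0 -0.0054  0.0020 -0.0092  -0.0015
1   8.0  0.0059  0.0017  0.0026   0.0092
2  17.0  0.0164  0.0036  0.0092   0.0235
```

The `score` row is the per-allele effect on mean ln(BMI) at the centring
age (8 years) — each extra risk allele raises BMI by ≈0.6%; the `score*a`
row is the per-allele change in annual slope. Both estimates sit within
one standard error of the injected truths (0.0049 and 0.0012). The
per-age table shows the effect emerging with age: slightly negative at
age 1, ≈1.6% of BMI by age 17.

A command-line interface mirrors the library:

```sh
bmigrowth simulate --scenario allele_score --n 1506 --seed 42 --out data/
bmigrowth fit --model splmm --sex female --cohort data/visits.csv
bmigrowth assoc --engine splmm --sex female --cohort data/visits.csv \
    --genotypes data/genotypes.csv
bmigrowth compare --engines lmm,splmm --sex female --cohort data/visits.csv
```

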