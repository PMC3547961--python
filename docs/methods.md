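# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices and the known limitations of `bmigrowth`.

## The modelling problem

Repeated childhood BMI measures are non-linear in age (adiposity peak in
infancy, rebound near 5–6 years, adolescent rise), within-child
correlated, increasingly dispersed with age, and right-skewed at older
ages. Genetic effects of interest are small (fractions of a percent of
BMI per allele), so the question of which growth model best supports
their detection is substantive. The package implements four candidate
models behind a common interface and the machinery to compare them.
All analyses are sex-stratified (growth differs qualitatively between
boys and girls) and age is centred at 8 years — a fixed constant, close
to the mean follow-up age of the emulated design, rather than each
stratum's realized mean, so estimates are comparable across strata and
across simulated cohorts. All models are fitted by maximum likelihood,
never REML, so log-likelihoods, AIC and LRTs are comparable across
methods with different fixed-effect structures.

## Gaussian mixed models (LMM and SPLMM)

One engine (`bmigrowth._mle`) covers both: per-subject response
`y_j ~ N(X_j beta, Z_j G Z_j' + sigma^2 C_j(phi))` where `C_j` is either
the identity or the continuous-AR(1) kernel `phi^|age_s - age_t|` with
gaps in raw years. The likelihood is profiled: for fixed variance-ratio
parameters (`Gamma = G/sigma^2`, Cholesky-parameterized with log
diagonal; `phi` on a logit scale), GLS gives `beta` and `sigma^2` in
closed form, leaving a 3–7 dimensional smooth optimization (L-BFGS-B,
relative tolerance 1e-8, up to 3 jittered restarts, then a capped
Nelder-Mead polish for boundary cases where the line search ends
abnormally — e.g. a random-effect variance estimated at zero).
Subjects are batched by visit count so all per-subject linear algebra is
stacked; with 8 follow-up waves there are at most 8 batches regardless
of cohort size, making a full ML fit at n=1,500 take ~1 s. Subjects with
a single visit contribute through their marginal variance and are never
dropped. Every converged fit's stored log-likelihood is verified in the
test-suite against an independent dense multivariate-normal evaluation
(tolerance 1e-6) and, for the independent-error case, against
statsmodels' MixedLM.

Model presets follow the selected specifications: the polynomial LMM
uses ln(BMI), cubic fixed age, quadratic random age and CAR(1) errors;
the spline SPLMM uses ln(BMI), a cubic truncated-power basis
`{1, a, a^2, a^3, (t-kappa)^3_+}` with knots at 2, 8 and 12 years
(knots quoted, and applied, on the raw age scale; only the polynomial
columns are centred), random effects `(1, a, 0.5 a^2)` and independent
errors. The 0.5-scaled quadratic changes only the parameterization of
`G`; a unit test verifies the fit is identical to the unscaled version.
A truncated *linear* basis is available (`truncated_power_basis(...,
power=1)`) but the cubic is the default, matching the selected
"piecewise cubic" specification. Knot and polynomial-degree selection
use AIC with ties broken toward fewer parameters
(`select_spline_model`); candidates that fail to converge are recorded
and skipped.

## Skew-t mixed model (STLMM)

Untransformed BMI; the skewness and heavy tails of the response are
carried by the error law instead of a transformation. Hierarchically,
with one `Gamma(nu/2, nu/2)` mixing variable `u_j` per subject and a
half-normal `t_j`:

    b_j | t_j, u_j ~ N(Delta t_j, Gamma_b / u_j)
    y_j | b_j, u_j ~ N(X_j beta + Z_j b_j, sigma^2 I / u_j)

so the random-effect scale matrix is `D = Gamma_b + Delta Delta'`, the
marginal response is multivariate skew-t, and the skewness vector is
`lambda = D^{-1/2} Delta / sqrt(1 - Delta' D^{-1} Delta)` (one entry per
random effect; the random design is intercept + linear age, the
specification that is estimable in practice — richer random structures
fail to converge). Errors are symmetric-t; skewness enters only through
the random effects. CAR(1) is not combined with the skew-t law.

Estimation is EM with exact closed-form E-steps: the conditional
moments `E[u|y]`, `E[ut|y]`, `E[ut^2|y]` reduce to Student-t CDF ratios
and gamma-function factors (the univariate truncation is handled
analytically; no Monte Carlo), and the `b`-moments follow from the
Gaussian conditional given `(t, u)`. These formulas were validated
against weighted Monte-Carlo draws during development, and the marginal
density integrates to 1 on a grid in the test-suite. CM-steps update
`beta, sigma^2, Delta, Gamma_b` in closed form; `nu` is an ECME step
(coarse log grid on (2, 200] refined by bounded golden-section) every 5
iterations, with a config override to fix it. The observed-data
log-likelihood is asserted non-decreasing at every iteration — a
decrease beyond numerical tolerance raises, because with exact E/M steps
it can only be a bug. Convergence: relative change < 1e-6, cap 2,000
iterations, flagged (never silent) on failure; initialization from the
Gaussian fit with a moderate positive skew split (`Delta_0 = 0.3
sqrt(diag G)`).

Because the skew-normal random effect has non-zero mean
`E[b] = Delta sqrt(nu/pi) Gamma((nu-1)/2)/Gamma(nu/2)`, the raw fixed
intercept/slope are confounded with skewness. Reported fixed effects
(`params`) fold this mean in, so population curves and the genetic terms
are comparable across methods; `params_raw` keeps the unshifted values.
Standard errors come from the numerically differentiated observed
information with a delta-method transform for `lambda`. Standardized
residuals use each visit's marginal univariate skew-t law, with
theoretical quantiles from the pooled-shape fitted law (grid-quadrature
CDF/quantile; the skew-t has no closed-form CDF).

## SITAR

`ln BMI_it = mu + alpha_i + h((x_it - beta_i) exp(gamma_0 + gamma_i))`
where `x = ln(age)` centred at its mean and `h` is a natural cubic
spline (boundary knots at the 2.5th/97.5th percentiles of `x`, interior
knots at equally-spaced quantiles; df 3–8 columns). Centring the
transformed age is essential: the velocity stretch then pivots mid-range
instead of at age 1, which otherwise makes tempo and velocity nearly
collinear (verified during development — without centring, tempo
predictions collapse). Fixed effects are size (`mu`) and velocity
(`gamma_0`); a fixed tempo shift is absorbed by `h` and therefore not
identified separately. Random effects `(alpha, beta, gamma)` have an
unstructured covariance. Because age is ln-transformed, the tempo shift
`beta_i` is additive in ln(age), i.e. multiplicative in age — a child
with `beta_i = 0.05` hits each growth landmark about 5% later in age.

Estimation is the Lindstrom–Bates alternating scheme: linearize about
the current random-effect predictions, fit the resulting LMM by ML with
the shared engine (warm-started variance parameters), update predictions
(BLUPs) and fixed parameters with an adaptive relaxation factor (halved
when the linearized log-likelihood oscillates), and stop at relative
change < 1e-7, a <0.05-unit plateau over six iterations, or 80 outer
iterations. The reported log-likelihood is the linearized
(Laplace-type) value; on a 30-subject toy it agrees with a mode-centred
adaptive Gauss–Hermite evaluation of the exact marginal likelihood to
well under 0.5 units (test-suite oracle). Deviance = −2·logLik; AIC
counts fixed (2 + df), covariance (6) and residual (1) parameters.
`choose_sitar_df` compares df 3–8 by AIC and reports deviance and
residual SD per candidate. Residuals are conditionally independent; a
CAR(1) residual option is deliberately not implemented for SITAR (the
standard formulation, and the only one exercised downstream, uses
independent residuals).

## Genetic association

Dosage is the risk-allele count 0/1/2; the allele score is the
unweighted sum over the 17-locus panel, computed on complete cases only
(subjects missing any locus are excluded from score analyses; subjects
missing a given SNP are excluded from that SNP's single-SNP analysis —
never imputed). Genetic fixed effects are `g, g·a, g·a^2, g·a^3` with
`a` centred age — polynomial interactions even under a spline base
trend, so the interaction structure (and its 4-df global LRT) is
identical across engines; interacting `g` with spline columns is
deliberately not done. The global LRT compares full vs genetics-free
fits on the identical complete-case subjects, with the full fit
warm-started from the null's variance parameters; df = number of added
columns (4 by default). Per-term Wald summaries and delta-method
per-age effect curves (`effect(a) = g + g1 a + g2 a^2 + g3 a^3`) come
from the fixed-effect covariance; at the centring age the per-age effect
equals the main-effect coefficient exactly. For SITAR, association is
three ordinary regressions (size, tempo, velocity on dosage), so a
17-SNP scan has 51 tests. No multiple-testing adjustment is applied by
default (the loci are pre-validated candidates); a Bonferroni helper
exists. Principal components or other per-subject covariates can enter
as extra fixed columns (`ModelSpec.covariates`); their computation is
out of scope.

## Model comparison and bootstrap

`R^2 = 1 - SSE/SST` uses subject-level fitted values (fixed effects plus
predicted random effects) on the model's response scale; population-level
fitted values cannot reach the 80–90% range these models attain on BMI
panels because most BMI variance is between children (a population-level
variant exists behind a flag). Bootstrap resampling draws subjects (whole
visit blocks) with replacement — the valid unit for clustered
longitudinal data — re-fits the frozen specification (no knot/df
reselection per replicate), and reports the median and IQR of `R^2`;
non-convergent replicates are excluded with their rate reported, and a
failure rate above 20% flags the summary unusable. Power is the fraction
of subject-resampled datasets with a significant global LRT, with a
binomial CI. Wall-clock time per fit is recorded as metadata but never
asserted.

## Synthetic cohorts

The generator produces the structure the analyses assume, with defaults
calibrated to a well-known eight-wave pregnancy cohort (n = 1,506; 773
boys, 733 girls):

- **Schedule**: waves at nominal ages 1, 2, 3, 6, 8, 10, 14, 17 years;
  per-wave attendance (0.913, 0.267, 0.660, 0.879, 0.876, 0.846, 0.847,
  0.678) derived from wave sample sizes, giving a median of 6 visits per
  child (IQR 5–7); per-wave age jitter SDs 0.10–0.35 years; every child
  attends at least one wave (all-miss draws are redrawn).
- **Mean curves**: sex-specific ln(BMI) curves built by projecting a
  shape-preserving (PCHIP) interpolant through calibration anchors onto
  the truncated-power basis. Anchors follow the large-wave BMI means
  (≈17.1 kg/m² at age 1, minimum ≈15.8–16.0 at rebound, ≈23 at 17) with
  the sparse year-2 wave (27% attendance, whose raw mean is inconsistent
  with a single rebound) replaced by a smooth-descent anchor; girls
  rebound earlier (~4.6 y) than boys (~5.3 y). These are calibration
  constants, not estimates.
- **Random effects**: default `G` for `(1, a, 0.5a^2)` has intercept SD
  0.10 ln-units, slope SD 0.015 /yr, curvature SD 0.0022, intercept-slope
  correlation 0.5 — reproducing the rise of between-child dispersion from
  ≈8% of BMI at age 1 to ≈19% at 17. Residual SD 0.04 ln-units.
- **Error families**: Gaussian; multivariate-t and skew-t via the exact
  stochastic representation (half-normal × Cholesky Gaussian ÷
  sqrt-Gamma, one mixing draw per subject) so the skew-t density the
  STLMM implements can be validated against draws. CAR(1) noise is drawn
  exactly from the per-subject joint covariance (Cholesky of
  `sigma^2 phi^|dt|`), not by AR recursion, because visit ages are
  irregular.
- **Genotypes**: 17 independent loci in Hardy–Weinberg equilibrium,
  dosage ~ Binomial(2, risk-allele frequency). MAFs for FTO (0.41), MC4R
  (0.23), NEGR1 (0.38) and BDNF rs1488830 (0.21) follow published
  values; the remainder are plausible published frequencies, with the
  risk allele set to the major allele at roughly half the loci so the
  score distribution centres near 17 of 34 with quartiles near 15/17/18.
  Per-dosage missingness 1.25% leaves ≈81% of subjects complete-case.
  Linkage disequilibrium between loci is not simulated.
- **Scenarios**: `null` (no genetic effects), `single_snp` (FTO only),
  `allele_score` (per-allele level 0.0049 / slope 0.0012 ln-units for
  girls, 0.0071 / 0.0008 for boys — the order of magnitude reported for
  17-locus obesity scores). Effects are injected through the *underlying*
  complete genotypes; observational missingness is masked afterwards.
- **SITAR generator**: `simulate_sitar_cohort` draws size/tempo/velocity
  (default SDs 0.1, 0.05, 0.1) around an `h` calibrated to the female
  mean curve on centred ln(age). Its residual SD defaults to 0.005
  ln-units: data generated exactly from the model leave only measurement
  error (clinic weight/height precision ≈0.1 kg/0.1 cm ≈ 0.004
  ln-units), unlike real-cohort residuals (~0.02–0.04) which also absorb
  lack of fit.

What passing tests on these cohorts do and do not show: they demonstrate
correctness of the estimators and tests *under the assumed generative
models* (calibrated type-I error, unbiased recovery, consistent model
selection). They do not establish robustness to features real cohorts
have and the generator omits: informative missingness, measurement
batch effects, relatedness/population structure, LD between loci, or
mean-model misspecification.

## Problem sizes and test design

The statistical acceptance checks run at the sizes that make their
claims meaningful while keeping the suite desk-scale: likelihood-oracle
agreement on 50 random small instances; allele-score recovery over 50
cohorts of 1,500 girls; type-I calibration over 1,000 null cohorts of
500 children on a reduced 4-wave schedule; skew-t recovery at n = 1,500
with truth `lambda = (4.58, 2.23)`, `nu = 8`; SITAR recovery at
n = 1,000 and df-selection over 20 cohorts of 250; bootstrap consistency
at B = 200. The acceptance script uses one 1,000-girl stratum, 300 null
simulations and B = 40–50 bootstrap replicates; B = 1,000 runs are
available through the CLI.

## Known limitations

- The SPLMM treats spline terms as unpenalized fixed effects with knots
  chosen by AIC; no penalized smoothing-parameter selection.
- The STLMM's `nu` profile is bounded at 200; beyond that the model is
  numerically Gaussian-t-indistinguishable. STLMM coefficients are on
  the raw-BMI scale and are not rescaled for comparison with ln-scale
  methods.
- SITAR's log-likelihood is the linearized approximation; exact
  adaptive-quadrature ML is implemented only as a test oracle.
- The EM's convergence is linear; very tight tolerances can take
  thousands of iterations (the method is by far the slowest of the
  four, consistent with its reputation).
- Bootstrap refits freeze the selected specification; uncertainty from
  knot/df selection is not propagated.
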