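"""Allele-score construction and genetic trajectory association.

A SNP dosage or an unweighted risk-allele score enters a growth model's
fixed design as ``g, g*a, g*a^2, g*a^3`` (``a`` = centred age, polynomial
interactions regardless of whether the base time trend is polynomial or
spline), and association is judged by the global likelihood-ratio test of
all added terms jointly against the genetics-free nested model.  For the
SITAR model, association runs as three ordinary regressions of the
per-subject size/tempo/velocity predictions on dosage.  Per-age effect
curves (the effect of one extra risk allele on the mean response at each
follow-up age) come from the fitted interaction polynomial with
delta-method confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import Cohort, GenotypeTable, SnpInfo
from .lmm import GeneticTerms, GrowthLMM, GrowthLMMResults, ModelSpec, lrt_nested

__all__ = [
    "compute_allele_score",
    "add_genetic_terms",
    "AssocResult",
    "global_lrt_assoc",
    "sitar_param_assoc",
    "per_age_effect",
    "bonferroni",
]


def compute_allele_score(genotypes: GenotypeTable, loci=None) -> pd.Series:
    """Unweighted risk-allele score: sum of dosages over the loci.

    Only complete-case subjects (no missing dosage at any locus) are
    returned; the score for L loci lies in [0, 2L].
    """
    if loci is None:
        ids = genotypes.snp_ids
    else:
        ids = [s.snp_id if isinstance(s, SnpInfo) else str(s) for s in loci]
        absent = [s for s in ids if s not in genotypes.snp_ids]
        if absent:
            raise KeyError(f"loci absent from genotype table: {absent}")
    sub = genotypes.df[ids]
    complete = sub.notna().all(axis=1)
    score = sub.loc[complete].sum(axis=1).astype(int)
    score.name = "allele_score"
    return score


def add_genetic_terms(
    spec: ModelSpec, g: pd.Series, name: str = "score", interactions: int = 3
) -> ModelSpec:
    """Augment a model specification with additive genetic fixed effects.

    Adds ``interactions + 1`` columns (main effect plus age interactions
    up to the given degree).  A constant ``g`` raises at design-build
    time (the columns would be collinear with the time basis).
    """
    return spec.with_genetic(GeneticTerms(values=g, name=name, interactions=interactions))


@dataclass
class AssocResult:
    """Genetic association result for one SNP/score in one stratum.

    ``terms``: per-term estimates, SEs, Wald 95% CIs and p-values.
    ``lrt_stat``/``lrt_df``/``lrt_p``: the global likelihood-ratio test of
    all genetic terms jointly (df = number of added columns).  When either
    fit failed to converge the result is flagged and carries no p-value.
    """

    method: str
    name: str
    terms: pd.DataFrame
    lrt_stat: float | None
    lrt_df: int | None
    lrt_p: float | None
    converged: bool
    llf_full: float = np.nan
    llf_null: float = np.nan
    fit_full: object = field(default=None, repr=False)
    fit_null: object = field(default=None, repr=False)

    @property
    def significant(self) -> bool:
        return self.converged and self.lrt_p is not None and self.lrt_p < 0.05


def _wald_terms(params, bse, names) -> pd.DataFrame:
    est = params[names]
    se = bse[names]
    z = est / se
    return pd.DataFrame(
        {
            "beta": est,
            "se": se,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
            "p": 2 * stats.norm.sf(np.abs(z)),
        }
    )


def global_lrt_assoc(
    cohort: Cohort,
    base_spec: ModelSpec,
    g: pd.Series,
    engine: str = "splmm",
    name: str = "score",
    interactions: int = 3,
    **fit_kw,
) -> AssocResult:
    """Fit null (no genetic terms) and full models, return the global LRT.

    ``engine``: "lmm"/"splmm" (Gaussian ML; the two differ only through
    ``base_spec``) or "stlmm" (skew-t EM).  Subjects with missing ``g``
    are excluded from both fits so the test compares identical data.
    """
    if engine not in ("lmm", "splmm", "stlmm"):
        raise ValueError(f"unknown engine {engine!r}")
    have = g.dropna()
    stratum = cohort.subset(have.index)
    full_spec = add_genetic_terms(base_spec.drop_genetic(), have, name, interactions)
    null_spec = base_spec.drop_genetic()

    if engine == "stlmm":
        from .skewt import SkewTLMM

        fit_null = SkewTLMM(stratum, null_spec).fit(compute_se=False, **fit_kw)
        fit_full = SkewTLMM(stratum, full_spec).fit(compute_se=True, **fit_kw)
        converged = fit_null.converged and fit_full.converged
        gnames = full_spec.genetic.column_names()
        terms = _wald_terms(fit_full.params, fit_full.bse, gnames)
        if not converged:
            return AssocResult("stlmm", name, terms, None, None, None, False,
                               fit_full.llf, fit_null.llf, fit_full, fit_null)
        stat = max(2.0 * (fit_full.llf - fit_null.llf), 0.0)
        df = interactions + 1
        return AssocResult(
            "stlmm", name, terms, stat, df, float(stats.chi2.sf(stat, df)),
            True, fit_full.llf, fit_null.llf, fit_full, fit_null,
        )

    fit_null = GrowthLMM(stratum, null_spec).fit(**fit_kw)
    # warm-start the full fit from the null's variance parameters
    fit_full = GrowthLMM(stratum, full_spec).fit(
        start_params=(fit_null._ml.Gamma, fit_null._ml.phi), **fit_kw
    )
    converged = fit_null.converged and fit_full.converged
    gnames = full_spec.genetic.column_names()
    terms = _wald_terms(fit_full.params, fit_full.bse, gnames)
    if not converged:
        return AssocResult(engine, name, terms, None, None, None, False,
                           fit_full.llf, fit_null.llf, fit_full, fit_null)
    stat, df, p = lrt_nested(fit_full, fit_null)
    return AssocResult(engine, name, terms, stat, df, p, True,
                       fit_full.llf, fit_null.llf, fit_full, fit_null)


def _ols_slope(x: np.ndarray, yv: np.ndarray):
    """Simple regression slope with classic SE and t-based p-value."""
    n = len(x)
    X = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ coef
    dof = n - 2
    s2 = resid @ resid / dof
    covb = s2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(covb[1, 1])
    tstat = coef[1] / se
    return coef[1], se, 2 * stats.t.sf(abs(tstat), dof)


def sitar_param_assoc(subject_params: pd.DataFrame, g: pd.Series) -> pd.DataFrame:
    """Regress each SITAR subject parameter (size, tempo, velocity) on
    dosage; one ordinary regression per parameter (three tests per SNP)."""
    merged = subject_params.join(g.rename("g"), how="inner").dropna()
    if len(merged) < 3:
        raise ValueError("need at least 3 subjects with genotype and SITAR parameters")
    rows = {}
    for col in ("size", "tempo", "velocity"):
        slope, se, p = _ols_slope(merged["g"].to_numpy(float), merged[col].to_numpy())
        rows[col] = {"beta": slope, "se": se, "p": p}
    return pd.DataFrame(rows).T


def per_age_effect(result: GrowthLMMResults | object, ages, name: str = "score") -> pd.DataFrame:
    """Per-age effect of one extra risk allele with delta-method 95% CI.

    ``effect(a) = g + g1 a + g2 a^2 + g3 a^3`` at centred age ``a``; at the
    centring age the effect equals the main-effect coefficient exactly.
    """
    model = result.model
    spec = model.spec
    if spec.genetic is None:
        raise ValueError("fit has no genetic terms")
    gnames = spec.genetic.column_names()
    cov = result.cov_params().loc[gnames, gnames].to_numpy()
    coefs = result.params[gnames].to_numpy()
    ages = np.asarray(ages, float)
    lo_obs, hi_obs = model.meta["age_range"]
    if np.any(ages < lo_obs - 0.5) or np.any(ages > hi_obs + 0.5):
        import warnings

        warnings.warn("per-age effects requested outside the observed age range",
                      UserWarning, stacklevel=2)
    a = ages - spec.age_center
    C = np.vander(a, N=len(gnames), increasing=True)  # rows (1, a, a^2, ...)
    eff = C @ coefs
    var = np.einsum("nd,de,ne->n", C, cov, C)
    se = np.sqrt(np.maximum(var, 0))
    return pd.DataFrame(
        {
            "age": ages,
            "effect": eff,
            "se": se,
            "ci_low": eff - 1.959963984540054 * se,
            "ci_high": eff + 1.959963984540054 * se,
        }
    )


def bonferroni(pvalues, alpha: float = 0.05):
    """Bonferroni-adjusted p-values and rejections (off by default in the
    analysis pipeline: the loci are pre-validated candidates)."""
    p = np.asarray(pvalues, float)
    adj = np.minimum(p * len(p), 1.0)
    return adj, adj < alpha
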