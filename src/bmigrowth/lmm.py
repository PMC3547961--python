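"""Gaussian linear mixed growth models (polynomial LMM and spline SPLMM).

A :class:`GrowthLMM` is built from a :class:`~bmigrowth.cohort.Cohort`
stratum and a declarative :class:`ModelSpec`; ``fit()`` maximizes the
marginal likelihood (ML, never REML, so log-likelihoods are comparable
across the four modelling approaches) and returns a
:class:`GrowthLMMResults` carrying estimates, their covariance, the
random-effect covariance ``G``, residual variance, optional CAR(1)
parameter, fitted values at population and subject (BLUP) level, and
diagnostics.

The polynomial LMM and the semi-parametric spline LMM are the same engine
under two fixed-basis configurations; shipped presets reproduce the
selected specifications for each sex (ln(BMI); cubic age polynomial with
CAR(1) errors, or a cubic truncated-power spline with knots at 2, 8 and
12 years with independent errors and (1, a, 0.5 a^2) random effects).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._mle import GroupedData, MLFit, fit_ml, loglik_at
from .bases import RANDOM_KINDS, BasisSpec, random_design
from .cohort import Cohort

__all__ = [
    "ModelSpec",
    "GeneticTerms",
    "GrowthLMM",
    "GrowthLMMResults",
    "lrt_nested",
    "select_spline_model",
    "preset_spec",
]


@dataclass(frozen=True)
class GeneticTerms:
    """Additive genetic fixed-effect columns: ``g, g*a, ..., g*a^degree``
    with ``a`` centred age and ``g`` a per-subject dosage or allele score."""

    values: pd.Series  # subject_id -> g (NaN = missing; subject excluded)
    name: str = "score"
    interactions: int = 3

    def __post_init__(self):
        if not 0 <= self.interactions <= 3:
            raise ValueError("interaction degree must be 0..3")

    @property
    def n_columns(self) -> int:
        return self.interactions + 1

    def column_names(self):
        return [self.name] + [
            f"{self.name}*a^{d}" if d > 1 else f"{self.name}*a"
            for d in range(1, self.interactions + 1)
        ]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative mixed-model specification.

    ``scale``: response scale ("ln" fits ln(BMI), "raw" fits BMI).
    ``fixed``: time basis for the fixed effects.  ``random``: random-effect
    design kind ("intercept", "linear", "quad", "quad_half").  ``error``:
    within-subject residual structure ("independent" or "car1").
    """

    scale: str = "ln"
    fixed: BasisSpec = field(default_factory=lambda: BasisSpec(kind="polynomial", degree=3))
    random: str = "quad"
    error: str = "car1"
    age_center: float = 8.0
    genetic: GeneticTerms | None = None
    covariates: pd.DataFrame | None = None  # optional per-subject extras (e.g. PCs)

    def __post_init__(self):
        if self.scale not in ("ln", "raw"):
            raise ValueError("scale must be 'ln' or 'raw'")
        if self.random not in RANDOM_KINDS:
            raise ValueError(f"unknown random design {self.random!r}")
        if self.error not in ("independent", "car1"):
            raise ValueError("error must be 'independent' or 'car1'")

    def with_genetic(self, genetic: GeneticTerms) -> "ModelSpec":
        return replace(self, genetic=genetic)

    def drop_genetic(self) -> "ModelSpec":
        return replace(self, genetic=None)

    def fixed_names(self) -> list[str]:
        b = self.fixed
        if b.kind == "polynomial":
            names = ["const"] + [f"a^{d}" if d > 1 else "a" for d in range(1, b.degree + 1)]
        elif b.kind == "truncated_power_cubic":
            # polynomial part centred like the plain polynomial basis, so the
            # names match (spline models nest polynomial ones column-for-column)
            names = ["const", "a", "a^2", "a^3"] + [f"(t-{k:g})^3_+" for k in b.knots]
        else:
            names = ["const"] + [f"ns{j}" for j in range(1, b.df + 1)]
        if self.covariates is not None:
            names += list(self.covariates.columns)
        if self.genetic is not None:
            names += self.genetic.column_names()
        return names


def preset_spec(method: str, sex: str | None = None) -> ModelSpec:
    """Named model presets for the selected specification of each method.

    ``lmm``: ln(BMI), cubic polynomial fixed, quadratic random, CAR(1).
    ``splmm``: ln(BMI), cubic truncated-power spline with knots 2/8/12,
    (1, a, 0.5 a^2) random, independent errors.  ``stlmm``: raw BMI, cubic
    polynomial fixed, linear random, independent errors (fit with
    :class:`~bmigrowth.skewt.SkewTLMM`).  The specifications are identical
    for the two sexes (sex enters by stratified fitting).
    """
    if method == "lmm":
        return ModelSpec(
            scale="ln",
            fixed=BasisSpec(kind="polynomial", degree=3, center=8.0),
            random="quad",
            error="car1",
        )
    if method == "splmm":
        return ModelSpec(
            scale="ln",
            fixed=BasisSpec(kind="truncated_power_cubic", knots=(2.0, 8.0, 12.0), center=8.0),
            random="quad_half",
            error="independent",
        )
    if method == "stlmm":
        return ModelSpec(
            scale="raw",
            fixed=BasisSpec(kind="polynomial", degree=3, center=8.0),
            random="linear",
            error="independent",
        )
    raise ValueError(f"unknown preset {method!r}")


def _build_design(cohort: Cohort, spec: ModelSpec):
    """Shared design construction for the Gaussian and skew-t models.

    Returns (grouped_data, subject_ids, meta).  Subjects with missing
    genetic value are excluded (complete-case for the added terms).
    """
    df = cohort.df
    if spec.genetic is not None:
        g = spec.genetic.values
        have = df["subject_id"].map(g).notna()
        n_dropped = df.loc[~have, "subject_id"].nunique()
        df = df.loc[have]
        if df["subject_id"].nunique() < 3:
            raise ValueError("fewer than 3 subjects with genetic data")
    else:
        n_dropped = 0

    ages = df["age_years"].to_numpy()
    y = df["bmi"].to_numpy()
    if spec.scale == "ln":
        y = np.log(y)
    X = spec.fixed.build(ages)
    if spec.covariates is not None:
        cov = spec.covariates.reindex(df["subject_id"]).to_numpy(dtype=float)
        if np.isnan(cov).any():
            raise ValueError("covariates missing for some subjects")
        X = np.column_stack([X, cov])
    if spec.genetic is not None:
        gvis = df["subject_id"].map(spec.genetic.values).to_numpy(dtype=float)
        if np.nanstd(gvis) == 0:
            raise ValueError(
                f"genetic term {spec.genetic.name!r} is constant; columns would be collinear"
            )
        a = ages - spec.age_center
        for d in range(spec.genetic.interactions + 1):
            X = np.column_stack([X, gvis * a**d])
    Z = random_design(ages, spec.random, spec.age_center)
    codes, subject_ids = pd.factorize(df["subject_id"], sort=False)
    gd = GroupedData(codes, y, X, Z, ages, x_names=spec.fixed_names())
    meta = {
        "n_dropped_missing_g": int(n_dropped),
        "age_range": (float(ages.min()), float(ages.max())),
    }
    return gd, np.asarray(subject_ids), meta


class GrowthLMM:
    """Gaussian linear mixed growth model for one sex stratum."""

    def __init__(self, cohort: Cohort, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else preset_spec("splmm")
        self.cohort = cohort
        self.data, self.subject_ids, self.meta = _build_design(cohort, self.spec)

    @classmethod
    def from_dataframe(cls, visits: pd.DataFrame, spec: ModelSpec | None = None) -> "GrowthLMM":
        return cls(Cohort(visits), spec)

    def loglike(self, beta, G, sigma2, phi=0.0) -> float:
        """Exact marginal log-likelihood at given parameters (for checks)."""
        return loglik_at(self.data, beta, G, sigma2, phi)

    def fit(self, start_params=None, tol: float = 1e-8, maxiter: int = 500,
            n_restarts: int = 3) -> "GrowthLMMResults":
        ml = fit_ml(
            self.data,
            error=self.spec.error,
            start_params=start_params,
            tol=tol,
            maxiter=maxiter,
            n_restarts=n_restarts,
        )
        return GrowthLMMResults(self, ml)


class GrowthLMMResults:
    """ML fit of a :class:`GrowthLMM`.

    Attributes follow statsmodels conventions: ``params``, ``bse``,
    ``cov_params()``, ``llf``, ``aic``, ``fittedvalues``,
    ``random_effects``, ``converged``.
    """

    def __init__(self, model: GrowthLMM, ml: MLFit):
        self.model = model
        self._ml = ml
        names = model.spec.fixed_names()
        self.params = pd.Series(ml.beta, index=names)
        self.bse = pd.Series(np.sqrt(np.diag(ml.cov_beta)), index=names)
        self.G = ml.G
        self.sigma2 = ml.sigma2
        self.phi = ml.phi if model.spec.error == "car1" else None
        self.llf = ml.llf
        self.aic = ml.aic
        self.n_params = ml.n_params
        self.converged = ml.converged
        self.nobs = ml.data.n_obs
        self.n_subjects = ml.data.n_subjects

    def cov_params(self) -> pd.DataFrame:
        names = self.params.index
        return pd.DataFrame(self._ml.cov_beta, index=names, columns=names)

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.tvalues)), index=self.params.index
        )

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"lower": self.params - z * self.bse, "upper": self.params + z * self.bse}
        )

    @property
    def fittedvalues(self) -> np.ndarray:
        """Subject-level (fixed + BLUP) fitted values on the model scale."""
        return self._ml.fitted(level="subject")

    def fitted(self, level: str = "subject") -> np.ndarray:
        if level not in ("subject", "population"):
            raise ValueError("level must be 'subject' or 'population'")
        return self._ml.fitted(level=level)

    @property
    def observed(self) -> np.ndarray:
        """Response on the model scale, aligned with ``fittedvalues``."""
        out = np.empty(self.nobs)
        for g in self._ml.data.groups:
            out[g["visit_idx"].ravel()] = g["y"].ravel()
        return out

    @property
    def resid(self) -> np.ndarray:
        return self.observed - self.fittedvalues

    @property
    def random_effects(self) -> pd.DataFrame:
        u = self._ml.blups()
        cols = ["u_const", "u_a", "u_a2"][: u.shape[1]]
        order = self._ml.data.subject_order
        return pd.DataFrame(u, index=self.model.subject_ids[order], columns=cols)

    # -- prediction --------------------------------------------------------
    def predict(
        self,
        ages,
        level: str = "population",
        subject=None,
        response_scale: str | None = None,
        guard: float = 0.5,
    ) -> np.ndarray:
        """Predicted response at given ages.

        ``level='subject'`` adds the BLUP random-effect contribution for
        ``subject``.  ``response_scale='bmi'`` returns kg/m^2 (exponentiates
        an ln-scale model); default is the model scale.  Ages outside the
        observed range +- ``guard`` years trigger an extrapolation warning.
        """
        ages = np.asarray(ages, float)
        lo, hi = self.model.meta["age_range"]
        if np.any(ages < lo - guard) or np.any(ages > hi + guard):
            warnings.warn(
                f"predicting outside observed age range [{lo:.2f}, {hi:.2f}] +- {guard}",
                UserWarning,
                stacklevel=2,
            )
        spec = self.model.spec
        X = spec.fixed.build(ages)
        beta = self.params.to_numpy()[: X.shape[1]]
        pred = X @ beta
        if spec.genetic is not None and subject is not None:
            gval = float(spec.genetic.values.loc[subject])
            a = ages - spec.age_center
            gnames = spec.genetic.column_names()
            gcoefs = self.params[gnames].to_numpy()
            pred = pred + sum(
                gcoefs[d] * gval * a**d for d in range(spec.genetic.interactions + 1)
            )
        if level == "subject":
            if subject is None:
                raise ValueError("subject required for subject-level prediction")
            u = self.random_effects.loc[subject].to_numpy()
            pred = pred + random_design(ages, spec.random, spec.age_center) @ u
        if response_scale == "bmi" and spec.scale == "ln":
            pred = np.exp(pred)
        return pred

    # -- diagnostics -------------------------------------------------------
    def resid_std(self) -> np.ndarray:
        """Marginal standardized residuals."""
        return self._ml.resid_std()

    def diagnostics(self) -> dict[str, pd.DataFrame]:
        """Plot-ready diagnostic tables (no rendering dependency).

        ``qq``: theoretical vs sample quantiles of standardized residuals;
        ``fitted_observed`` and ``fitted_resid`` at subject level.
        """
        r = np.sort(self.resid_std())
        n = len(r)
        theo = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
        fitted = self.fittedvalues
        return {
            "qq": pd.DataFrame({"theoretical": theo, "sample": r}),
            "fitted_observed": pd.DataFrame({"fitted": fitted, "observed": self.observed}),
            "fitted_resid": pd.DataFrame({"fitted": fitted, "resid": self.resid}),
        }

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Gaussian linear mixed growth model (ML)",
            "=" * 54,
            f"Response scale: {'ln(BMI)' if spec.scale == 'ln' else 'BMI'}"
            f"    Subjects: {self.n_subjects}    Visits: {self.nobs}",
            f"Fixed basis: {spec.fixed.kind}    Random: {spec.random}"
            f"    Errors: {spec.error}",
            f"logLik: {self.llf:.3f}    AIC: {self.aic:.3f}"
            f"    converged: {self.converged}",
            "-" * 54,
            f"{'term':<16}{'coef':>12}{'se':>10}{'z':>8}{'P>|z|':>9}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<16}{self.params[name]:>12.5f}{self.bse[name]:>10.5f}"
                f"{self.tvalues[name]:>8.2f}{self.pvalues[name]:>9.4f}"
            )
        lines.append("-" * 54)
        sds = np.sqrt(np.diag(self.G))
        lines.append("Random-effect SDs: " + ", ".join(f"{s:.5f}" for s in sds))
        lines.append(f"Residual SD: {np.sqrt(self.sigma2):.5f}")
        if self.phi is not None:
            lines.append(f"CAR(1) phi: {self.phi:.4f} per year")
        return "\n".join(lines)

    def plot_trajectories(self, ax=None, n_grid: int = 120):
        """Population curve (BMI scale) over the observed age range."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lo, hi = self.model.meta["age_range"]
        grid = np.linspace(lo, hi, n_grid)
        ax.plot(grid, self.predict(grid, response_scale="bmi"))
        ax.set_xlabel("age (years)")
        ax.set_ylabel("BMI (kg/m$^2$)")
        return ax


def lrt_nested(full: GrowthLMMResults, null: GrowthLMMResults):
    """Likelihood-ratio test of nested ML fits on identical data.

    Returns ``(statistic, df, p)``; ``statistic = 2 (llf_full - llf_null)``,
    p from the upper chi-square tail.  Small negative statistics within
    convergence tolerance are clipped to 0; larger ones raise (refit
    signal).
    """
    names_full = set(full.params.index)
    names_null = set(null.params.index)
    if not names_null <= names_full or full.n_params < null.n_params:
        raise ValueError("models are not nested (null must be a sub-model of full)")
    if full.nobs != null.nobs:
        raise ValueError("fits use different data")
    stat = 2.0 * (full.llf - null.llf)
    if stat < -1e-4 * max(1.0, abs(full.llf)):
        raise RuntimeError(
            f"LRT statistic {stat:.4g} < 0 beyond tolerance; refit the full model"
        )
    stat = max(stat, 0.0)
    df = full.n_params - null.n_params
    p = float(stats.chi2.sf(stat, df)) if stat > 0 and df > 0 else 1.0
    return stat, df, p


def select_spline_model(
    cohort: Cohort,
    knot_grids,
    base_spec: ModelSpec | None = None,
    **fit_kw,
):
    """AIC model selection over candidate spline knot sets.

    ``knot_grids`` is an iterable of knot tuples (years).  Returns
    ``(best_spec, table)`` where the table lists AIC, log-likelihood and
    parameter count per converged candidate; failures are recorded and
    skipped.  Ties break toward fewer parameters.
    """
    if base_spec is None:
        base_spec = preset_spec("splmm")
    rows = []
    specs = {}
    candidates = list(knot_grids)
    if not candidates:
        raise ValueError("need at least one candidate knot set")
    for knots in candidates:
        spec = replace(
            base_spec, fixed=replace(base_spec.fixed, knots=tuple(knots))
        )
        try:
            res = GrowthLMM(cohort, spec).fit(**fit_kw)
        except Exception as exc:  # noqa: BLE001 - record and skip
            rows.append({"knots": tuple(knots), "aic": np.nan, "llf": np.nan,
                         "k": np.nan, "converged": False, "error": str(exc)})
            continue
        rows.append(
            {
                "knots": tuple(knots),
                "aic": res.aic,
                "llf": res.llf,
                "k": res.n_params,
                "converged": res.converged,
                "error": "",
            }
        )
        specs[tuple(knots)] = spec
    table = pd.DataFrame(rows)
    ok = table[table["converged"] == True]  # noqa: E712
    if ok.empty:
        raise RuntimeError("no candidate converged")
    ok = ok.sort_values(["aic", "k"], kind="mergesort")
    best = specs[tuple(ok.iloc[0]["knots"])]
    return best, table
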