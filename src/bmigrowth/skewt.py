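"""Skew-t linear mixed model (STLMM), estimated by EM.

The model extends the Gaussian LMM by giving the random effects a
multivariate skew-normal law and the within-subject errors a multivariate
t law that share one Gamma(nu/2, nu/2) mixing variable per subject, so the
marginal response of subject ``j`` is multivariate skew-t: asymmetry is
carried by a shape vector and heavy tails by the t degrees of freedom.
BMI is modelled untransformed; the skewness and kurtosis of the BMI
distribution are absorbed by the error law rather than a transformation.

Hierarchical form per subject (dropping the index): with mixing
``u ~ Gamma(nu/2, nu/2)`` and half-normal ``t0``,

    b | t0, u ~ N(Delta t0, Gamma_b / u),   t0 | u ~ N(0, 1/u) 1(t0 > 0)
    y | b, u  ~ N(X beta + Z b, sigma^2 I / u)

so the random-effect scale matrix is ``D = Gamma_b + Delta Delta'`` and
the skewness vector is ``lambda = D^{-1/2} Delta / sqrt(1 - Delta' D^{-1}
Delta)``.  The EM algorithm uses exact closed-form conditional moments of
``(u, t0, b)`` given ``y`` (no Monte Carlo), giving a deterministic,
provably monotone iteration; ``nu`` is updated by maximizing the observed
log-likelihood on a log grid refined by golden-section (an ECME step).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import gammaln

from .cohort import Cohort
from .lmm import GrowthLMM, ModelSpec, _build_design, preset_spec

__all__ = ["SkewTParams", "SkewTLMM", "SkewTLMMResults", "skew_t_univariate"]

_LOG_2PI = np.log(2.0 * np.pi)


@dataclass
class SkewTParams:
    """Parameters of the skew-t mixed model.

    ``Gamma_b`` and ``Delta`` parameterize the random-effect law; the
    scale matrix is ``D = Gamma_b + Delta Delta'``.  ``nu`` in (2, 200].
    """

    beta: np.ndarray
    sigma2: float
    Gamma_b: np.ndarray
    Delta: np.ndarray
    nu: float

    def __post_init__(self):
        self.beta = np.asarray(self.beta, float)
        self.Gamma_b = np.asarray(self.Gamma_b, float)
        self.Delta = np.asarray(self.Delta, float)
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.nu <= 2.0:
            raise ValueError("nu must exceed 2 (finite-variance regime)")
        if not np.allclose(self.Gamma_b, self.Gamma_b.T):
            raise ValueError("Gamma_b must be symmetric")

    @property
    def D(self) -> np.ndarray:
        """Random-effect scale matrix."""
        return self.Gamma_b + np.outer(self.Delta, self.Delta)

    @property
    def skewness(self) -> np.ndarray:
        """Skewness (shape) vector, one entry per random effect."""
        D = self.D
        evals, evecs = np.linalg.eigh(D)
        Dm12 = evecs @ np.diag(1.0 / np.sqrt(np.clip(evals, 1e-12, None))) @ evecs.T
        delta = Dm12 @ self.Delta
        denom = max(1.0 - float(delta @ delta), 1e-10)
        return delta / np.sqrt(denom)

    @property
    def k1(self) -> float:
        """E[t0 / sqrt(u)] = sqrt(nu/pi) Gamma((nu-1)/2) / Gamma(nu/2)."""
        nu = self.nu
        return float(np.sqrt(nu / np.pi) * np.exp(gammaln((nu - 1) / 2) - gammaln(nu / 2)))

    @property
    def random_effect_mean(self) -> np.ndarray:
        return self.Delta * self.k1


def _estep_group(g, beta, sigma2, Gamma_b, Delta, nu, want_moments=True):
    """Closed-form conditional moments for one visit-count group.

    Returns per-subject loglik contributions and (if requested) the
    moments (e_u, e_ut, e_ut2, e_ub, e_utb, e_ubb) plus reusable pieces.
    """
    Z, X, y = g["Z"], g["X"], g["y"]
    m, k, q = Z.shape
    R = y - X @ beta
    ZG = Z @ Gamma_b  # (m,k,q)
    Omega = ZG @ np.swapaxes(Z, 1, 2) + sigma2 * np.broadcast_to(np.eye(k), (m, k, k))
    Dy = Z @ Delta  # (m,k)
    Oi_R = np.linalg.solve(Omega, R[:, :, None])[:, :, 0]
    Oi_Dy = np.linalg.solve(Omega, Dy[:, :, None])[:, :, 0]
    q1 = np.einsum("mk,mk->m", Dy, Oi_R)
    M2 = 1.0 / (1.0 + np.einsum("mk,mk->m", Dy, Oi_Dy))
    mu_t = M2 * q1
    rOr = np.einsum("mk,mk->m", R, Oi_R)
    d = np.maximum(rOr - q1**2 * M2, 1e-12)
    _, ld_O = np.linalg.slogdet(Omega)
    logdetS = ld_O - np.log(M2)
    A = np.sqrt(M2) * q1

    nk = nu + k
    c = np.sqrt(nk / (nu + d))
    Tcdf = stats.t.cdf(A * c, df=nk)
    Tcdf = np.clip(Tcdf, 1e-300, None)
    ll = (
        np.log(2.0)
        + gammaln(nk / 2)
        - gammaln(nu / 2)
        - (k / 2) * np.log(nu * np.pi)
        - 0.5 * logdetS
        - (nk / 2) * np.log1p(d / nu)
        + np.log(Tcdf)
    )
    if not want_moments:
        return ll, None

    e_u = (nk / (nu + d)) * stats.t.cdf(A * np.sqrt((nk + 2) / (nu + d)), df=nk + 2) / Tcdf
    alpha = nk / 2.0
    bg = (nu + d) / 2.0
    bg2 = (nu + d + A**2) / 2.0
    kappa = (
        np.exp(gammaln(alpha + 0.5) - gammaln(alpha) + alpha * np.log(bg) - (alpha + 0.5) * np.log(bg2))
        / (np.sqrt(2.0 * np.pi) * Tcdf)
    )
    Mt = np.sqrt(M2)
    e_ut = mu_t * e_u + Mt * kappa
    e_ut2 = mu_t * e_ut + M2

    s = np.einsum("mkq,mk->mq", ZG, Oi_R)
    r_vec = Delta[None, :] - np.einsum("mkq,mk->mq", ZG, Oi_Dy)
    Lam = Gamma_b[None, :, :] - np.einsum(
        "mki,mkj->mij", ZG, np.linalg.solve(Omega, ZG)
    )
    e_ub = s * e_u[:, None] + r_vec * e_ut[:, None]
    e_utb = s * e_ut[:, None] + r_vec * e_ut2[:, None]
    e_ubb = (
        Lam
        + np.einsum("mi,mj->mij", s, s) * e_u[:, None, None]
        + (np.einsum("mi,mj->mij", s, r_vec) + np.einsum("mi,mj->mij", r_vec, s))
        * e_ut[:, None, None]
        + np.einsum("mi,mj->mij", r_vec, r_vec) * e_ut2[:, None, None]
    )
    return ll, (e_u, e_ut, e_ut2, e_ub, e_utb, e_ubb)


def _total_loglik(gd, params: SkewTParams) -> float:
    return float(
        sum(
            _estep_group(g, params.beta, params.sigma2, params.Gamma_b,
                         params.Delta, params.nu, want_moments=False)[0].sum()
            for g in gd.groups
        )
    )


def _nu_profile(gd, params: SkewTParams, grid_size: int = 12) -> float:
    """ECME step for nu: coarse log-grid then golden-section refinement."""
    def f(log_nu):
        p = SkewTParams(params.beta, params.sigma2, params.Gamma_b, params.Delta,
                        float(np.exp(log_nu)))
        return -_total_loglik(gd, p)

    lo, hi = np.log(2.05), np.log(200.0)
    grid = np.linspace(lo, hi, grid_size)
    vals = [f(x) for x in grid]
    i = int(np.argmin(vals))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, grid_size - 1)]
    if a == b:
        return float(np.exp(grid[i]))
    res = optimize.minimize_scalar(f, bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-4})
    return float(np.exp(res.x))


class SkewTLMM:
    """Skew-t linear mixed growth model for one sex stratum.

    Defaults to the selected specification: untransformed BMI, cubic age
    polynomial fixed effects, random intercept and linear age slope,
    independent (conditionally, given the shared mixing variable) errors.
    """

    def __init__(self, cohort: Cohort, spec: ModelSpec | None = None):
        self.spec = spec if spec is not None else preset_spec("stlmm")
        if self.spec.error != "independent":
            raise ValueError("the skew-t model supports independent errors only")
        self.cohort = cohort
        self.data, self.subject_ids, self.meta = _build_design(cohort, self.spec)

    @classmethod
    def from_dataframe(cls, visits: pd.DataFrame, spec: ModelSpec | None = None) -> "SkewTLMM":
        return cls(Cohort(visits), spec)

    def loglike(self, params: SkewTParams) -> float:
        """Observed-data marginal skew-t log-likelihood."""
        return _total_loglik(self.data, params)

    def _init_params(self, nu0: float = 10.0, skew_frac: float = 0.3) -> SkewTParams:
        gauss = GrowthLMM(self.cohort, self.spec).fit()
        G0 = gauss.G
        Delta0 = skew_frac * np.sqrt(np.diag(G0))
        Gamma0 = G0 - np.outer(Delta0, Delta0)
        # keep Gamma_b positive definite
        while np.linalg.eigvalsh(Gamma0).min() <= 1e-10:
            Delta0 *= 0.7
            Gamma0 = G0 - np.outer(Delta0, Delta0)
        return SkewTParams(gauss.params.to_numpy(), gauss.sigma2, Gamma0, Delta0, nu0)

    def fit(
        self,
        init: SkewTParams | None = None,
        max_iter: int = 2000,
        tol: float = 1e-6,
        nu_fixed: float | None = None,
        nu_every: int = 5,
        compute_se: bool = True,
    ) -> "SkewTLMMResults":
        """EM estimation.  The observed-data log-likelihood is checked to
        be non-decreasing at every iteration (a decrease beyond numerical
        tolerance raises, as it can only indicate an implementation bug).
        """
        gd = self.data
        params = init if init is not None else self._init_params(
            nu0=nu_fixed if nu_fixed is not None else 10.0
        )
        if nu_fixed is not None:
            params.nu = float(nu_fixed)
        N = gd.n_obs
        m_subj = gd.n_subjects
        p, q = gd.p, gd.q

        trace = [self.loglike(params)]
        converged = False
        rel = np.inf
        for it in range(max_iter):
            XtuX = np.zeros((p, p))
            Xtres = np.zeros(p)
            sum_utb = np.zeros(q)
            sum_ut2 = 0.0
            sum_ubb = np.zeros((q, q))
            group_moms = []
            for g in gd.groups:
                _, moms = _estep_group(
                    g, params.beta, params.sigma2, params.Gamma_b, params.Delta, params.nu
                )
                e_u, e_ut, e_ut2, e_ub, e_utb, e_ubb = moms
                group_moms.append(moms)
                X, Z, y = g["X"], g["Z"], g["y"]
                XtuX += np.einsum("m,mki,mkj->ij", e_u, X, X)
                Xtres += np.einsum("mki,mk->i", X, e_u[:, None] * y - np.einsum("mkq,mq->mk", Z, e_ub))
                sum_utb += e_utb.sum(axis=0)
                sum_ut2 += float(e_ut2.sum())
                sum_ubb += e_ubb.sum(axis=0)

            beta_new = np.linalg.solve(XtuX, Xtres)

            s2_acc = 0.0
            for g, moms in zip(gd.groups, group_moms):
                e_u, e_ut, e_ut2, e_ub, e_utb, e_ubb = moms
                X, Z, y = g["X"], g["Z"], g["y"]
                r = y - X @ beta_new
                s2_acc += float(np.einsum("m,mk,mk->", e_u, r, r))
                s2_acc -= 2.0 * float(np.einsum("mk,mkq,mq->", r, Z, e_ub))
                s2_acc += float(np.einsum("mki,mkj,mij->", Z, Z, e_ubb))
            sigma2_new = max(s2_acc / N, 1e-12)

            Delta_new = sum_utb / sum_ut2
            Gamma_new = (
                sum_ubb
                - np.outer(sum_utb, Delta_new)
                - np.outer(Delta_new, sum_utb)
                + sum_ut2 * np.outer(Delta_new, Delta_new)
            ) / m_subj
            Gamma_new = 0.5 * (Gamma_new + Gamma_new.T)
            ev = np.linalg.eigvalsh(Gamma_new)
            if ev.min() < 1e-12:
                Gamma_new += (1e-12 - ev.min()) * np.eye(q)

            params = SkewTParams(beta_new, sigma2_new, Gamma_new, Delta_new, params.nu)
            if nu_fixed is None and (it + 1) % nu_every == 0:
                params.nu = _nu_profile(gd, params)

            ll = self.loglike(params)
            if ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
                raise RuntimeError(
                    f"EM log-likelihood decreased at iteration {it}: "
                    f"{trace[-1]:.8f} -> {ll:.8f} (internal consistency failure)"
                )
            rel = abs(ll - trace[-1]) / max(1.0, abs(ll))
            trace.append(ll)
            if rel < tol:
                converged = True
                break

        if nu_fixed is None and converged:
            nu_final = _nu_profile(gd, params)
            p2 = SkewTParams(params.beta, params.sigma2, params.Gamma_b, params.Delta, nu_final)
            ll2 = self.loglike(p2)
            if ll2 >= trace[-1]:
                params, trace = p2, trace + [ll2]

        if not converged:
            warnings.warn(
                f"EM did not converge in {max_iter} iterations "
                f"(last relative change {rel:.2e})",
                UserWarning,
            )
        res = SkewTLMMResults(self, params, trace, converged)
        if compute_se:
            res._compute_se(nu_free=nu_fixed is None)
        return res


def _pack(params: SkewTParams, nu_free: bool):
    q = len(params.Delta)
    iu = np.triu_indices(q)
    vec = [params.beta, [np.log(params.sigma2)], params.Delta, params.Gamma_b[iu]]
    if nu_free:
        vec.append([np.log(params.nu - 2.0)])
    return np.concatenate([np.atleast_1d(np.asarray(v, float)) for v in vec])


def _unpack(x, p, q, nu, nu_free):
    iu = np.triu_indices(q)
    beta = x[:p]
    sigma2 = float(np.exp(x[p]))
    Delta = x[p + 1 : p + 1 + q]
    nG = q * (q + 1) // 2
    G = np.zeros((q, q))
    G[iu] = x[p + 1 + q : p + 1 + q + nG]
    G = G + G.T - np.diag(np.diag(G))
    if nu_free:
        nu = 2.0 + float(np.exp(x[p + 1 + q + nG]))
    return SkewTParams(beta, sigma2, G, Delta, nu)


class SkewTLMMResults:
    """EM fit of the skew-t mixed model."""

    def __init__(self, model: SkewTLMM, params: SkewTParams, trace, converged):
        self.model = model
        self.params_st = params
        self.loglik_trace = np.asarray(trace)
        self.llf = float(trace[-1])
        self.converged = bool(converged)
        self.n_iter = len(trace) - 1
        names = model.spec.fixed_names()
        # report fixed effects with the random-effect mean folded in, so the
        # population mean curve (and intercept) is comparable across methods
        beta_adj = params.beta.copy()
        mean_b = params.random_effect_mean
        beta_adj[: len(mean_b)] += mean_b  # Z columns (1, a) lead the X columns
        self.params = pd.Series(beta_adj, index=names)
        self.params_raw = pd.Series(params.beta.copy(), index=names)
        self.sigma2 = params.sigma2
        self.D = params.D
        self.skewness = params.skewness
        self.nu = params.nu
        self.nobs = model.data.n_obs
        q = len(params.Delta)
        self.n_params = len(params.beta) + 1 + q + q * (q + 1) // 2 + 1
        self.aic = -2 * self.llf + 2 * self.n_params
        self.bse = pd.Series(np.nan, index=names)
        self.skewness_se = np.full(q, np.nan)
        self.cov_all = None

    # -- uncertainty -------------------------------------------------------
    def _compute_se(self, nu_free: bool = True, eps: float = 1e-4):
        """Observed-information SEs by numerical differentiation of the
        marginal log-likelihood; delta method for the skewness vector."""
        gd = self.model.data
        pars = self.params_st
        p, q = gd.p, len(pars.Delta)
        x0 = _pack(pars, nu_free)
        n_par = len(x0)

        def nll(x):
            try:
                return -_total_loglik(gd, _unpack(x, p, q, pars.nu, nu_free))
            except (ValueError, np.linalg.LinAlgError):
                return np.inf

        h = eps * np.maximum(np.abs(x0), 1.0)
        H = np.zeros((n_par, n_par))
        f0 = nll(x0)
        fp = np.empty(n_par)
        fm = np.empty(n_par)
        for i in range(n_par):
            xi = x0.copy(); xi[i] += h[i]; fp[i] = nll(xi)
            xi = x0.copy(); xi[i] -= h[i]; fm[i] = nll(xi)
        for i in range(n_par):
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
            for j in range(i + 1, n_par):
                xpp = x0.copy(); xpp[[i, j]] += h[[i, j]]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x0.copy(); xmm[[i, j]] -= h[[i, j]]
                H[i, j] = H[j, i] = (nll(xpp) - nll(xpm) - nll(xmp) + nll(xmm)) / (
                    4 * h[i] * h[j]
                )
        try:
            cov = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            warnings.warn("observed information singular; SEs unavailable", UserWarning)
            return
        dvar = np.diag(cov)
        if np.any(dvar[:p] < 0):
            warnings.warn("information not PD at optimum; SEs unreliable", UserWarning)
        self.cov_all = cov
        self.bse = pd.Series(np.sqrt(np.abs(dvar[:p])), index=self.params.index)

        def lam_of(x):
            return _unpack(x, p, q, pars.nu, nu_free).skewness

        J = np.zeros((q, n_par))
        for i in range(n_par):
            xi = x0.copy(); xi[i] += h[i]
            xm = x0.copy(); xm[i] -= h[i]
            J[:, i] = (lam_of(xi) - lam_of(xm)) / (2 * h[i])
        lam_cov = J @ cov @ J.T
        self.skewness_se = np.sqrt(np.abs(np.diag(lam_cov)))

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2 * stats.norm.sf(np.abs(z)), index=self.params.index)

    def cov_params(self) -> pd.DataFrame:
        if self.cov_all is None:
            raise RuntimeError("SEs were not computed (compute_se=False)")
        p = self.model.data.p
        return pd.DataFrame(self.cov_all[:p, :p], index=self.params.index,
                            columns=self.params.index)

    # -- residuals ---------------------------------------------------------
    def standardized_residuals(self):
        """Marginal standardized residuals and theoretical skew-t quantiles.

        Each visit's marginal law is univariate skew-t; residuals are
        centred/scaled by that law's location and scale, and theoretical
        quantiles come from the pooled-shape fitted law, enabling the
        skew-t QQ panel.  Returns a DataFrame (theoretical, sample).
        """
        gd = self.model.data
        pars = self.params_st
        zs, deltas = [], []
        for g in gd.groups:
            Z, X, y = g["Z"], g["X"], g["y"]
            mu = X @ pars.beta
            Dy = Z @ pars.Delta
            Om_diag = np.einsum("mkq,qr,mkr->mk", Z, pars.Gamma_b, Z) + pars.sigma2
            S_diag = Om_diag + Dy**2
            scale = np.sqrt(S_diag)
            zs.append(((y - mu) / scale).ravel())
            deltas.append((Dy / scale).ravel())
        z = np.concatenate(zs)
        delta_bar = float(np.mean(np.concatenate(deltas)))
        lam = delta_bar / np.sqrt(max(1.0 - delta_bar**2, 1e-10))
        n = len(z)
        probs = (np.arange(1, n + 1) - 0.5) / n
        theo = skew_t_univariate.ppf(probs, lam, pars.nu)
        return pd.DataFrame({"theoretical": theo, "sample": np.sort(z)})

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            "Skew-t linear mixed growth model (EM)",
            "=" * 54,
            f"Response: BMI (untransformed)    Subjects: {self.model.data.n_subjects}"
            f"    Visits: {self.nobs}",
            f"logLik: {self.llf:.3f}    AIC: {self.aic:.3f}"
            f"    EM iterations: {self.n_iter}    converged: {self.converged}",
            "-" * 54,
            f"{'term':<16}{'coef':>12}{'se':>10}",
        ]
        for name in self.params.index:
            lines.append(f"{name:<16}{self.params[name]:>12.5f}{self.bse[name]:>10.5f}")
        lines.append("-" * 54)
        lines.append(
            "Skewness (intercept, slope): "
            + ", ".join(
                f"{l:.4f} [SE {s:.4f}]" for l, s in zip(self.skewness, self.skewness_se)
            )
        )
        lines.append(f"t degrees of freedom: {self.nu:.2f}")
        lines.append(f"Residual scale sigma: {np.sqrt(self.sigma2):.4f}")
        return "\n".join(lines)


class skew_t_univariate:
    """Univariate skew-t distribution helpers (location 0, scale 1).

    Density ``2 t(x; nu) T(lam x sqrt((nu+1)/(nu+x^2)); nu+1)``; the CDF
    and quantile function are evaluated by dense-grid quadrature (the
    distribution has no closed-form CDF).
    """

    @staticmethod
    def pdf(x, lam, nu):
        x = np.asarray(x, float)
        return 2.0 * stats.t.pdf(x, nu) * stats.t.cdf(
            lam * x * np.sqrt((nu + 1.0) / (nu + x**2)), nu + 1.0
        )

    @staticmethod
    def _grid(lam, nu):
        lim = max(12.0, 12.0 * np.sqrt(nu / max(nu - 2.0, 0.5)))
        return np.linspace(-lim, lim, 8001)

    @classmethod
    def cdf(cls, x, lam, nu):
        grid = cls._grid(lam, nu)
        pdf = cls.pdf(grid, lam, nu)
        c = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        c /= c[-1]
        return np.interp(np.asarray(x, float), grid, c)

    @classmethod
    def ppf(cls, p, lam, nu):
        grid = cls._grid(lam, nu)
        pdf = cls.pdf(grid, lam, nu)
        c = np.concatenate([[0.0], np.cumsum((pdf[1:] + pdf[:-1]) / 2 * np.diff(grid))])
        c /= c[-1]
        return np.interp(np.asarray(p, float), c, grid)
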