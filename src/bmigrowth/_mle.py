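"""Maximum-likelihood engine for Gaussian linear mixed growth models.

Subjects are grouped by visit count so per-subject covariance algebra runs
as stacked (batched) numpy linear algebra; with 8 follow-up waves there are
at most 8 groups regardless of cohort size.  Fixed effects and the residual
variance are profiled out by generalized least squares, so the numerical
search runs only over the random-effect covariance ratio ``Gamma = G /
sigma^2`` (Cholesky-parameterized) and, optionally, the CAR(1) parameter
``phi`` (logit-parameterized).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize
from scipy.special import expit, logit

__all__ = ["GroupedData", "MLFit", "fit_ml", "loglik_at"]

_LOG_2PI = np.log(2.0 * np.pi)


class GroupedData:
    """Visit-level arrays grouped by subjects' visit counts.

    Parameters are per-visit arrays, all aligned: integer subject codes
    (contiguous 0..m-1, visits of a subject adjacent), response ``y``,
    fixed design ``X`` (n, p), random design ``Z`` (n, q) and raw ages
    (years, used for CAR(1) gaps).
    """

    def __init__(self, codes, y, X, Z, ages, x_names=None):
        codes = np.asarray(codes)
        y = np.asarray(y, float)
        X = np.atleast_2d(np.asarray(X, float))
        Z = np.atleast_2d(np.asarray(Z, float))
        ages = np.asarray(ages, float)
        order = np.argsort(codes, kind="stable")
        codes, y, X, Z, ages = codes[order], y[order], X[order], Z[order], ages[order]
        self._order = order
        self.n_obs = len(y)
        self.p = X.shape[1]
        self.q = Z.shape[1]
        self.x_names = list(x_names) if x_names is not None else [f"x{i}" for i in range(self.p)]
        uniq, counts = np.unique(codes, return_counts=True)
        self.n_subjects = len(uniq)
        self.subject_codes = uniq
        # positions of each subject's first visit in the sorted arrays
        starts = np.concatenate([[0], np.cumsum(counts)[:-1]])
        self.groups = []
        for k in np.unique(counts):
            sel = counts == k
            m = int(sel.sum())
            idx = (starts[sel][:, None] + np.arange(k)[None, :]).ravel()
            self.groups.append(
                {
                    "k": int(k),
                    "m": m,
                    "subjects": uniq[sel],
                    "y": y[idx].reshape(m, k),
                    "X": X[idx].reshape(m, k, self.p),
                    "Z": Z[idx].reshape(m, k, self.q),
                    "ages": ages[idx].reshape(m, k),
                    "visit_idx": order[idx].reshape(m, k),  # original row positions
                }
            )
        for g in self.groups:
            a = g["ages"]
            g["gaps"] = np.abs(a[:, :, None] - a[:, None, :])
        # subject codes in the order blups()/fitted() iterate the groups
        self.subject_order = np.concatenate([g["subjects"] for g in self.groups])

        rank = np.linalg.matrix_rank(X) if self.n_obs >= self.p else self.n_obs
        if rank < self.p:
            # name a minimal set of collinear columns for the error message
            _, R = np.linalg.qr(X)
            kmax = min(self.n_obs, self.p)
            bad = [
                self.x_names[i]
                for i in range(kmax)
                if abs(R[i, i]) < 1e-8 * max(1, abs(R[0, 0]))
            ] + self.x_names[kmax:]
            raise np.linalg.LinAlgError(
                f"fixed-effect design is rank deficient (rank {rank} < {self.p}); "
                f"collinear columns: {bad}"
            )


def _corr_matrices(group, phi):
    k = group["k"]
    if phi == 0.0:
        return np.broadcast_to(np.eye(k), (group["m"], k, k))
    return phi ** group["gaps"]


def _gls_pass(gd: GroupedData, Gamma, phi):
    """One GLS sweep: returns (XtWiX, XtWiy, ytWiy, sum_logdet)."""
    p = gd.p
    XtWiX = np.zeros((p, p))
    XtWiy = np.zeros(p)
    ytWiy = 0.0
    logdet = 0.0
    for g in gd.groups:
        Z = g["Z"]
        W = Z @ Gamma @ np.swapaxes(Z, 1, 2) + _corr_matrices(g, phi)
        WiX = np.linalg.solve(W, g["X"])
        Wiy = np.linalg.solve(W, g["y"][:, :, None])[:, :, 0]
        XtWiX += np.einsum("mki,mkj->ij", g["X"], WiX)
        XtWiy += np.einsum("mki,mk->i", g["X"], Wiy)
        ytWiy += float(np.einsum("mk,mk->", g["y"], Wiy))
        sign, ld = np.linalg.slogdet(W)
        if np.any(sign <= 0):
            return None
        logdet += float(ld.sum())
    return XtWiX, XtWiy, ytWiy, logdet


def _profiled_nll(gd: GroupedData, Gamma, phi):
    out = _gls_pass(gd, Gamma, phi)
    if out is None:
        return np.inf, None
    XtWiX, XtWiy, ytWiy, logdet = out
    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
    except np.linalg.LinAlgError:
        return np.inf, None
    rss = ytWiy - XtWiy @ beta
    N = gd.n_obs
    if not np.isfinite(rss):
        return np.inf, None
    # exact-fit limit: clamp rather than reject so noise-free data work
    sigma2 = max(rss, 1e-280) / N
    nll = 0.5 * (N * (_LOG_2PI + np.log(sigma2) + 1.0) + logdet)
    return nll, (beta, sigma2, XtWiX)


def _theta_to_params(theta, q, car1):
    L = np.zeros((q, q))
    pos = 0
    for i in range(q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[pos])
            else:
                L[i, j] = theta[pos]
            pos += 1
    Gamma = L @ L.T
    phi = float(expit(theta[pos])) if car1 else 0.0
    return Gamma, phi


def _params_to_theta(Gamma, phi, car1):
    q = Gamma.shape[0]
    # stabilized Cholesky for (near-)singular Gamma
    L = np.linalg.cholesky(Gamma + 1e-10 * np.eye(q))
    theta = []
    for i in range(q):
        for j in range(i + 1):
            theta.append(np.log(max(L[i, j], 1e-8)) if i == j else L[i, j])
    if car1:
        theta.append(float(logit(np.clip(phi, 1e-3, 1 - 1e-3))))
    return np.asarray(theta)


class MLFit:
    """Container for a converged (or flagged) ML fit of the Gaussian LMM."""

    def __init__(self, gd, beta, cov_beta, sigma2, Gamma, phi, llf, n_params,
                 converged, n_iter, message=""):
        self.data = gd
        self.beta = beta
        self.cov_beta = cov_beta
        self.sigma2 = float(sigma2)
        self.Gamma = Gamma
        self.G = sigma2 * Gamma
        self.phi = float(phi)
        self.llf = float(llf)
        self.n_params = int(n_params)
        self.aic = -2.0 * self.llf + 2.0 * self.n_params
        self.converged = bool(converged)
        self.n_iter = int(n_iter)
        self.message = message

    def blups(self):
        """Per-subject random-effect predictions u_j = G Z' V^-1 (y - X beta)."""
        out = np.empty((self.data.n_subjects, self.data.q))
        pos = 0
        for g in self.data.groups:
            Z = g["Z"]
            W = Z @ self.Gamma @ np.swapaxes(Z, 1, 2) + _corr_matrices(g, self.phi)
            r = g["y"] - g["X"] @ self.beta
            Wir = np.linalg.solve(W, r[:, :, None])[:, :, 0]
            u = np.einsum("ij,mkj,mk->mi", self.Gamma, Z, Wir)
            out[pos : pos + g["m"]] = u
            pos += g["m"]
        return out

    def fitted(self, level="subject"):
        """Fitted values in original visit order (population or subject level)."""
        fit = np.empty(self.data.n_obs)
        u = self.blups() if level == "subject" else None
        pos = 0
        for g in self.data.groups:
            f = g["X"] @ self.beta
            if level == "subject":
                f = f + np.einsum("mkq,mq->mk", g["Z"], u[pos : pos + g["m"]])
            fit[g["visit_idx"].ravel()] = f.ravel()
            pos += g["m"]
        return fit

    def resid_std(self):
        """Marginal standardized residuals (y - X beta) / sd, per visit."""
        out = np.empty(self.data.n_obs)
        for g in self.data.groups:
            Z = g["Z"]
            W = Z @ self.Gamma @ np.swapaxes(Z, 1, 2) + _corr_matrices(g, self.phi)
            sd = np.sqrt(self.sigma2 * np.einsum("mkk->mk", W))
            r = (g["y"] - g["X"] @ self.beta) / sd
            out[g["visit_idx"].ravel()] = r.ravel()
        return out


def loglik_at(gd: GroupedData, beta, G, sigma2, phi=0.0):
    """Exact marginal log-likelihood at given parameters (no profiling)."""
    beta = np.asarray(beta, float)
    Gamma = np.asarray(G, float) / sigma2
    ll = 0.0
    for g in gd.groups:
        Z = g["Z"]
        W = Z @ Gamma @ np.swapaxes(Z, 1, 2) + _corr_matrices(g, phi)
        r = g["y"] - g["X"] @ beta
        Wir = np.linalg.solve(W, r[:, :, None])[:, :, 0]
        quad = np.einsum("mk,mk->m", r, Wir) / sigma2
        _, ld = np.linalg.slogdet(W)
        k = g["k"]
        ll += float(np.sum(-0.5 * (k * (_LOG_2PI + np.log(sigma2)) + ld + quad)))
    return ll


def fit_ml(
    gd: GroupedData,
    error: str = "independent",
    start: np.ndarray | None = None,
    start_params: tuple | None = None,
    tol: float = 1e-8,
    maxiter: int = 500,
    n_restarts: int = 3,
    seed: int = 0,
) -> MLFit:
    """Maximize the marginal likelihood; returns an :class:`MLFit`.

    ``error``: "independent" or "car1".  ``start_params`` optionally gives
    (Gamma, phi) to warm-start from a previous fit.  Non-convergence is
    flagged on the result, never silent.
    """
    if error not in ("independent", "car1"):
        raise ValueError(f"unknown error structure {error!r}")
    car1 = error == "car1"
    q = gd.q
    if gd.n_subjects <= gd.p:
        raise ValueError(
            f"need more subjects ({gd.n_subjects}) than fixed effects ({gd.p})"
        )

    if start is not None:
        theta0 = np.asarray(start, float)
    elif start_params is not None:
        theta0 = _params_to_theta(np.asarray(start_params[0], float),
                                  start_params[1] if car1 else 0.0, car1)
    else:
        theta0 = _params_to_theta(0.25 * np.eye(q), 0.3, car1)

    nll_cache = {}

    def objective(theta):
        key = theta.tobytes()
        if key not in nll_cache:
            Gamma, phi = _theta_to_params(theta, q, car1)
            nll_cache[key] = _profiled_nll(gd, Gamma, phi)
        return nll_cache[key][0]

    rng = np.random.default_rng(seed)
    best = None
    theta_init = theta0
    n_theta = len(theta0)
    bounds = []
    pos = 0
    for i in range(q):
        for j in range(i + 1):
            bounds.append((-12.0, 6.0) if i == j else (-30.0, 30.0))
            pos += 1
    if car1:
        bounds.append((-8.0, 8.0))

    total_nit = 0
    message = ""
    for attempt in range(1 + n_restarts):
        res = optimize.minimize(
            objective,
            theta_init,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
        )
        total_nit += res.nit
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        converged = res.success or res.fun < np.inf
        if res.success and np.isfinite(res.fun):
            break
        # restart from a jittered point
        theta_init = theta0 + rng.normal(scale=0.5, size=n_theta)
        message = res.message

    res = best
    if not res.success and np.isfinite(res.fun):
        # boundary/flat regions can end L-BFGS-B line searches abnormally;
        # a derivative-free polish settles convergence there
        polish = optimize.minimize(
            objective, res.x, method="Nelder-Mead",
            options={"maxiter": 60 * n_theta, "fatol": 1e-9, "xatol": 1e-7},
        )
        total_nit += polish.nit
        if polish.fun <= res.fun + 1e-9 and polish.success:
            res = polish
    Gamma, phi = _theta_to_params(res.x, q, car1)
    nll, aux = _profiled_nll(gd, Gamma, phi)
    if aux is None:
        raise np.linalg.LinAlgError("likelihood undefined at optimum (singular W)")
    beta, sigma2, XtWiX = aux
    cov_beta = sigma2 * np.linalg.inv(XtWiX)
    n_params = gd.p + 1 + q * (q + 1) // 2 + (1 if car1 else 0)
    return MLFit(
        gd,
        beta,
        cov_beta,
        sigma2,
        Gamma,
        phi,
        llf=-nll,
        n_params=n_params,
        converged=bool(res.success and np.isfinite(res.fun)),
        n_iter=total_nit,
        message=str(res.message),
    )
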