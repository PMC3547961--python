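"""Cross-method comparison: R², cluster-bootstrap R², squared-error
summaries, SNP detection tallies and bootstrap power.

The fit statistic is ``R² = 1 - SSE/SST`` computed with *subject-level*
fitted values (fixed effects plus predicted random effects) on the model's
response scale — population-level fitted values cannot reach the 80-90%
range that longitudinal BMI models attain, because most BMI variance is
between children.  Bootstrap resampling is by subject (all of a child's
visits stay together), the valid resampling unit for clustered
longitudinal data.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assoc import AssocResult, global_lrt_assoc
from .cohort import Cohort
from .lmm import GrowthLMM, ModelSpec

__all__ = [
    "r_squared",
    "squared_error_summary",
    "bootstrap_r_squared",
    "count_significant",
    "power_bootstrap",
    "ComparisonReport",
]


def r_squared(observed, fitted) -> float:
    """``1 - SSE/SST`` with SST about the observed mean."""
    o = np.asarray(observed, float)
    f = np.asarray(fitted, float)
    if o.shape != f.shape or o.ndim != 1 or len(o) < 2:
        raise ValueError("observed and fitted must be equal-length vectors (n >= 2)")
    sst = float(np.sum((o - o.mean()) ** 2))
    if sst == 0:
        raise ValueError("observed values have zero variance; R^2 undefined")
    return 1.0 - float(np.sum((o - f) ** 2)) / sst


def squared_error_summary(observed, fitted) -> dict:
    """Median and IQR of per-visit squared errors ``(observed - fitted)^2``."""
    o = np.asarray(observed, float)
    f = np.asarray(fitted, float)
    if o.shape != f.shape:
        raise ValueError("length mismatch")
    sq = (o - f) ** 2
    q25, med, q75 = np.percentile(sq, [25, 50, 75])
    return {"median": float(med), "iqr_low": float(q25), "iqr_high": float(q75)}


def _resample_cohort(cohort: Cohort, rng) -> Cohort:
    """Cluster bootstrap: subjects drawn with replacement, visits intact.

    Re-drawn subjects get fresh ids so repeated draws stay distinct
    clusters.
    """
    subjects = cohort.subjects
    draw = rng.choice(subjects, size=len(subjects), replace=True)
    frames = []
    df = cohort.df.set_index("subject_id")
    for new_id, sid in enumerate(draw):
        block = df.loc[[sid]].reset_index()
        block["subject_id"] = new_id
        frames.append(block)
    return Cohort(pd.concat(frames, ignore_index=True), validate=False)


def bootstrap_r_squared(
    cohort: Cohort,
    spec: ModelSpec,
    engine: str = "splmm",
    B: int = 200,
    seed: int = 0,
    max_fail: float = 0.2,
) -> dict:
    """Median and IQR of R² over ``B`` subject-level bootstrap refits.

    The model specification is frozen across replicates (no knot/df
    reselection).  Non-convergent replicates are excluded and their rate
    reported; above ``max_fail`` the summary is flagged unusable.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    vals, fails = [], 0
    for _ in range(B):
        boot = _resample_cohort(cohort, rng)
        try:
            res = _fit_engine(boot, spec, engine)
            if not res["converged"]:
                raise RuntimeError("non-convergent replicate")
            vals.append(r_squared(res["observed"], res["fitted"]))
        except Exception:  # noqa: BLE001 - replicate failure, counted
            fails += 1
    fail_rate = fails / B
    out = {
        "B": B,
        "n_failed": fails,
        "fail_rate": fail_rate,
        "usable": fail_rate <= max_fail,
    }
    if vals:
        q25, med, q75 = np.percentile(vals, [25, 50, 75])
        out.update(median=float(med), iqr_low=float(q25), iqr_high=float(q75))
    return out


def _fit_engine(cohort: Cohort, spec: ModelSpec | None, engine: str, **kw) -> dict:
    """Uniform fitting front-end returning observed/fitted on model scale."""
    if engine in ("lmm", "splmm"):
        res = GrowthLMM(cohort, spec).fit(**kw)
        return {
            "observed": res.observed,
            "fitted": res.fittedvalues,
            "llf": res.llf,
            "converged": res.converged,
            "result": res,
        }
    if engine == "stlmm":
        from .skewt import SkewTLMM

        res = SkewTLMM(cohort, spec).fit(compute_se=False, **kw)
        return {
            "observed": np.concatenate([g["y"].ravel() for g in res.model.data.groups]),
            "fitted": _stlmm_fitted(res),
            "llf": res.llf,
            "converged": res.converged,
            "result": res,
        }
    if engine == "sitar":
        from .sitar import SITAR

        df = kw.pop("df", 4)
        res = SITAR(cohort, df=df).fit(**kw)
        return {
            "observed": res.observed,
            "fitted": res.fittedvalues,
            "llf": res.llf,
            "converged": res.converged,
            "result": res,
        }
    raise ValueError(f"unknown engine {engine!r}")


def _stlmm_fitted(res) -> np.ndarray:
    """Subject-level fitted values for the skew-t fit: X beta + Z E[b|y]."""
    from .skewt import _estep_group

    gd = res.model.data
    pars = res.params_st
    out = []
    for g in gd.groups:
        _, moms = _estep_group(g, pars.beta, pars.sigma2, pars.Gamma_b, pars.Delta, pars.nu)
        e_u, _, _, e_ub, _, _ = moms
        e_b = e_ub / e_u[:, None]  # E[b|y] approximated by E[ub|y]/E[u|y]
        f = g["X"] @ pars.beta + np.einsum("mkq,mq->mk", g["Z"], e_b)
        out.append(f.ravel())
    return np.concatenate(out)


def count_significant(results, alpha: float = 0.05) -> int:
    """Detection tally.

    ``results`` is a list of :class:`AssocResult` (one global LRT per SNP)
    and/or SITAR three-test tables (count of single-parameter tests with
    p < alpha; 3 tests per SNP, denominator 3L).
    """
    n = 0
    for r in results:
        if isinstance(r, AssocResult):
            if r.converged and r.lrt_p is not None and r.lrt_p < alpha:
                n += 1
        elif isinstance(r, pd.DataFrame):
            n += int((r["p"] < alpha).sum())
        else:
            raise TypeError(f"unsupported result type {type(r)!r}")
    return n


def power_bootstrap(
    cohort: Cohort,
    g: pd.Series,
    base_spec: ModelSpec,
    engine: str = "splmm",
    B: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    interactions: int = 3,
) -> dict:
    """Non-parametric bootstrap power: fraction of ``B`` subject-resampled
    datasets whose global LRT is significant at ``alpha``.

    Resamples (cohort, genotype) jointly by subject from the provided
    stratum, so the injected (or real) effect structure is preserved.
    Returns the power estimate with a binomial 95% CI.
    """
    rng = np.random.default_rng(seed)
    subjects = cohort.subjects
    df = cohort.df.set_index("subject_id")
    hits, fails = 0, 0
    for _ in range(B):
        draw = rng.choice(subjects, size=len(subjects), replace=True)
        frames, gvals = [], {}
        for new_id, sid in enumerate(draw):
            block = df.loc[[sid]].reset_index()
            block["subject_id"] = new_id
            frames.append(block)
            gvals[new_id] = g.get(sid, np.nan)
        boot = Cohort(pd.concat(frames, ignore_index=True), validate=False)
        gboot = pd.Series(gvals)
        try:
            res = global_lrt_assoc(boot, base_spec, gboot, engine=engine,
                                   interactions=interactions)
            if not res.converged:
                raise RuntimeError("replicate did not converge")
            hits += res.lrt_p < alpha
        except Exception:  # noqa: BLE001
            fails += 1
    n_ok = B - fails
    power = hits / n_ok if n_ok else np.nan
    half = 1.959963984540054 * np.sqrt(max(power * (1 - power), 1e-12) / n_ok) if n_ok else np.nan
    return {
        "power": power,
        "ci_low": max(power - half, 0.0) if n_ok else np.nan,
        "ci_high": min(power + half, 1.0) if n_ok else np.nan,
        "B": B,
        "n_failed": fails,
        "alpha": alpha,
    }


@dataclass
class ComparisonReport:
    """Comparison metrics across methods, serializable to JSON."""

    entries: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def add(self, method: str, *, r2: float, boot: dict | None = None,
            sq_err: dict | None = None, n_significant: int | None = None,
            n_tests: int | None = None, runtime_s: float | None = None):
        if not 0.0 <= r2 <= 1.0:
            raise ValueError("R^2 outside [0, 1] for an intercept model")
        self.entries[method] = {
            "r2": r2,
            "bootstrap_r2": boot,
            "squared_error": sq_err,
            "n_significant": n_significant,
            "n_tests": n_tests,
            "runtime_s": runtime_s,
        }

    def to_frame(self) -> pd.DataFrame:
        rows = {}
        for method, e in self.entries.items():
            row = {"R2": e["r2"]}
            if e["bootstrap_r2"] and "median" in e["bootstrap_r2"]:
                b = e["bootstrap_r2"]
                row["bootR2_median"] = b["median"]
                row["bootR2_iqr"] = f"({b['iqr_low']:.4f}, {b['iqr_high']:.4f})"
            if e["squared_error"]:
                s = e["squared_error"]
                row["sqerr_median"] = s["median"]
                row["sqerr_iqr"] = f"({s['iqr_low']:.4g}, {s['iqr_high']:.4g})"
            if e["n_significant"] is not None:
                row["detected"] = f"{e['n_significant']} of {e['n_tests']}"
            if e["runtime_s"] is not None:
                row["runtime_s"] = e["runtime_s"]
            rows[method] = row
        return pd.DataFrame(rows).T

    def to_json(self, path=None) -> str:
        payload = json.dumps({"entries": self.entries, "meta": self.meta}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "ComparisonReport":
        d = json.loads(text)
        return cls(entries=d["entries"], meta=d["meta"])
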