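"""Design bases for growth-curve models.

Centred polynomials, cubic truncated-power splines, natural cubic splines
and the continuous-time AR(1) correlation kernel.  All model modules build
their fixed- and random-effect design matrices through this module, so a
model specification can be written down declaratively (see
:class:`BasisSpec`) and serialized to YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BasisSpec",
    "polynomial_basis",
    "truncated_power_basis",
    "truncated_power_cubic_basis",
    "natural_cubic_spline_basis",
    "natural_cubic_spline_deriv",
    "natural_spline_knots",
    "car1_correlation",
]

_MAX_DEGREE = 3


@dataclass(frozen=True)
class BasisSpec:
    """Declarative description of a time basis.

    Parameters
    ----------
    kind : {"polynomial", "truncated_power_cubic", "natural_cubic_spline"}
    degree : polynomial degree (<= 3), used by ``polynomial``.
    knots : interior knot positions in years (raw age scale), used by
        ``truncated_power_cubic``.
    df : degrees of freedom, used by ``natural_cubic_spline`` (3..8).
    center : centring constant in years applied to polynomial columns
        (spline knots stay on the raw age scale).
    log_time : apply ln() to age before building the basis.
    """

    kind: str = "polynomial"
    degree: int = 3
    knots: tuple[float, ...] = ()
    df: int = 3
    center: float = 8.0
    log_time: bool = False

    def __post_init__(self):
        if self.kind not in (
            "polynomial",
            "truncated_power_cubic",
            "natural_cubic_spline",
        ):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.kind == "polynomial" and not 0 <= self.degree <= _MAX_DEGREE:
            raise ValueError("polynomial degree must be in 0..3")
        if self.kind == "natural_cubic_spline" and not 3 <= self.df <= 8:
            raise ValueError("natural spline df must be in 3..8")
        if len(self.knots) > 1 and np.any(np.diff(self.knots) <= 0):
            raise ValueError("knots must be strictly increasing")
        object.__setattr__(self, "knots", tuple(float(k) for k in self.knots))

    @property
    def n_columns(self) -> int:
        if self.kind == "polynomial":
            return self.degree + 1
        if self.kind == "truncated_power_cubic":
            return len(self.knots) + 4
        return self.df + 1  # natural spline: intercept + df columns

    def build(self, ages: np.ndarray, boundary: tuple[float, float] | None = None) -> np.ndarray:
        """Evaluate the basis at ``ages`` (years), returning a design matrix."""
        t = np.asarray(ages, dtype=float)
        if self.log_time:
            if np.any(t <= 0):
                raise ValueError("log time transform requires positive ages")
            t = np.log(t)
        if self.kind == "polynomial":
            return polynomial_basis(t, self.degree, self.center, _pre_transformed=True)
        if self.kind == "truncated_power_cubic":
            return truncated_power_cubic_basis(t, self.knots, center=self.center)
        interior, bnd = natural_spline_knots(t, self.df, boundary)
        ns = natural_cubic_spline_basis(t, interior, bnd)
        return np.column_stack([np.ones_like(t), ns])

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "degree": self.degree,
            "knots": list(self.knots),
            "df": self.df,
            "center": self.center,
            "log_time": self.log_time,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BasisSpec":
        d = dict(d)
        if "knots" in d:
            d["knots"] = tuple(d["knots"])
        return cls(**d)


def polynomial_basis(
    ages, degree: int, center: float = 0.0, *, _pre_transformed: bool = False
) -> np.ndarray:
    """Centred polynomial design matrix ``[1, a, a^2, ..., a^degree]``.

    ``a = age - center``.  Degree is capped at 3 (growth-curve practice:
    cubic fixed effects suffice for childhood BMI and higher orders are
    numerically fragile with 8 visit waves).
    """
    if not 0 <= degree <= _MAX_DEGREE:
        raise ValueError(f"degree must be in 0..{_MAX_DEGREE}, got {degree}")
    a = np.asarray(ages, dtype=float) - float(center)
    return np.vander(a, N=degree + 1, increasing=True)


def truncated_power_basis(
    ages, knots, power: int = 3, center: float = 0.0
) -> np.ndarray:
    """Truncated power spline basis of a given power (1 = linear, 3 = cubic).

    Columns are ``[1, t, .., t^power, (t-k1)^power_+, ..., (t-kK)^power_+]``
    where ``(t-k)_+ = 0`` for ``t <= k``.  The polynomial columns are centred
    at ``center``; the truncated columns use raw age so knots keep their
    year units.
    """
    if power not in (1, 2, 3):
        raise ValueError("power must be 1, 2 or 3")
    t = np.asarray(ages, dtype=float)
    knots = np.asarray(knots, dtype=float)
    if knots.size > 1 and np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing and distinct")
    cols = [polynomial_basis(t, power, center)]
    for k in knots:
        cols.append(np.clip(t - k, 0.0, None)[:, None] ** power)
    return np.hstack(cols)


def truncated_power_cubic_basis(ages, knots, center: float = 0.0) -> np.ndarray:
    """Cubic truncated power basis: ``K + 4`` columns, C2-continuous at knots."""
    return truncated_power_basis(ages, knots, power=3, center=center)


def natural_spline_knots(
    x, df: int, boundary: tuple[float, float] | None = None
) -> tuple[np.ndarray, tuple[float, float]]:
    """Knot layout for a natural cubic spline with ``df`` columns.

    Interior knots sit at equally spaced quantiles of ``x``; boundary knots
    default to the 2.5th/97.5th percentiles (stabilises the natural
    constraints against sparse extremes).  ``df`` columns (excluding
    intercept) need ``df + 1`` knots in total, i.e. ``df - 1`` interior.
    """
    x = np.asarray(x, dtype=float)
    if not 3 <= df <= 8:
        raise ValueError("df must be in 3..8")
    if np.unique(x).size < df + 2:
        raise ValueError(f"need at least {df + 2} distinct x values for df={df}")
    if boundary is None:
        boundary = (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))
    lo, hi = boundary
    n_interior = df - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    inner = x[(x > lo) & (x < hi)]
    if inner.size < n_interior + 2:
        inner = x
    interior = np.quantile(inner, qs)
    interior = np.clip(interior, lo + 1e-8, hi - 1e-8)
    return np.asarray(interior, dtype=float), (lo, hi)


def _ns_d(x, k, k_last):
    """Helper d_k(x) of the natural-spline basis (divided truncated cubics)."""
    return (np.clip(x - k, 0, None) ** 3 - np.clip(x - k_last, 0, None) ** 3) / (
        k_last - k
    )


def _ns_d_deriv(x, k, k_last):
    return (3 * np.clip(x - k, 0, None) ** 2 - 3 * np.clip(x - k_last, 0, None) ** 2) / (
        k_last - k
    )


def natural_cubic_spline_basis(x, interior_knots, boundary: tuple[float, float]) -> np.ndarray:
    """Natural cubic spline basis (no intercept column).

    Standard reduced truncated-power construction: with knots
    ``xi_1 < ... < xi_K`` (boundary + interior), the K basis functions are
    ``N_1 = x`` and ``N_{j+1}(x) = d_j(x) - d_{K-1}(x)`` which are linear
    beyond the boundary knots (f'' = f''' = 0 outside).
    Returns ``K - 1`` columns for ``K`` knots, i.e. ``df`` columns for
    ``df - 1`` interior knots.
    """
    x = np.asarray(x, dtype=float)
    knots = np.concatenate([[boundary[0]], np.asarray(interior_knots, float), [boundary[1]]])
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots (boundary + interior) must be strictly increasing")
    K = len(knots)
    cols = [x]
    k_last, k_penult = knots[-1], knots[-2]
    d_penult = _ns_d(x, k_penult, k_last)
    for j in range(K - 2):
        cols.append(_ns_d(x, knots[j], k_last) - d_penult)
    return np.column_stack(cols)


def natural_cubic_spline_deriv(x, interior_knots, boundary: tuple[float, float]) -> np.ndarray:
    """First derivative of each column of :func:`natural_cubic_spline_basis`."""
    x = np.asarray(x, dtype=float)
    knots = np.concatenate([[boundary[0]], np.asarray(interior_knots, float), [boundary[1]]])
    K = len(knots)
    cols = [np.ones_like(x)]
    k_last, k_penult = knots[-1], knots[-2]
    d_penult = _ns_d_deriv(x, k_penult, k_last)
    for j in range(K - 2):
        cols.append(_ns_d_deriv(x, knots[j], k_last) - d_penult)
    return np.column_stack(cols)


#: random-effect design kinds -> number of columns
RANDOM_KINDS = {"intercept": 1, "linear": 2, "quad": 3, "quad_half": 3}


def random_design(ages, kind: str = "quad_half", center: float = 8.0) -> np.ndarray:
    """Random-effect design columns on centred age ``a = age - center``.

    ``intercept`` -> (1,); ``linear`` -> (1, a); ``quad`` -> (1, a, a^2);
    ``quad_half`` -> (1, a, 0.5 a^2).  The 0.5-scaled quadratic is the
    parameterization used for the spline mixed model; it changes only the
    parameterization of the random-effect covariance, not the model.
    """
    a = np.asarray(ages, float) - center
    if kind == "intercept":
        return np.ones((len(a), 1))
    if kind == "linear":
        return np.column_stack([np.ones_like(a), a])
    if kind == "quad":
        return np.column_stack([np.ones_like(a), a, a**2])
    if kind == "quad_half":
        return np.column_stack([np.ones_like(a), a, 0.5 * a**2])
    raise ValueError(f"unknown random design {kind!r}")


def car1_correlation(ages, phi: float) -> np.ndarray:
    """Continuous-time AR(1) correlation matrix ``C[s,t] = phi^|age_s - age_t|``.

    ``phi`` in [0, 1); gaps measured in raw years.  ``phi = 0`` gives the
    identity (independent errors).
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"phi must be in [0, 1), got {phi}")
    t = np.asarray(ages, dtype=float)
    D = np.abs(t[:, None] - t[None, :])
    if phi == 0.0:
        return np.eye(len(t)) + 0.0 * D  # exact identity even with tied ages
    return phi**D
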