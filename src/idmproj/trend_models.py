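"""Smooth age-time trend surfaces and the two-group mortality model.

Incidence and prevalence trends are fitted as additive natural-cubic-spline
models in age and calendar time on the log scale, one surface per sex and
measure.  Natural cubic splines are linear beyond their boundary knots, so
extrapolating the calendar-time dimension into projection years continues
the fitted log-linear trend -- the property the projections rely on.

The basis is the classic truncated-power construction (with K knots
``xi_1 < ... < xi_K``)::

    N_1(x) = 1,   N_2(x) = x,
    N_{j+2}(x) = d_j(x) - d_{K-1}(x),   j = 1..K-2,
    d_j(x) = [ (x - xi_j)_+^3 - (x - xi_K)_+^3 ] / (xi_K - xi_j)

which spans exactly the natural cubic splines on the knot set and is
linear outside [xi_1, xi_K] by construction.

Disease-specific mortality is rarely observed.  Given an overall mortality
surface ``m_all``, the prevalence ``p`` and a mortality-risk ratio
``RR(t) = max(1, rr0 - rr_decline*(t - reference_time))`` (default
``rr0 = 1.4``), the susceptible and diseased rates solve the 2x2 system::

    m_all = p*m1 + (1-p)*m0,      m1 = RR(t)*m0

giving ``m0 = m_all / (1 + p*(RR - 1))`` and ``m1 = RR*m0``.  The linear
decline of the ratio encodes an expected gradual improvement in disease and
comorbidity management that is faster in the diseased group; the floor at 1
keeps the ratio meaningful at distant times.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

MEASURES = (
    "incidence",
    "prevalence",
    "mortality_all",
    "mortality_susceptible",
    "mortality_diseased",
)

AGE_DOMAIN = (0.0, 95.0)
DEFAULT_AGE_KNOTS = tuple(range(0, 91, 10))
LOG_FLOOR = 1e-8  # zero-rate floor before the log transform


def natural_cubic_basis(x, knots: Sequence[float]) -> np.ndarray:
    """Evaluate the K-column natural-cubic-spline basis at ``x``.

    With two knots the basis degenerates to [1, x].  Outside the boundary
    knots every column is a linear function of ``x``.
    """
    x = np.asarray(x, dtype=float)
    k = np.asarray(sorted(set(float(v) for v in knots)), dtype=float)
    if k.size < 2:
        raise ValueError("need at least two distinct knots")

    def d(j: int) -> np.ndarray:
        pos_j = np.maximum(x - k[j], 0.0) ** 3
        pos_K = np.maximum(x - k[-1], 0.0) ** 3
        return (pos_j - pos_K) / (k[-1] - k[j])

    cols = [np.ones_like(x), x]
    if k.size > 2:
        d_last = d(k.size - 2)
        cols.extend(d(j) - d_last for j in range(k.size - 2))
    return np.column_stack(cols)


def default_time_knots(years, spacing: float = 5.0) -> tuple[float, ...]:
    """Knots every ``spacing`` calendar years spanning the observed range."""
    lo, hi = float(np.min(years)), float(np.max(years))
    knots = list(np.arange(lo, hi, spacing)) + [hi]
    return tuple(dict.fromkeys(knots))


@dataclass
class RateSurface:
    """A fitted log-scale additive spline surface rate(age, time).

    Evaluation exponentiates the spline; prevalence surfaces are clipped
    to <= 1.  Age evaluation outside ``age_domain`` is refused (no age
    extrapolation); calendar time extrapolates linearly on the log scale.
    """

    sex: str
    measure: str
    age_knots: tuple
    time_knots: tuple
    coef: np.ndarray
    age_domain: tuple = AGE_DOMAIN
    time_domain: tuple = (1990.0, 2019.0)
    tensor: bool = False

    def __post_init__(self):
        if self.measure not in MEASURES:
            raise ValueError(f"unknown measure {self.measure!r}")
        self.coef = np.asarray(self.coef, dtype=float)

    def design(self, age, time) -> np.ndarray:
        age = np.asarray(age, dtype=float)
        time = np.asarray(time, dtype=float)
        age, time = np.broadcast_arrays(age, time)
        Xa = natural_cubic_basis(age.ravel(), self.age_knots)[:, 1:]
        Xt = natural_cubic_basis(time.ravel(), self.time_knots)[:, 1:]
        blocks = [np.ones((Xa.shape[0], 1)), Xa, Xt]
        if self.tensor:
            blocks.append(_tensor_cols(Xa, Xt))
        return np.hstack(blocks)

    def __call__(self, age, time):
        return self.evaluate(age, time)

    def evaluate(self, age, time):
        age_arr = np.asarray(age, dtype=float)
        if np.any(age_arr < self.age_domain[0]) or np.any(age_arr > self.age_domain[1]):
            raise ValueError(
                f"age outside domain {self.age_domain}; age extrapolation is not supported"
            )
        shape = np.broadcast_shapes(age_arr.shape, np.asarray(time, float).shape)
        val = np.exp(self.design(age, time) @ self.coef).reshape(shape)
        if self.measure == "prevalence":
            val = np.minimum(val, 1.0)
        out = val if shape else float(val)
        return out

    def to_dict(self) -> dict:
        return {
            "sex": self.sex,
            "measure": self.measure,
            "age_knots": list(self.age_knots),
            "time_knots": list(self.time_knots),
            "coef": self.coef.tolist(),
            "age_domain": list(self.age_domain),
            "time_domain": list(self.time_domain),
            "tensor": self.tensor,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RateSurface":
        return cls(
            sex=d["sex"],
            measure=d["measure"],
            age_knots=tuple(d["age_knots"]),
            time_knots=tuple(d["time_knots"]),
            coef=np.asarray(d["coef"], float),
            age_domain=tuple(d["age_domain"]),
            time_domain=tuple(d["time_domain"]),
            tensor=bool(d.get("tensor", False)),
        )


def _tensor_cols(Xa: np.ndarray, Xt: np.ndarray) -> np.ndarray:
    return (Xa[:, :, None] * Xt[:, None, :]).reshape(Xa.shape[0], -1)


def fit_rate_surface(
    observations,
    measure: str,
    sex: str = "",
    age_knots: Sequence[float] | None = None,
    time_knots: Sequence[float] | None = None,
    tensor: bool = False,
    floor: float = LOG_FLOOR,
) -> RateSurface:
    """Least-squares fit of the additive log-scale spline surface.

    ``observations`` is a DataFrame (or convertible) with columns
    ``age``, ``year``, ``value``.  Zeros (and anything below ``floor``)
    are floored before the log transform.  Raises if either dimension's
    data cannot identify its basis (rank deficiency), naming the
    offending dimension.
    """
    obs = pd.DataFrame(observations)
    missing = {"age", "year", "value"} - set(obs.columns)
    if missing:
        raise ValueError(f"observations lack columns {sorted(missing)}")
    if obs["age"].nunique() < 2 or obs["year"].nunique() < 2:
        raise ValueError("need >= 2 distinct ages and >= 2 distinct years")
    age_knots = tuple(age_knots) if age_knots is not None else DEFAULT_AGE_KNOTS
    time_knots = (
        tuple(time_knots) if time_knots is not None else default_time_knots(obs["year"])
    )
    surf = RateSurface(
        sex=sex,
        measure=measure,
        age_knots=age_knots,
        time_knots=time_knots,
        coef=np.zeros(1),
        time_domain=(float(obs["year"].min()), float(obs["year"].max())),
        tensor=tensor,
    )
    X = surf.design(obs["age"].to_numpy(float), obs["year"].to_numpy(float))
    n_age_cols = len(age_knots) - 1
    n_time_cols = len(time_knots) - 1
    if np.linalg.matrix_rank(X) < X.shape[1]:
        if obs["age"].nunique() <= n_age_cols:
            dim = "age"
        elif obs["year"].nunique() <= n_time_cols:
            dim = "time"
        else:
            dim = "age x time"
        raise ValueError(
            f"rank-deficient spline basis in the {dim} dimension: "
            f"too many knots for the observed grid"
        )
    y = np.log(np.maximum(obs["value"].to_numpy(float), floor))
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    surf.coef = coef
    return surf


def eval_rate(surface: RateSurface, age, time):
    """Evaluate a fitted surface; see :meth:`RateSurface.evaluate`."""
    return surface.evaluate(age, time)


RateLike = Callable[..., np.ndarray]


def _as_fn(obj) -> RateLike:
    if callable(obj):
        return obj
    raise TypeError("expected a RateSurface or callable rate(age, time)")


@dataclass
class MortalityModel:
    """Susceptible/diseased mortality split from overall mortality.

    ``m_all`` and ``prevalence`` are callables (age, time) -> value (a
    :class:`RateSurface` qualifies).  The implied ratio m1/m0 equals
    ``rr0`` at ``reference_time`` and declines linearly at ``rr_decline``
    per year, floored at 1.
    """

    m_all: RateLike
    prevalence: RateLike
    rr0: float = 1.4
    rr_decline: float = 0.01
    reference_time: float = 2019.0

    def __post_init__(self):
        if self.rr0 < 1:
            raise ValueError("rr0 must be >= 1")
        self.m_all = _as_fn(self.m_all)
        self.prevalence = _as_fn(self.prevalence)

    def rr(self, time):
        t = np.asarray(time, dtype=float)
        return np.maximum(1.0, self.rr0 - self.rr_decline * (t - self.reference_time))

    def m0(self, age, time):
        p = np.asarray(self.prevalence(age, time), dtype=float)
        if np.any(p >= 1.0):
            raise ValueError("prevalence = 1 leaves the susceptible rate undefined")
        return np.asarray(self.m_all(age, time), float) / (1.0 + p * (self.rr(time) - 1.0))

    def m1(self, age, time):
        return self.rr(time) * self.m0(age, time)


def build_mortality(
    m_all,
    prevalence,
    rr0: float = 1.4,
    rr_decline: float = 0.01,
    reference_time: float = 2019.0,
) -> MortalityModel:
    """Construct the two-group mortality model from overall mortality.

    Solves ``m_all = p*m1 + (1-p)*m0`` with ``m1 = RR(t)*m0`` pointwise.
    """
    return MortalityModel(
        m_all=m_all,
        prevalence=prevalence,
        rr0=rr0,
        rr_decline=rr_decline,
        reference_time=reference_time,
    )


def mortality_from_pyramid(pyramid: pd.DataFrame) -> pd.DataFrame:
    """Implied overall mortality records from cohort shrinkage.

    With zero migration, ``count(age+1, year+1) = count(age, year) *
    exp(-m_all)``, so ``m_all = -log(count(a+1, y+1)/count(a, y))``.
    Returns long records (sex, age, year, value) suitable for
    :func:`fit_rate_surface`; cells with non-shrinking cohorts get the
    rate floor.
    """
    rows = []
    for sex, grp in pyramid.groupby("sex"):
        tab = grp.pivot_table(index="age", columns="year", values="count")
        ages = tab.index.to_numpy()
        years = tab.columns.to_numpy()
        vals = tab.to_numpy(float)
        for ai in range(len(ages) - 1):
            for yi in range(len(years) - 1):
                n0, n1 = vals[ai, yi], vals[ai + 1, yi + 1]
                if n0 > 0 and n1 > 0:
                    m = max(-np.log(n1 / n0), LOG_FLOOR)
                    rows.append(
                        {"sex": sex, "age": ages[ai], "year": years[yi], "value": m}
                    )
    return pd.DataFrame(rows)
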