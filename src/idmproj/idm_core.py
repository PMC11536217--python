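"""Discrete-time illness-death model with remission.

The population is divided into three states: *susceptible* (S), *diseased*
(C) and *dead*.  Per time step of length ``tau`` (years), transitions are
governed by the incidence rate ``i`` (per person-year), the mortality rates
``m0`` (susceptible) and ``m1`` (diseased), and the per-step remission
probability ``r`` by which diseased individuals return to the susceptible
state.  The first-order difference scheme applies every flow to the
start-of-step stocks::

    S' = S * (1 - (i + m0)*tau) + r*C
    C' = C * (1 - m1*tau - r)   + i*tau*S

Dividing the two equations gives the equivalent recursion on the prevalence
odds ``pi = C/S = p/(1-p)``::

    pi' = (pi*(1 - m1*tau - r) + i*tau) / (1 - (i + m0)*tau + r*pi)

Solving that recursion for ``r`` lets the remission probability be
recovered from a prevalence series together with incidence and the two
mortality rates -- the model-inversion route used when no direct remission
data exist.

All operations are vectorised over a single-year age grid (default 0-95).
Aging is a separate bookkeeping step (:func:`advance_cohorts`), applied
once per whole simulated year.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: per-step transition probabilities (i*tau, m0*tau, m1*tau) must stay
#: below this bound for the explicit scheme to be well behaved
STABILITY_BOUND = 0.5

AGE_MAX_DEFAULT = 95


def _as_grid(x, n: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class StepRates:
    """Transition rates for one step on an age grid.

    ``i``, ``m0``, ``m1`` are rates per person-year; ``r`` is a per-step
    probability in [0, 1]; ``tau`` is the step length in years.  Scalars
    broadcast over the grid.
    """

    i: np.ndarray
    m0: np.ndarray
    m1: np.ndarray
    r: np.ndarray
    tau: float
    n_ages: int = AGE_MAX_DEFAULT + 1

    def __post_init__(self):
        n = int(self.n_ages)
        for name in ("i", "m0", "m1", "r"):
            object.__setattr__(self, name, _as_grid(getattr(self, name), n, name))
        object.__setattr__(self, "tau", float(self.tau))
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        for name in ("i", "m0", "m1"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if np.any((self.r < 0) | (self.r > 1)):
            raise ValueError("r must lie in [0, 1]")
        worst = max(
            float(np.max(self.i * self.tau)),
            float(np.max(self.m0 * self.tau)),
            float(np.max(self.m1 * self.tau)),
        )
        if worst >= STABILITY_BOUND:
            raise ValueError(
                f"per-step transition probability {worst:.3f} exceeds the "
                f"stability bound {STABILITY_BOUND}; use a smaller tau"
            )


@dataclass
class CompartmentState:
    """Counts of susceptible (S) and diseased (C) per single-year age bin."""

    time: float
    sex: str
    S: np.ndarray
    C: np.ndarray
    ages: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if self.ages is None:
            self.ages = np.arange(self.S.size)
        self.ages = np.asarray(self.ages)
        if not (self.S.shape == self.C.shape == self.ages.shape):
            raise ValueError("S, C and ages must share one age grid")
        if np.any(self.S < 0) or np.any(self.C < 0):
            raise ValueError("compartment counts must be nonnegative")

    @property
    def population(self) -> float:
        return float(self.S.sum() + self.C.sum())

    @property
    def cases(self) -> float:
        return float(self.C.sum())

    @property
    def prevalence(self) -> float:
        pop = self.population
        return self.cases / pop if pop > 0 else 0.0

    def odds(self) -> "PrevalenceOdds":
        with np.errstate(divide="ignore", invalid="ignore"):
            pi = np.where(self.S > 0, self.C / self.S, np.inf)
        pi = np.where((self.S == 0) & (self.C == 0), 0.0, pi)
        return PrevalenceOdds(pi=pi, time=self.time)


@dataclass
class PrevalenceOdds:
    """Prevalence odds pi = p/(1-p) on the age grid at one time point."""

    pi: np.ndarray
    time: float

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        if np.any(self.pi < 0):
            raise ValueError("odds must be nonnegative")

    @property
    def prevalence(self) -> np.ndarray:
        return self.pi / (1.0 + self.pi)


class ClampLog:
    """Tracks mass clamped away when a compartment would go negative.

    The explicit scheme can momentarily drive a stock slightly negative
    under extreme shocks at coarse steps; those cells are clamped to zero
    and the lost mass recorded so a run can fail loudly if clamping stops
    being negligible.
    """

    def __init__(self, tolerance_fraction: float = 1e-4):
        self.mass = 0.0
        self.count = 0
        self.tolerance_fraction = tolerance_fraction

    def record(self, mass: float, count: int) -> None:
        if count:
            self.mass += mass
            self.count += count
            logger.warning("clamped %d negative compartment cells (mass %.3g)", count, mass)

    def check(self, total_population: float) -> None:
        if total_population > 0 and self.mass > self.tolerance_fraction * total_population:
            raise RuntimeError(
                f"clamped mass {self.mass:.3g} exceeds "
                f"{self.tolerance_fraction:.0e} of population {total_population:.3g}"
            )


def step_compartments(
    state: CompartmentState, rates: StepRates, clamp_log: ClampLog | None = None
) -> CompartmentState:
    """Advance the (S, C) stocks by one step of length ``rates.tau``.

    Deaths leave the system; remission moves ``r*C`` back to susceptible;
    ``i*tau*S`` becomes newly diseased.
    """
    if state.S.size != rates.i.size:
        raise ValueError("state and rates are on different age grids")
    tau = rates.tau
    S, C = state.S, state.C
    S_new = S * (1.0 - (rates.i + rates.m0) * tau) + rates.r * C
    C_new = C * (1.0 - rates.m1 * tau - rates.r) + rates.i * tau * S
    neg = (S_new < 0) | (C_new < 0)
    if np.any(neg):
        lost = float(-(np.minimum(S_new, 0).sum() + np.minimum(C_new, 0).sum()))
        (clamp_log or ClampLog()).record(lost, int(neg.sum()))
        S_new = np.maximum(S_new, 0.0)
        C_new = np.maximum(C_new, 0.0)
    return CompartmentState(
        time=state.time + tau, sex=state.sex, S=S_new, C=C_new, ages=state.ages
    )


def step_odds(odds: PrevalenceOdds, rates: StepRates) -> PrevalenceOdds:
    """Advance the prevalence odds by one step.

    Algebraically identical to forming odds from :func:`step_compartments`
    output, but operates on ``pi`` directly so no absolute counts are
    needed.
    """
    pi = odds.pi
    if not np.all(np.isfinite(pi)):
        raise ValueError("odds are unbounded (prevalence reached 1)")
    if pi.size != rates.i.size:
        raise ValueError("odds and rates are on different age grids")
    tau = rates.tau
    num = pi * (1.0 - rates.m1 * tau - rates.r) + rates.i * tau
    den = 1.0 - (rates.i + rates.m0) * tau + rates.r * pi
    if np.any(den <= 0):
        raise ValueError("odds step denominator vanished; use a smaller tau")
    return PrevalenceOdds(pi=np.maximum(num / den, 0.0), time=odds.time + tau)


@dataclass
class RemissionEstimate:
    """Result of inverting the odds recursion for the remission probability.

    ``r`` has one row per step; NaN marks cells where the diseased mass is
    zero and remission is undefined.  ``n_clamped`` counts cells whose raw
    inverse fell outside [0, 1] and was clamped.
    """

    r: np.ndarray
    n_clamped: int
    missing: np.ndarray


def invert_remission(pi_k, pi_next, i, m0, m1, tau: float):
    """Solve the odds recursion for ``r`` given consecutive odds and rates.

    Returns (r_raw, defined_mask); ``r_raw`` is NaN where pi_k == 0.
    """
    pi_k = np.asarray(pi_k, dtype=float)
    pi_next = np.asarray(pi_next, dtype=float)
    i = np.asarray(i, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    m1 = np.asarray(m1, dtype=float)
    num = pi_k * (1.0 - m1 * tau) + i * tau - pi_next * (1.0 - (i + m0) * tau)
    den = pi_k * (1.0 + pi_next)
    defined = den > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(defined, num / np.where(defined, den, 1.0), np.nan)
    return r, defined


def estimate_remission(
    p_series: np.ndarray,
    i: np.ndarray,
    m0: np.ndarray,
    m1: np.ndarray,
    tau: float,
    along: str = "time",
) -> RemissionEstimate:
    """Estimate the per-step remission probability from a prevalence series.

    Parameters
    ----------
    p_series : array, shape (n_steps + 1, n_ages)
        Prevalence proportions in [0, 1), time-major.
    i, m0, m1 : arrays broadcastable to (n_steps, n_ages)
        Rates in force during each step, evaluated at the step's start cell.
    tau : step length in years.
    along : {"time", "cohort"}
        "time" pairs ``p[k, a]`` with ``p[k+1, a]`` (a pure time recursion
        per age cell); "cohort" pairs ``p[k, a]`` with ``p[k+1, a+1]``,
        the age-stratified reading where a step also ages the cohort by
        one bin (requires tau equal to the age-grid spacing).

    Values outside [0, 1] are clamped and counted; cells with zero
    prevalence at the step start are reported as NaN (missing), not
    clamped.
    """
    p = np.asarray(p_series, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("p_series must be (n_steps+1, n_ages) with >= 2 time points")
    if np.any((p < 0) | (p >= 1)):
        raise ValueError("prevalence values must lie in [0, 1)")
    n_steps, n_ages = p.shape[0] - 1, p.shape[1]
    i = np.broadcast_to(np.asarray(i, float), (n_steps, n_ages))
    m0 = np.broadcast_to(np.asarray(m0, float), (n_steps, n_ages))
    m1 = np.broadcast_to(np.asarray(m1, float), (n_steps, n_ages))
    pi = p / (1.0 - p)
    if along == "time":
        pi_k, pi_next = pi[:-1, :], pi[1:, :]
        ik, m0k, m1k = i, m0, m1
    elif along == "cohort":
        pi_k, pi_next = pi[:-1, :-1], pi[1:, 1:]
        ik, m0k, m1k = i[:, :-1], m0[:, :-1], m1[:, :-1]
    else:
        raise ValueError("along must be 'time' or 'cohort'")
    r_raw, defined = invert_remission(pi_k, pi_next, ik, m0k, m1k, tau)
    clamped = defined & ((r_raw < 0) | (r_raw > 1))
    r = np.where(defined, np.clip(r_raw, 0.0, 1.0), np.nan)
    return RemissionEstimate(r=r, n_clamped=int(clamped.sum()), missing=~defined)


def advance_cohorts(state: CompartmentState, births: float) -> CompartmentState:
    """Shift every cohort up one age bin; the oldest bin exits the analysis.

    ``births`` enter at age 0 as susceptible.  Call once per whole year of
    simulated time.
    """
    if births < 0:
        raise ValueError("births must be nonnegative")
    S = np.empty_like(state.S)
    C = np.empty_like(state.C)
    S[1:] = state.S[:-1]
    C[1:] = state.C[:-1]
    S[0] = births
    C[0] = 0.0
    return CompartmentState(time=state.time, sex=state.sex, S=S, C=C, ages=state.ages)
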