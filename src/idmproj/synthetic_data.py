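"""Synthetic study inputs with known ground truth.

Three input classes are emulated, matching the dialects the readers in
:mod:`idmproj.projection_engine` consume:

* a GBD-results-style long table of age-, sex- and year-specific incidence
  rates and prevalence proportions for a disorder over a historical window
  (default 1990-2019), generated so that the prevalence surface is
  *exactly* the forward simulation of the illness-death recursion under a
  known (i, m0, m1, r) ground truth -- the model-inversion estimate of
  remission therefore recovers r to machine precision;
* cohort-consistent population pyramids with annual births (no migration,
  deaths only), in the style of official population projections;
* a weekly epidemic incidence series composed of K Gaussian waves plus
  multiplicative lognormal noise, with the generating wave parameters
  carried alongside.

Ground-truth shapes: incidence is log-quadratic in age (a Gaussian bump on
the rate scale peaking in early adulthood) with a log-linear calendar
decline; remission is constant; mortality is Gompertz in age with a
log-linear calendar decline and a constant susceptible/diseased risk
ratio.  All shapes are free parameters of :class:`SynthConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._calendar import iso_week_midpoint, iso_weeks
from .idm_core import STABILITY_BOUND, PrevalenceOdds, StepRates, step_odds
from .wave_model import GaussianWave, WaveSet

SEXES = ("female", "male")

#: default wave layout: 7 pulses spanning early 2020 to late 2022 (rates
#: per 100,000 per week), centres separated by more than one FWHM
DEFAULT_WAVE_PARAMS = (
    (45.0, 2020.22, 0.045),
    (160.0, 2020.96, 0.075),
    (110.0, 2021.28, 0.055),
    (310.0, 2021.85, 0.070),
    (1250.0, 2022.10, 0.060),
    (550.0, 2022.52, 0.080),
    (260.0, 2022.88, 0.050),
)


@dataclass(frozen=True)
class BaseRates:
    """Parameters of the ground-truth transition-rate functions.

    Rates are per person-year; ``remission`` is the per-annual-step
    probability.  ``inc_peak`` gives the incidence at the modal age per
    sex; mortality is Gompertz ``mort_base * exp(mort_gompertz * age)``
    with log-linear calendar trends relative to ``time_ref``.
    """

    inc_peak: tuple = (("female", 0.009), ("male", 0.005))
    inc_age_mode: float = 18.0
    inc_age_width: float = 28.0
    inc_time_slope: float = -0.002
    remission: float = 0.08
    mort_base: float = 2.5e-5
    mort_gompertz: float = 0.085
    mort_time_slope: float = -0.01
    mort_rr: float = 1.4
    time_ref: float = 2000.0

    def incidence(self, age, time, sex: str):
        peak = dict(self.inc_peak)[sex]
        age = np.asarray(age, dtype=float)
        time = np.asarray(time, dtype=float)
        return (
            peak
            * np.exp(-((age - self.inc_age_mode) ** 2) / (2.0 * self.inc_age_width**2))
            * np.exp(self.inc_time_slope * (time - self.time_ref))
        )

    def m0(self, age, time, sex: str):
        age = np.asarray(age, dtype=float)
        time = np.asarray(time, dtype=float)
        return (
            self.mort_base
            * np.exp(self.mort_gompertz * age)
            * np.exp(self.mort_time_slope * (time - self.time_ref))
        )

    def m1(self, age, time, sex: str):
        return self.mort_rr * self.m0(age, time, sex)

    def r(self, age, time, sex: str):
        return np.broadcast_to(
            self.remission, np.broadcast_shapes(np.shape(age), np.shape(time))
        ).astype(float)


@dataclass(frozen=True)
class SynthConfig:
    """Configuration of all three synthetic generators (fully seeded)."""

    seed: int = 0
    age_max: int = 95
    years_history: tuple = (1990, 2019)
    years_projection: tuple = (2019, 2030)
    n_waves: int = 7
    wave_params: tuple = DEFAULT_WAVE_PARAMS
    noise_sd: float = 0.05
    base_rates: BaseRates = field(default_factory=BaseRates)
    births_per_sex: float = 360_000.0
    births_fluctuation: float = 0.02

    def __post_init__(self):
        if self.age_max < 1:
            raise ValueError("age_max must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_waves < 0:
            raise ValueError("n_waves must be >= 0")
        waves = tuple(self.wave_params)[: self.n_waves]
        if len(waves) != self.n_waves:
            raise ValueError("wave_params shorter than n_waves")
        centres = [w[1] for w in waves]
        if any(b <= a for a, b in zip(centres, centres[1:])):
            raise ValueError("wave centres must be strictly increasing")
        if any(w[2] <= 0 for w in waves):
            raise ValueError("wave s.d. must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class HistoryBundle:
    """Ground-truth gridded history for one sex, plus evaluation rules.

    ``prevalence`` etc. are (n_ages, n_years) arrays on ``ages`` x
    ``years``; the ``*_fn(age, time)`` callables evaluate the underlying
    smooth ground truth anywhere (including projection years).
    """

    sex: str
    ages: np.ndarray
    years: np.ndarray
    tau: float
    prevalence: np.ndarray
    incidence: np.ndarray
    mort_susceptible: np.ndarray
    mort_diseased: np.ndarray
    remission: np.ndarray
    incidence_fn: Callable
    m0_fn: Callable
    m1_fn: Callable
    r_fn: Callable
    prevalence_fn: Callable

    @property
    def mort_all(self) -> np.ndarray:
        p = self.prevalence
        return p * self.mort_diseased + (1.0 - p) * self.mort_susceptible


def _check_stability(config: SynthConfig, sex: str, tau: float) -> None:
    br = config.base_rates
    ages = np.arange(config.age_max + 1, dtype=float)
    # earliest birth cohort reaches back age_max years before the window
    t_lo = config.years_history[0] - config.age_max
    t_hi = config.years_projection[1] + 1
    for t in (t_lo, t_hi):
        worst = max(
            float(np.max(br.incidence(ages, t, sex) * tau)),
            float(np.max(br.m0(ages, t, sex) * tau)),
            float(np.max(br.m1(ages, t, sex) * tau)),
        )
        if worst >= STABILITY_BOUND:
            raise ValueError(
                f"ground-truth per-step probability {worst:.3f} at t={t} "
                f"exceeds the stability bound {STABILITY_BOUND}"
            )


def gen_consistent_history(config: SynthConfig, sex: str) -> HistoryBundle:
    """Generate a recursion-consistent (p, i, m0, m1, r) history for one sex.

    Every cohort is simulated from birth (prevalence 0 at age 0) with
    annual steps of the prevalence-odds recursion, so the returned
    prevalence grid satisfies the recursion exactly along cohort
    diagonals and the remission inversion recovers the ground truth.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}")
    tau = 1.0
    _check_stability(config, sex, tau)
    br = config.base_rates
    ages = np.arange(config.age_max + 1)
    y0, y1 = config.years_history
    years = np.arange(y0, y1 + 1)
    n_a, n_y = ages.size, years.size
    prev = np.zeros((n_a, n_y))
    # simulate each birth cohort along its diagonal
    for birth in range(y0 - config.age_max, y1 + 1):
        pi = 0.0
        for a in range(config.age_max + 1):
            t = birth + a
            if t > y1:
                break
            if y0 <= t <= y1:
                prev[a, t - y0] = pi / (1.0 + pi)
            rates = StepRates(
                i=br.incidence(float(a), float(t), sex),
                m0=br.m0(float(a), float(t), sex),
                m1=br.m1(float(a), float(t), sex),
                r=br.r(float(a), float(t), sex),
                tau=tau,
                n_ages=1,
            )
            pi = float(step_odds(PrevalenceOdds(pi=[pi], time=float(t)), rates).pi[0])
    A, Y = np.meshgrid(ages.astype(float), years.astype(float), indexing="ij")
    bundle = HistoryBundle(
        sex=sex,
        ages=ages,
        years=years,
        tau=tau,
        prevalence=prev,
        incidence=br.incidence(A, Y, sex),
        mort_susceptible=br.m0(A, Y, sex),
        mort_diseased=br.m1(A, Y, sex),
        remission=br.r(A, Y, sex),
        incidence_fn=lambda age, time, _s=sex: br.incidence(age, time, _s),
        m0_fn=lambda age, time, _s=sex: br.m0(age, time, _s),
        m1_fn=lambda age, time, _s=sex: br.m1(age, time, _s),
        r_fn=lambda age, time, _s=sex: br.r(age, time, _s),
        prevalence_fn=lambda age, time, _c=config, _s=sex: _prevalence_at(
            _c, _s, age, time
        ),
    )
    return bundle


def _prevalence_at(config: SynthConfig, sex: str, age, time):
    """Ground-truth prevalence at arbitrary (integer-age, integer-year) points."""
    age = np.atleast_1d(np.asarray(age))
    time = np.atleast_1d(np.asarray(time))
    age_b, time_b = np.broadcast_arrays(age, time)
    br = config.base_rates
    out = np.zeros(age_b.shape, dtype=float)
    it = np.nditer(age_b, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        a_target = int(age_b[idx])
        t_target = float(time_b[idx])
        birth = t_target - a_target
        pi = 0.0
        for a in range(a_target):
            t = birth + a
            rates = StepRates(
                i=br.incidence(float(a), t, sex),
                m0=br.m0(float(a), t, sex),
                m1=br.m1(float(a), t, sex),
                r=br.r(float(a), t, sex),
                tau=1.0,
                n_ages=1,
            )
            pi = float(step_odds(PrevalenceOdds(pi=[pi], time=t), rates).pi[0])
        out[idx] = pi / (1.0 + pi)
    return out if out.size > 1 else float(out.ravel()[0])


def gen_population(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort-consistent population pyramids and annual births.

    Returns ``(pyramid, births)``: the pyramid covers every calendar year
    from the history start to one past the projection end, ages 0 to
    ``age_max``, per sex; births give the age-0 intake per (sex, year).
    ``count(age+1, year+1) = count(age, year) * exp(-m_all(age, year))``
    exactly (deaths only, no migration).
    """
    br = config.base_rates
    ages = np.arange(config.age_max + 1)
    years = np.arange(config.years_history[0], config.years_projection[1] + 2)
    rng = config.rng(stream=1)
    rows = []
    birth_rows = []
    for sex in SEXES:
        fluct = np.exp(config.births_fluctuation * rng.standard_normal(years.size))
        births = config.births_per_sex * fluct
        m = br.m0(ages[:, None].astype(float), years[None, :].astype(float), sex)
        counts = np.zeros((ages.size, years.size))
        # initial pyramid: stationary population under year-0 mortality
        surv = np.exp(-np.concatenate([[0.0], np.cumsum(m[:-1, 0])]))
        counts[:, 0] = config.births_per_sex * surv
        counts[0, :] = births
        for yi in range(years.size - 1):
            counts[1:, yi + 1] = counts[:-1, yi] * np.exp(-m[:-1, yi])
        for yi, year in enumerate(years):
            birth_rows.append({"sex": sex, "year": int(year), "births": births[yi]})
            for ai, age in enumerate(ages):
                rows.append(
                    {
                        "age": int(age),
                        "sex": sex,
                        "year": int(year),
                        "count": counts[ai, yi],
                    }
                )
    return pd.DataFrame(rows), pd.DataFrame(birth_rows)


def gen_covid_series(config: SynthConfig) -> tuple[pd.DataFrame, WaveSet]:
    """Weekly epidemic incidence series plus its generating WaveSet.

    The series is the sum of ``n_waves`` Gaussians evaluated at ISO-week
    midpoints, perturbed by multiplicative lognormal noise of scale
    ``noise_sd`` and truncated at zero.
    """
    if config.n_waves < 1:
        raise ValueError("n_waves must be >= 1")
    waves = WaveSet(
        waves=[
            GaussianWave(amplitude=a, mu=mu, sigma=sd)
            for a, mu, sd in tuple(config.wave_params)[: config.n_waves]
        ]
    )
    weeks = iso_weeks(2020, 2022)
    times = np.array([iso_week_midpoint(y, w) for y, w in weeks])
    clean = waves(times)
    rng = config.rng(stream=2)
    noisy = clean * np.exp(config.noise_sd * rng.standard_normal(times.size))
    rates = np.maximum(noisy, 0.0)
    df = pd.DataFrame(
        {
            "week": [f"{y}-W{w:02d}" for y, w in weeks],
            "time": times,
            "rate": rates,
        }
    )
    return df, waves


# ---------------------------------------------------------------------------
# CSV writers (mirror the reader dialects in projection_engine)


def write_gbd_csv(histories: dict, path) -> None:
    """Write incidence/prevalence histories as GBD-style long CSV.

    Columns: measure, sex, age, year, val.  Incidence is written as a
    rate per person-year, prevalence as a proportion.
    """
    rows = []
    for sex, b in histories.items():
        for measure, grid in (("incidence", b.incidence), ("prevalence", b.prevalence)):
            for ai, age in enumerate(b.ages):
                for yi, year in enumerate(b.years):
                    rows.append(
                        {
                            "measure": measure,
                            "sex": sex,
                            "age": int(age),
                            "year": int(year),
                            "val": grid[ai, yi],
                        }
                    )
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def write_population_csv(pyramid: pd.DataFrame, births: pd.DataFrame, path) -> None:
    """Write the pyramid with a births column populated on age-0 rows."""
    merged = pyramid.merge(births, on=["sex", "year"], how="left")
    merged.loc[merged["age"] != 0, "births"] = np.nan
    merged.to_csv(Path(path), index=False, columns=["age", "sex", "year", "count", "births"])


def write_survstat_csv(series: pd.DataFrame, path) -> None:
    """Write the weekly series as (week, rate) CSV in ISO year-week notation."""
    series.to_csv(Path(path), index=False, columns=["week", "rate"])
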