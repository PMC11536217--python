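"""End-to-end projections, aggregation and file I/O.

The engine wires the pieces together per sex and scenario: initial
compartment counts are drawn from a prevalence rule applied to a
population pyramid at the start year; the illness-death recursion is
stepped weekly with the scenario's effective incidence (baseline rule
times ``1 + A(t)``); cohorts age one bin at each calendar-year boundary,
with the year's births entering at age 0; year-start case counts and
prevalence are recorded for every year of the horizon.

Remission rules are expressed as per-*year* probabilities and converted
to the step length internally via ``r_step = 1 - (1 - r_year)**tau``.

File dialects (all plain CSV):

* GBD-style long table: columns ``measure, sex, age, year, val``;
* pyramid: ``age, sex, year, count, births`` with births populated on the
  age-0 rows;
* weekly surveillance series: ``week, rate`` with ISO ``YYYY-Www`` weeks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ._calendar import iso_week_midpoint
from .idm_core import ClampLog, CompartmentState, StepRates, advance_cohorts, estimate_remission, step_compartments
from .shock_scenarios import ScenarioParams, ShockFunction, build_shock, scenario_grid
from .trend_models import MortalityModel, build_mortality, fit_rate_surface, mortality_from_pyramid
from .wave_model import WaveSet, fit_waves

SEXES = ("female", "male")
DEFAULT_HORIZON = (2019, 2031)
REPORT_YEARS = (2020, 2021, 2023, 2030)


# ---------------------------------------------------------------------------
# Readers


def _require_columns(df: pd.DataFrame, cols: set, path) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")


def _offending_rows(mask: pd.Series, limit: int = 5) -> str:
    # +2: one for the header line, one for 0-based indexing
    lines = [str(i + 2) for i in mask[mask].index[:limit]]
    more = "" if mask.sum() <= limit else f" (+{int(mask.sum()) - limit} more)"
    return ", ".join(lines) + more


def read_gbd_csv(path) -> pd.DataFrame:
    """Read and validate a GBD-style long CSV of rate observations."""
    df = pd.read_csv(path)
    _require_columns(df, {"measure", "sex", "age", "year", "val"}, path)
    bad_sex = ~df["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValueError(f"{path}: unknown sex at line(s) {_offending_rows(bad_sex)}")
    bad_age = (df["age"] < 0) | (df["age"] > 95)
    if bad_age.any():
        raise ValueError(f"{path}: age outside 0-95 at line(s) {_offending_rows(bad_age)}")
    bad_val = (df["val"] < 0) | df["val"].isna()
    if bad_val.any():
        raise ValueError(
            f"{path}: negative or missing value at line(s) {_offending_rows(bad_val)}"
        )
    return df


def read_population(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a pyramid CSV; returns (pyramid, births) frames."""
    df = pd.read_csv(path)
    _require_columns(df, {"age", "sex", "year", "count"}, path)
    bad = (df["count"] < 0) | df["count"].isna()
    if bad.any():
        raise ValueError(f"{path}: negative or missing count at line(s) {_offending_rows(bad)}")
    pyramid = df[["age", "sex", "year", "count"]].copy()
    if "births" in df.columns:
        births = (
            df.loc[df["age"] == 0, ["sex", "year", "births"]]
            .dropna(subset=["births"])
            .reset_index(drop=True)
        )
    else:
        births = df.loc[df["age"] == 0, ["sex", "year", "count"]].rename(
            columns={"count": "births"}
        )
    return pyramid, births


def parse_iso_week(label: str) -> tuple[int, int]:
    try:
        year_s, week_s = str(label).split("-W")
        return int(year_s), int(week_s)
    except (ValueError, AttributeError):
        raise ValueError(f"unparseable ISO week label {label!r}") from None


def read_survstat_csv(path) -> pd.DataFrame:
    """Read a weekly surveillance CSV; adds decimal-year week midpoints."""
    df = pd.read_csv(path)
    _require_columns(df, {"week", "rate"}, path)
    bad = (df["rate"] < 0) | df["rate"].isna()
    if bad.any():
        raise ValueError(f"{path}: negative or missing rate at line(s) {_offending_rows(bad)}")
    times = []
    for i, label in enumerate(df["week"]):
        try:
            y, w = parse_iso_week(label)
            times.append(iso_week_midpoint(y, w))
        except ValueError as e:
            raise ValueError(f"{path}: line {i + 2}: {e}") from None
    out = df.copy()
    out["time"] = times
    return out[["week", "time", "rate"]]


# ---------------------------------------------------------------------------
# Study assembly


@dataclass
class ProjectionInputs:
    """Everything a projection run needs, per sex.

    ``incidence``, ``m0``, ``m1`` map sex -> callable (age, time) -> rate
    per person-year; ``remission`` maps sex -> callable returning the
    per-year remission probability; ``births`` maps (sex, year) -> age-0
    intake applied at that year's end boundary.
    """

    initial: dict
    incidence: dict
    m0: dict
    m1: dict
    remission: dict
    births: dict
    sexes: tuple = SEXES


def initialise_states(prevalence, pyramid: pd.DataFrame, start_year: float, sexes=SEXES) -> dict:
    """Split the start-year pyramid into (S, C) by the prevalence rule.

    ``prevalence`` maps sex -> callable (age, time) -> proportion.
    """
    states = {}
    for sex in sexes:
        sub = pyramid[(pyramid["sex"] == sex) & (pyramid["year"] == int(start_year))]
        if sub.empty:
            raise ValueError(f"pyramid does not cover year {start_year} for sex {sex!r}")
        sub = sub.sort_values("age")
        ages = sub["age"].to_numpy()
        counts = sub["count"].to_numpy(float)
        p = np.asarray(prevalence[sex](ages.astype(float), float(start_year)), float)
        if np.any(p > 1):
            raise ValueError("prevalence exceeds 1; cannot initialise compartments")
        C = p * counts
        states[sex] = CompartmentState(
            time=float(start_year), sex=sex, S=counts - C, C=C, ages=ages
        )
    return states


@dataclass
class _RateArrays:
    week_times: np.ndarray
    i: np.ndarray
    m0: np.ndarray
    m1: np.ndarray
    r_step: np.ndarray


def _precompute(inputs: ProjectionInputs, sex: str, years: np.ndarray, spy: int) -> _RateArrays:
    tau = 1.0 / spy
    week_times = (years[:-1, None] + np.arange(spy)[None, :] / spy).ravel()
    ages = inputs.initial[sex].ages.astype(float)[:, None]
    t = week_times[None, :]
    r_year = np.clip(np.broadcast_to(np.asarray(inputs.remission[sex](ages, t), float),
                                     (ages.size, week_times.size)), 0.0, 1.0)
    bc = (ages.size, week_times.size)
    return _RateArrays(
        week_times=week_times,
        i=np.broadcast_to(np.asarray(inputs.incidence[sex](ages, t), float), bc).copy(),
        m0=np.broadcast_to(np.asarray(inputs.m0[sex](ages, t), float), bc).copy(),
        m1=np.broadcast_to(np.asarray(inputs.m1[sex](ages, t), float), bc).copy(),
        r_step=1.0 - (1.0 - r_year) ** tau,
    )


# ---------------------------------------------------------------------------
# Projection


@dataclass
class ProjectionResult:
    """Annual aggregates for one scenario and sex (year-start values)."""

    scenario_id: int
    sex: str
    years: np.ndarray
    cases: np.ndarray
    population: np.ndarray
    trajectory: dict | None = None

    @property
    def prevalence_pct(self) -> np.ndarray:
        return 100.0 * self.cases / self.population

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "scenario": self.scenario_id,
                "sex": self.sex,
                "year": self.years,
                "cases": self.cases,
                "population": self.population,
                "prevalence_pct": self.prevalence_pct,
            }
        )


def _simulate_sex(
    sex: str,
    state0: CompartmentState,
    arrays: _RateArrays,
    shock_vec: np.ndarray,
    inputs: ProjectionInputs,
    years: np.ndarray,
    spy: int,
    scenario_id: int,
    keep_trajectory: bool = False,
) -> ProjectionResult:
    tau = 1.0 / spy
    clamp_log = ClampLog()
    state = CompartmentState(
        time=float(years[0]), sex=sex, S=state0.S.copy(), C=state0.C.copy(), ages=state0.ages
    )
    n = state.S.size
    rec_cases, rec_pop = [], []
    trajectory = {} if keep_trajectory else None
    week = 0
    for year in years[:-1]:
        rec_cases.append(state.cases)
        rec_pop.append(state.population)
        if keep_trajectory:
            trajectory[int(year)] = (state.S.copy(), state.C.copy())
        for _ in range(spy):
            rates = StepRates(
                i=arrays.i[:, week] * (1.0 + shock_vec[week]),
                m0=arrays.m0[:, week],
                m1=arrays.m1[:, week],
                r=arrays.r_step[:, week],
                tau=tau,
                n_ages=n,
            )
            state = step_compartments(state, rates, clamp_log)
            week += 1
        key = (sex, int(year))
        if key not in inputs.births:
            raise ValueError(f"no births entry for {key}")
        state = advance_cohorts(state, inputs.births[key])
    rec_cases.append(state.cases)
    rec_pop.append(state.population)
    if keep_trajectory:
        trajectory[int(years[-1])] = (state.S.copy(), state.C.copy())
    clamp_log.check(state.population)
    return ProjectionResult(
        scenario_id=scenario_id,
        sex=sex,
        years=years.copy(),
        cases=np.asarray(rec_cases),
        population=np.asarray(rec_pop),
        trajectory=trajectory,
    )


def run_projection(
    inputs: ProjectionInputs,
    scenario: ScenarioParams,
    waves: WaveSet | None = None,
    horizon: tuple = DEFAULT_HORIZON,
    steps_per_year: int = 52,
    shape: str = "trapezoid",
    keep_trajectory: bool = False,
) -> list[ProjectionResult]:
    """Project one scenario over the horizon; returns one result per sex."""
    if not scenario.is_baseline and waves is None:
        raise ValueError("non-baseline scenarios need a fitted WaveSet")
    years = np.arange(horizon[0], horizon[1] + 1)
    shock = build_shock(scenario, waves, shape=shape) if not scenario.is_baseline else ShockFunction([])
    out = []
    for sex in inputs.sexes:
        arrays = _precompute(inputs, sex, years, steps_per_year)
        shock_vec = np.asarray(shock(arrays.week_times), float)
        out.append(
            _simulate_sex(
                sex, inputs.initial[sex], arrays, shock_vec, inputs, years,
                steps_per_year, scenario.scenario_id, keep_trajectory,
            )
        )
    return out


def run_grid(
    inputs: ProjectionInputs,
    waves: WaveSet,
    scenarios: list[ScenarioParams] | None = None,
    horizon: tuple = DEFAULT_HORIZON,
    steps_per_year: int = 52,
    shape: str = "trapezoid",
) -> list[ProjectionResult]:
    """Project every scenario (default: all 82), reusing baseline rate arrays."""
    scenarios = scenarios if scenarios is not None else scenario_grid()
    years = np.arange(horizon[0], horizon[1] + 1)
    arrays = {sex: _precompute(inputs, sex, years, steps_per_year) for sex in inputs.sexes}
    results = []
    for scenario in scenarios:
        shock = (
            ShockFunction([])
            if scenario.is_baseline
            else build_shock(scenario, waves, shape=shape)
        )
        for sex in inputs.sexes:
            shock_vec = np.asarray(shock(arrays[sex].week_times), float)
            results.append(
                _simulate_sex(
                    sex, inputs.initial[sex], arrays[sex], shock_vec, inputs,
                    years, steps_per_year, scenario.scenario_id,
                )
            )
    return results


def summarise(results, years, scenarios=None) -> pd.DataFrame:
    """Long summary table (scenario, sex, year, cases, millions, prevalence %).

    Case counts are reported raw and in millions (2 d.p.); prevalence in
    percent (2 d.p.).
    """
    years = [int(y) for y in years]
    rows = []
    seen_scenarios = set()
    for res in results:
        seen_scenarios.add(res.scenario_id)
        if scenarios is not None and res.scenario_id not in scenarios:
            continue
        available = set(int(y) for y in res.years)
        for y in years:
            if y not in available:
                raise ValueError(f"year {y} outside projection horizon")
            k = int(np.flatnonzero(res.years == y)[0])
            rows.append(
                {
                    "scenario": res.scenario_id,
                    "sex": res.sex,
                    "year": y,
                    "cases": res.cases[k],
                    "cases_millions": round(res.cases[k] / 1e6, 2),
                    "prevalence_pct": round(res.prevalence_pct[k], 2),
                }
            )
    if scenarios is not None:
        unknown = set(scenarios) - seen_scenarios
        if unknown:
            raise ValueError(f"unknown scenario(s) {sorted(unknown)}")
    return (
        pd.DataFrame(rows)
        .sort_values(["scenario", "sex", "year"])
        .reset_index(drop=True)
    )


def plot_prevalence(results, path, sex: str, scenarios=None) -> None:
    """Basic prevalence-vs-year plot for one sex (one line per scenario)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for res in results:
        if res.sex != sex:
            continue
        if scenarios is not None and res.scenario_id not in scenarios:
            continue
        ax.plot(res.years, res.prevalence_pct, label=f"scenario {res.scenario_id}")
    ax.set_xlabel("year")
    ax.set_ylabel("prevalence (%)")
    ax.set_title(f"Projected prevalence, {sex}")
    ax.legend(fontsize=7, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# High-level study builders


def build_synthetic_study(config) -> tuple[ProjectionInputs, WaveSet, pd.DataFrame]:
    """Assemble projection inputs from the synthetic generators.

    Uses the ground-truth rate rules directly (the fitted-surface route is
    exercised by :func:`build_study_from_files`).  Returns
    ``(inputs, ground_truth_waves, weekly_series)``.
    """
    from .synthetic_data import gen_consistent_history, gen_covid_series, gen_population

    start_year = config.years_projection[0]
    histories = {sex: gen_consistent_history(config, sex) for sex in SEXES}
    pyramid, births_df = gen_population(config)
    series, waves = gen_covid_series(config)
    births = {
        (row["sex"], int(row["year"])): float(row["births"])
        for _, row in births_df.iterrows()
    }
    yi = {sex: int(np.flatnonzero(histories[sex].years == start_year)[0]) for sex in SEXES}
    prevalence = {
        sex: (lambda age, time, _b=histories[sex], _k=yi[sex]: _b.prevalence[
            np.asarray(age, int), _k
        ])
        for sex in SEXES
    }
    initial = initialise_states(prevalence, pyramid, start_year)
    inputs = ProjectionInputs(
        initial=initial,
        incidence={sex: histories[sex].incidence_fn for sex in SEXES},
        m0={sex: histories[sex].m0_fn for sex in SEXES},
        m1={sex: histories[sex].m1_fn for sex in SEXES},
        remission={sex: histories[sex].r_fn for sex in SEXES},
        births=births,
    )
    return inputs, waves, series


def _remission_profile(p_grid, i_grid, m0_grid, m1_grid, ages) -> Callable:
    """Constant-in-time per-age remission rule from cohort inversion.

    ``p_grid`` etc. are (n_years, n_ages) annual grids.  The per-age
    profile is the median over the last up-to-5 cohort transitions;
    undefined cells fall back to the overall median.
    """
    est = estimate_remission(p_grid, i_grid[:-1], m0_grid[:-1], m1_grid[:-1], tau=1.0, along="cohort")
    tail = est.r[-5:]
    with np.errstate(invalid="ignore"):
        profile = np.nanmedian(tail, axis=0)
    overall = np.nanmedian(est.r)
    if np.isnan(overall):
        overall = 0.0
    profile = np.where(np.isnan(profile), overall, np.clip(profile, 0.0, 1.0))
    # profile covers ages[:-1]; extend to the last age bin
    full = np.append(profile, profile[-1])
    ages = np.asarray(ages)

    def r_fn(age, time, _full=full, _ages=ages):
        idx = np.clip(np.searchsorted(_ages, np.asarray(age)), 0, _ages.size - 1)
        out = _full[idx]
        return np.broadcast_to(out, np.broadcast_shapes(np.shape(age), np.shape(time)))

    return r_fn


def build_study_from_files(
    gbd_csv,
    population_csv,
    survstat_csv,
    start_year: int = 2019,
    rr0: float = 1.4,
    rr_decline: float = 0.01,
    k_waves: int = 7,
    age_knots=None,
    time_knots=None,
) -> tuple[ProjectionInputs, WaveSet]:
    """Build a full study from the three input files.

    Fits incidence/prevalence spline surfaces per sex from the GBD-style
    table, derives overall mortality from cohort shrinkage of the pyramid
    and splits it by the declining risk ratio, estimates remission by
    model inversion (held constant over age profile into the future), and
    fits the wave decomposition from the weekly series.
    """
    gbd = read_gbd_csv(gbd_csv)
    pyramid, births_df = read_population(population_csv)
    series = read_survstat_csv(survstat_csv)

    surfaces = {}
    for sex in SEXES:
        for measure in ("incidence", "prevalence"):
            sub = gbd[(gbd["sex"] == sex) & (gbd["measure"] == measure)]
            if sub.empty:
                raise ValueError(f"no {measure} records for sex {sex!r}")
            surfaces[(sex, measure)] = fit_rate_surface(
                sub.rename(columns={"val": "value"}),
                measure=measure,
                sex=sex,
                age_knots=age_knots,
                time_knots=time_knots,
            )

    mort_records = mortality_from_pyramid(pyramid)
    mortality = {}
    for sex in SEXES:
        m_all = fit_rate_surface(
            mort_records[mort_records["sex"] == sex],
            measure="mortality_all",
            sex=sex,
            age_knots=age_knots,
            time_knots=time_knots,
        )
        mortality[sex] = build_mortality(
            m_all,
            surfaces[(sex, "prevalence")],
            rr0=rr0,
            rr_decline=rr_decline,
            reference_time=float(start_year),
        )

    ages = np.arange(0, 96)
    years_hist = np.arange(int(gbd["year"].min()), int(gbd["year"].max()) + 1)
    remission = {}
    for sex in SEXES:
        A, Y = np.meshgrid(ages.astype(float), years_hist.astype(float), indexing="xy")
        p_grid = surfaces[(sex, "prevalence")](A, Y)
        i_grid = surfaces[(sex, "incidence")](A, Y)
        m0_grid = mortality[sex].m0(A, Y)
        m1_grid = mortality[sex].m1(A, Y)
        remission[sex] = _remission_profile(p_grid, i_grid, m0_grid, m1_grid, ages)

    waves = fit_waves(series["time"], series["rate"], k=k_waves)
    births = {
        (row["sex"], int(row["year"])): float(row["births"])
        for _, row in births_df.iterrows()
    }
    prevalence_rules = {sex: surfaces[(sex, "prevalence")] for sex in SEXES}
    initial = initialise_states(prevalence_rules, pyramid, start_year)
    inputs = ProjectionInputs(
        initial=initial,
        incidence={sex: surfaces[(sex, "incidence")] for sex in SEXES},
        m0={sex: mortality[sex].m0 for sex in SEXES},
        m1={sex: mortality[sex].m1 for sex in SEXES},
        remission=remission,
        births=births,
    )
    return inputs, waves
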