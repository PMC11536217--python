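"""Tests for initialisation, projection orchestration, summaries and I/O."""

import numpy as np
import pandas as pd
import pytest

from idmproj._calendar import iso_week_midpoint
from idmproj.projection_engine import (
    build_study_from_files,
    initialise_states,
    read_gbd_csv,
    read_population,
    read_survstat_csv,
    run_grid,
    run_projection,
    summarise,
)
from idmproj.shock_scenarios import ScenarioParams, scenario_grid
from idmproj.synthetic_data import (
    SynthConfig,
    gen_consistent_history,
    gen_covid_series,
    gen_population,
    write_gbd_csv,
    write_population_csv,
    write_survstat_csv,
)


def flat_pyramid(n=1000.0, year=2019):
    rows = [
        {"age": a, "sex": sex, "year": year, "count": n}
        for sex in ("female", "male")
        for a in range(96)
    ]
    return pd.DataFrame(rows)


class TestInitialiseStates:
    def test_zero_prevalence(self):
        rules = {s: (lambda age, t: np.zeros_like(np.asarray(age, float))) for s in ("female", "male")}
        states = initialise_states(rules, flat_pyramid(), 2019)
        assert np.all(states["female"].C == 0)
        assert np.all(states["female"].S == 1000.0)

    def test_uniform_prevalence_split(self):
        rules = {s: (lambda age, t: np.full_like(np.asarray(age, float), 0.1)) for s in ("female", "male")}
        states = initialise_states(rules, flat_pyramid(), 2019)
        assert np.allclose(states["male"].C, 100.0)
        assert np.allclose(states["male"].S, 900.0)

    def test_population_conserved(self, study):
        inputs, _, _ = study
        pyramid, _ = gen_population(SynthConfig(seed=1))
        for sex in ("female", "male"):
            total = pyramid[(pyramid["sex"] == sex) & (pyramid["year"] == 2019)]["count"].sum()
            assert inputs.initial[sex].population == pytest.approx(total)

    def test_prevalence_above_one_rejected(self):
        rules = {s: (lambda age, t: np.full_like(np.asarray(age, float), 1.5)) for s in ("female", "male")}
        with pytest.raises(ValueError, match="prevalence"):
            initialise_states(rules, flat_pyramid(), 2019)

    def test_missing_year_rejected(self):
        rules = {s: (lambda age, t: np.zeros_like(np.asarray(age, float))) for s in ("female", "male")}
        with pytest.raises(ValueError, match="cover"):
            initialise_states(rules, flat_pyramid(year=2000), 2019)


class TestRunProjection:
    def test_null_shock_matches_baseline(self, study, fitted_waves):
        """A scenario whose peak increase is zero reproduces scenario 0."""
        inputs, _, _ = study
        baseline = run_projection(inputs, scenario_grid()[0])
        null = ScenarioParams(scenario_id=1, w_in=0.2, w_out=0.2, delta=0.5, h0=0.0, lam=0.1)
        shocked = run_projection(inputs, null, fitted_waves)
        for b, s in zip(baseline, shocked):
            assert np.array_equal(b.cases, s.cases)
            assert np.array_equal(b.population, s.population)

    def test_shock_elevates_prevalence(self, study, fitted_waves):
        inputs, _, _ = study
        grid = {s.scenario_id: s for s in scenario_grid()}
        base = {r.sex: r for r in run_projection(inputs, grid[0])}
        for sid in (19, 61):
            for res in run_projection(inputs, grid[sid], fitted_waves):
                gap = res.prevalence_pct - base[res.sex].prevalence_pct
                post = res.years >= 2021
                assert np.all(gap[post] > 0)
                assert np.all(gap >= -1e-12)

    def test_extreme_scenario_dominates_mild(self, study, fitted_waves):
        """Large-delay/small-decay/h0=10 peaks above no-delay/large-decay/h0=1."""
        inputs, _, _ = study
        grid = {s.scenario_id: s for s in scenario_grid()}
        extreme = run_projection(inputs, grid[61], fitted_waves)
        mild = run_projection(inputs, grid[19], fitted_waves)
        for e, m in zip(extreme, mild):
            assert e.prevalence_pct.max() > m.prevalence_pct.max()

    def test_prevalence_identity(self, study, fitted_waves):
        inputs, _, _ = study
        for res in run_projection(inputs, scenario_grid()[61], fitted_waves):
            assert np.allclose(
                res.prevalence_pct, 100.0 * res.cases / res.population, rtol=1e-12
            )

    def test_post_shock_gap_relaxes(self, study, fitted_waves):
        """After the last wash-out the shocked-vs-baseline gap shrinks."""
        inputs, _, _ = study
        base = {r.sex: r for r in run_projection(inputs, scenario_grid()[0])}
        for res in run_projection(inputs, scenario_grid()[61], fitted_waves):
            gap = res.cases - base[res.sex].cases
            tail = gap[res.years >= 2024]
            assert np.all(np.diff(tail) < 0)

    def test_trajectory_on_request(self, study):
        inputs, _, _ = study
        res = run_projection(inputs, scenario_grid()[0], keep_trajectory=True)[0]
        assert set(res.trajectory) == set(int(y) for y in res.years)
        S, C = res.trajectory[2025]
        assert S.shape == (96,)

    def test_waves_required_for_shocked_scenarios(self, study):
        inputs, _, _ = study
        with pytest.raises(ValueError, match="WaveSet"):
            run_projection(inputs, scenario_grid()[61], waves=None)

    def test_determinism(self, study, fitted_waves):
        inputs, _, _ = study
        r1 = run_projection(inputs, scenario_grid()[13], fitted_waves)
        r2 = run_projection(inputs, scenario_grid()[13], fitted_waves)
        t1 = summarise(r1, [2020, 2030]).to_csv()
        t2 = summarise(r2, [2020, 2030]).to_csv()
        assert t1 == t2


class TestSummarise:
    def test_row_counts(self, study, fitted_waves):
        inputs, _, _ = study
        scenarios = scenario_grid()[:3]
        results = run_grid(inputs, fitted_waves, scenarios=scenarios)
        tab = summarise(results, [2020, 2021, 2023, 2030])
        assert len(tab) == 3 * 2 * 4
        one = summarise(results, [2030], scenarios=[2])
        assert len(one) == 2  # one row per sex

    def test_millions_rounding(self):
        from idmproj.projection_engine import ProjectionResult

        res = ProjectionResult(
            scenario_id=0,
            sex="female",
            years=np.array([2030]),
            cases=np.array([3_861_234.0]),
            population=np.array([38_761_000.0]),
        )
        tab = summarise([res], [2030])
        assert tab.loc[0, "cases_millions"] == 3.86

    def test_unknown_year_rejected(self, study):
        inputs, _, _ = study
        results = run_projection(inputs, scenario_grid()[0])
        with pytest.raises(ValueError, match="horizon"):
            summarise(results, [1980])

    def test_unknown_scenario_rejected(self, study):
        inputs, _, _ = study
        results = run_projection(inputs, scenario_grid()[0])
        with pytest.raises(ValueError, match="scenario"):
            summarise(results, [2030], scenarios=[55])


class TestReaders:
    def test_gbd_round_trip(self, tmp_path, config):
        histories = {s: gen_consistent_history(config, s) for s in ("female", "male")}
        path = tmp_path / "gbd.csv"
        write_gbd_csv(histories, path)
        df = read_gbd_csv(path)
        sub = df[(df.measure == "prevalence") & (df.sex == "female")]
        grid = sub.pivot_table(index="age", columns="year", values="val").to_numpy()
        assert np.allclose(grid, histories["female"].prevalence)

    def test_population_round_trip(self, tmp_path, config):
        pyramid, births = gen_population(config)
        path = tmp_path / "population.csv"
        write_population_csv(pyramid, births, path)
        pyr2, births2 = read_population(path)
        assert np.allclose(
            pyr2.sort_values(["sex", "year", "age"])["count"].to_numpy(),
            pyramid.sort_values(["sex", "year", "age"])["count"].to_numpy(),
        )
        m = births.merge(births2, on=["sex", "year"], suffixes=("", "_rt"))
        assert np.allclose(m["births"], m["births_rt"])

    def test_survstat_round_trip(self, tmp_path, covid_series):
        series, _ = covid_series
        path = tmp_path / "survstat.csv"
        write_survstat_csv(series, path)
        df = read_survstat_csv(path)
        assert np.allclose(df["rate"], series["rate"])
        assert np.allclose(df["time"], series["time"])

    def test_iso_week_midpoint(self):
        assert 2019.99 <= iso_week_midpoint(2020, 1) <= 2020.03
        # ISO weeks advance monotonically across a 53-week year
        times = [iso_week_midpoint(2020, w) for w in range(1, 54)]
        assert np.all(np.diff(times) > 0)

    def test_negative_rate_row_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("week,rate\n2020-W01,5.0\n2020-W02,-1.0\n")
        with pytest.raises(ValueError, match="line\\(s\\) 3"):
            read_survstat_csv(path)

    def test_unparseable_week_named(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("week,rate\n2020-XX,5.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_survstat_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("measure,sex,age,year\nincidence,female,0,1990\n")
        with pytest.raises(ValueError, match="val"):
            read_gbd_csv(path)

    def test_unknown_sex_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("measure,sex,age,year,val\nincidence,other,0,1990,0.1\n")
        with pytest.raises(ValueError, match="sex"):
            read_gbd_csv(path)


class TestFileDrivenStudy:
    @pytest.fixture(scope="class")
    @staticmethod
    def files(tmp_path_factory, config):
        d = tmp_path_factory.mktemp("inputs")
        histories = {s: gen_consistent_history(config, s) for s in ("female", "male")}
        write_gbd_csv(histories, d / "gbd.csv")
        pyramid, births = gen_population(config)
        write_population_csv(pyramid, births, d / "population.csv")
        series, _ = gen_covid_series(config)
        write_survstat_csv(series, d / "survstat.csv")
        return d, histories

    def test_fitted_study_tracks_ground_truth(self, files, study):
        """The fitted pipeline reproduces the ground-truth baseline closely."""
        d, histories = files
        inputs, waves = build_study_from_files(
            d / "gbd.csv", d / "population.csv", d / "survstat.csv"
        )
        assert len(waves) == 7
        fitted = {r.sex: r for r in run_projection(inputs, scenario_grid()[0])}
        truth_inputs, _, _ = study
        truth = {r.sex: r for r in run_projection(truth_inputs, scenario_grid()[0])}
        for sex in ("female", "male"):
            rel = np.abs(fitted[sex].prevalence_pct - truth[sex].prevalence_pct) / truth[
                sex
            ].prevalence_pct
            assert np.max(rel) < 0.10
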