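import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from n2oproj.errors import (
    ConfigError,
    InvalidArgumentError,
    UndefinedBaselineError,
)
from n2oproj.pipeline import run_all_scenarios, run_scenario
from n2oproj.projection_core import (
    ConversionConstants,
    ReductionGoal,
    cumulative_target_year,
    ensemble_summary,
    mitigation_potential,
    project_scenario,
    regional_totals,
    relative_change,
    static_dynamic_gap,
)
from n2oproj.scenario_fertilizer import default_scenario, build_scenario_field
from n2oproj.synthetic_world import generate_climate

from conftest import make_uniform_domain


def naive_percentile(values, q):
    """Independent linear-interpolation percentile (sort-based)."""
    xs = sorted(values)
    h = (len(xs) - 1) * q / 100.0
    lo = int(np.floor(h))
    hi = min(lo + 1, len(xs) - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


class TestEnsembleSummary:
    def test_identical_members(self):
        s = ensemble_summary(np.tile([2.0, 3.0], (5, 1)), [2010, 2011])
        assert (s["p25"] == s["median"]).all()
        assert (s["median"] == s["p75"]).all()

    def test_textbook_median(self):
        s = ensemble_summary(np.array([[1.0], [2.0], [3.0], [4.0]]), [2010])
        assert s["median"][0] == pytest.approx(2.5)

    def test_against_naive_oracle(self):
        rng = np.random.default_rng(0)
        members = rng.uniform(0, 10, size=(37, 4))
        s = ensemble_summary(members, [2010, 2011, 2012, 2013])
        for j in range(4):
            assert s["median"][j] == pytest.approx(naive_percentile(members[:, j], 50))
            assert s["p25"][j] == pytest.approx(naive_percentile(members[:, j], 25))
            assert s["p75"][j] == pytest.approx(naive_percentile(members[:, j], 75))

    def test_band_contains_median(self):
        rng = np.random.default_rng(1)
        s = ensemble_summary(rng.uniform(0, 5, (9, 6)), np.arange(2010, 2016))
        assert (s["p25"] <= s["median"]).all()
        assert (s["median"] <= s["p75"]).all()

    def test_empty_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ensemble_summary(np.empty((0, 0)), [])


class TestRelativeChange:
    def test_zero_change(self):
        s = pd.Series({2010: 1.5, 2030: 1.5})
        assert relative_change(s)[2030] == pytest.approx(0.0)

    def test_printed_reduction_56(self):
        s = pd.Series({2010: 1.46, 2030: 0.64})
        assert round(relative_change(s)[2030]) == -56

    def test_printed_reduction_45(self):
        s = pd.Series({2010: 1.46, 2050: 0.81})
        assert round(relative_change(s)[2050]) == -45

    def test_zero_baseline(self):
        with pytest.raises(UndefinedBaselineError):
            relative_change(pd.Series({2010: 0.0, 2030: 1.0}))


class TestCumulativeTargetYear:
    def test_flat_series_never(self):
        years = np.arange(2010, 2051)
        s = pd.Series(1.0, index=years)
        for basis in ("annual", "cumulative"):
            assert cumulative_target_year(s, ReductionGoal(0.25, basis)) is None

    def test_step_series(self):
        years = np.arange(2010, 2031)
        vals = np.where(years >= 2020, 0.5, 1.0)
        s = pd.Series(vals, index=years)
        assert cumulative_target_year(s, ReductionGoal(0.25, "annual")) == 2020

    def _oracle_scan(self, s, goal):
        """Exhaustive year-scan oracle for both bases."""
        base = s.loc[2010]
        thr = (1 - goal.goal_fraction) * base
        years = [y for y in s.index if y > 2010]
        if goal.basis == "annual":
            hits = [y for y in years if s.loc[y] <= thr]
        else:
            hits = []
            for y in years:
                cum = sum(s.loc[yy] for yy in years if yy <= y)
                if cum <= thr * (y - 2010):
                    hits.append(y)
        return min(hits) if hits else None

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_scan(self, seed):
        rng = np.random.default_rng(seed)
        years = np.arange(2010, 2051)
        # declining-after-peak series with noise
        vals = 1.0 + 0.3 * rng.random() - 0.02 * (years - 2015) \
            + 0.05 * rng.standard_normal(years.size)
        vals = np.clip(vals, 0.01, None)
        s = pd.Series(vals, index=years)
        for basis in ("annual", "cumulative"):
            goal = ReductionGoal(0.25, basis)
            assert cumulative_target_year(s, goal) == self._oracle_scan(s, goal)

    def test_cumulative_lags_annual(self):
        """Monotone-declining series: cumulative goal year >= annual year."""
        years = np.arange(2010, 2051)
        vals = np.maximum(1.0 - 0.03 * (years - 2010), 0.1)
        s = pd.Series(vals, index=years)
        for frac in (0.25, 0.45):
            ya = cumulative_target_year(s, ReductionGoal(frac, "annual"))
            yc = cumulative_target_year(s, ReductionGoal(frac, "cumulative"))
            assert ya is not None and yc is not None
            assert yc >= ya


class TestRegionalTotals:
    def test_single_region(self):
        d = make_uniform_domain(10, n_countries=1)
        out = regional_totals(np.ones(10), d)
        assert len(out) == 1 and out["share"][0] == pytest.approx(1.0)

    def test_two_equal_regions(self):
        d = make_uniform_domain(10, n_countries=2)
        out = regional_totals(np.ones(10), d)
        np.testing.assert_allclose(out["share"], 0.5)

    def test_shares_normalize(self):
        d = make_uniform_domain(180, n_countries=18)
        rng = np.random.default_rng(2)
        out = regional_totals(rng.uniform(0, 1, 180), d)
        assert out["share"].sum() == pytest.approx(1.0)

    def test_additivity_to_global(self):
        d = make_uniform_domain(90, n_countries=9)
        rng = np.random.default_rng(3)
        field = rng.uniform(0, 1, (5, 90))
        out = regional_totals(field, d)
        assert out["value"].sum() == pytest.approx(field.sum(), rel=1e-12)


class TestMitigationPotential:
    def test_printed_70_percent(self):
        bau = pd.Series({2050: 3.07})
        amb = pd.Series({2050: 3.07 - 2.14})
        got = mitigation_potential(bau, amb)
        assert got["delta_tg_n"] == pytest.approx(2.14)
        assert round(got["percent_of_bau"]) == 70

    def test_printed_co2e(self):
        bau = pd.Series({2050: 3.28})
        amb = pd.Series({2050: 3.28 - 2.50})
        got = mitigation_potential(bau, amb, constants=ConversionConstants(gwp100=265))
        assert round(got["pg_co2e"], 2) == pytest.approx(1.04)

    def test_zero_delta(self):
        s = pd.Series({2050: 2.0})
        got = mitigation_potential(s, s)
        assert got["delta_tg_n"] == 0.0
        assert got["pg_co2e"] == 0.0
        assert got["percent_of_bau"] == 0.0

    def test_per_hectare(self):
        bau = pd.Series({2050: 3.28})
        amb = pd.Series({2050: 3.28 - 2.50})
        got = mitigation_potential(bau, amb,
                                   constants=ConversionConstants(gwp100=265))
        # 1.04 Pg over 1.35 Gha croplands ~ 0.77 Mg/ha
        assert got["mg_co2e_per_ha"] == pytest.approx(0.77, abs=0.01)


class TestStaticDynamicGap:
    def test_printed_26_percent(self):
        dyn = pd.Series({2010: 1.41})
        stat = pd.Series({2010: 1.04})
        out = static_dynamic_gap(dyn, stat)
        assert round(out["gap_percent"][0]) == 26

    def test_identical_series(self):
        s = pd.Series({2010: 1.0, 2011: 2.0})
        out = static_dynamic_gap(s, s)
        np.testing.assert_allclose(out["gap_tg_n"], 0.0)
        np.testing.assert_allclose(out["gap_percent"], 0.0)


class TestProjectScenario:
    def test_flat_series_under_constant_forcing(self, constant_world):
        world, emulator = constant_world
        d = world.domain
        years = np.arange(2010, 2021)
        climate = generate_climate(d, years, "SSP5-8.5", n_members=1,
                                   warming_rate=0.0, bias_sd=0.0,
                                   noise_sd=0.0, seed=world.config.seed)
        spec = default_scenario("INMS1", d)
        f0 = build_scenario_field(spec, d, world.baseline, [2010])
        const_table = f0.country_totals.copy()
        frames = [const_table.assign(year=y) for y in years]
        import n2oproj.scenario_fertilizer as sf
        fert = sf.scale_gridded_fertilizer(world.baseline, d,
                                           pd.concat(frames, ignore_index=True),
                                           "INMS1")
        proj = project_scenario(spec, emulator, climate.members, fert,
                                d, world.soil)
        series = proj.member_global_tg[0]
        np.testing.assert_allclose(series, series[0], rtol=1e-9)

    def test_static_series_identity(self, small_run_world):
        world, emulator = small_run_world
        proj = run_scenario(world, emulator, "INMS2", keep_cells=False)
        spec = default_scenario("INMS2", world.domain)
        fert = build_scenario_field(spec, world.domain, world.baseline,
                                    list(world.config.proj_years))
        n_totals = (fert.rates * world.domain.fertilized_area_ha[None, :]
                    ).sum(axis=1) * 1e-9
        np.testing.assert_allclose(proj.static_global_tg, 0.01 * n_totals,
                                   rtol=1e-12)

    def test_member_median_matches_naive(self, small_run_world):
        world, emulator = small_run_world
        proj = run_scenario(world, emulator, "INMS3", keep_cells=False)
        med = proj.median_global()
        for j in range(proj.years.size):
            assert med[j] == pytest.approx(
                naive_percentile(proj.member_global_tg[:, j], 50))

    def test_pathway_mismatch_rejected(self, constant_world):
        world, emulator = constant_world
        d = world.domain
        climate = generate_climate(d, np.arange(2010, 2012), "SSP1-2.6",
                                   n_members=1, seed=0)
        spec = default_scenario("INMS1", d)  # wants SSP5-8.5
        fert = build_scenario_field(spec, d, world.baseline, [2010, 2011])
        with pytest.raises(ConfigError):
            project_scenario(spec, emulator, climate.members, fert,
                             d, world.soil)


class TestRunInvariants:
    def test_scenario_ordering_2050(self, small_run_world):
        world, emulator = small_run_world
        runs = run_all_scenarios(world, emulator,
                                 scenario_ids=("INMS1", "INMS2", "INMS3", "INMS4"))
        finals = {s: runs[s].median_global()[-1] for s in runs}
        assert finals["INMS1"] >= finals["INMS2"] >= finals["INMS3"] \
            >= finals["INMS4"]

    def test_dynamic_exceeds_static_2050_bau(self, small_run_world):
        """Warming + monotone surface calibrated above 1%: the 2050 dynamic
        total strictly exceeds the static total under BAU."""
        world, emulator = small_run_world
        proj = run_scenario(world, emulator, "INMS1", keep_cells=False)
        assert proj.median_global()[-1] > proj.static_global_tg[-1]

    def test_band_coverage(self, small_run_world):
        world, emulator = small_run_world
        proj = run_scenario(world, emulator, "INMS2", keep_cells=False)
        s = ensemble_summary(proj.member_global_tg, proj.years)
        assert (s["p25"] <= s["median"]).all() and (s["median"] <= s["p75"]).all()

    def test_global_equals_sum_of_regions(self, small_run_world):
        world, emulator = small_run_world
        proj = run_scenario(world, emulator, "INMS4", keep_cells=True)
        field = proj.member_cell_tg[0]       # one member, all years
        out = regional_totals(field, world.domain)
        assert out["value"].sum() == pytest.approx(
            proj.member_global_tg[0].sum(), rel=1e-9)
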