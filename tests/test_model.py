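"""Box model: daily/yearly calcification, sweeps, and the dark-day fit."""

import math
from dataclasses import replace

import numpy as np
import pytest

from corallight import (
    LightParams,
    ModelConfig,
    SyntheticGradientSpec,
    attenuate,
    count_dark_days,
    crossing_latitude,
    daily_G,
    f_darkdays,
    f_light,
    f_temp,
    fit_light_cutoff,
    poleward_cutoff,
    surface_par_series,
    sweep,
    synth_scenario,
    yearly_profile,
)


def cold_spec(t_eq=32.0, t_pole=2.0, p=2.0):
    return SyntheticGradientSpec(
        t_eq_cold=t_eq, t_pole_cold=t_pole,
        t_eq_warm=t_eq + 2.0, t_pole_warm=t_pole + 2.0,
        shape_exponent=p,
    )


class TestDailyG:
    def test_polar_night_day_is_zero(self, default_config, warm_flat_scenario):
        config = replace(
            default_config,
            light=LightParams(e_lim=None, tolerance_days=None),
        )
        series = surface_par_series(80.0, config.orbit)
        dark_day = int(np.argmin(series)) + 1
        assert series[dark_day - 1] == 0.0
        assert daily_G(80.0, dark_day, config, warm_flat_scenario) == 0.0

    def test_cold_scenario_zeroes_every_day(self, default_config):
        freezing = synth_scenario(cold_spec(t_eq=14.0, t_pole=-2.0), name="cold")
        for day in (1, 100, 200, 300):
            assert daily_G(10.0, day, default_config, freezing) == 0.0

    def test_saturation_point_value(self, warm_flat_scenario):
        # E_z == E_k with open gates gives G = G_max * tanh(1)
        config = ModelConfig(light=LightParams(e_lim=None, tolerance_days=None))
        series = surface_par_series(0.0, config.orbit)
        day = 42
        e_z = series[day - 1] * math.exp(-0.75)
        config = replace(config, light=replace(config.light, e_k=e_z))
        got = daily_G(0.0, day, config, warm_flat_scenario)
        assert got == pytest.approx(math.tanh(1.0))

    def test_factorization_to_machine_precision(self, default_config,
                                                warm_flat_scenario, rng):
        lp = default_config.light
        for _ in range(10):
            lat = float(rng.integers(0, 91))
            day = int(rng.integers(1, 366))
            series = surface_par_series(lat, default_config.orbit)
            fl = f_light(attenuate(series[day - 1], lp.k_par, lp.z), lp.e_k)
            fd = f_darkdays(count_dark_days(series, lp.e_lim), lp.tolerance_days)
            cold, warm = warm_flat_scenario.interp(lat)
            ft = f_temp(float(cold), float(warm), default_config.envelope)
            expected = default_config.g_max * fl * fd * ft
            assert daily_G(lat, day, default_config, warm_flat_scenario) == expected

    def test_latitude_outside_scenario_rejected(self, default_config):
        import pandas  # noqa: F401  (dataframe-backed scenario below)
        from corallight import TemperatureScenario

        narrow = TemperatureScenario(
            "narrow", np.arange(0.0, 41.0), np.full(41, 26.0), np.full(41, 27.0)
        )
        with pytest.raises(ValueError):
            daily_G(60.0, 1, default_config, narrow)


class TestYearlyProfile:
    def test_normalization_peaks_near_equator(self, warm_flat_scenario):
        config = ModelConfig(light=LightParams(e_lim=None, tolerance_days=None))
        prof = yearly_profile(config, warm_flat_scenario)
        assert prof.yearly_pct.max() == pytest.approx(100.0)
        # profile is equator-peaked to within hundredths of a percent
        assert prof.yearly_pct[0] >= 99.99
        assert np.all(np.diff(prof.yearly_pct) <= 0.01)

    def test_dark_day_rule_cuts_beyond_50(self, warm_flat_scenario):
        config = ModelConfig(
            light=LightParams(e_k=50.0, k_par=0.05, z=15.0,
                              e_lim=105.0, tolerance_days=26)
        )
        prof = yearly_profile(config, warm_flat_scenario)
        above = prof.latitudes > 50.0
        assert np.all(prof.yearly_G[above] == 0.0)
        assert prof.yearly_G[prof.latitudes == 50.0] > 0.0
        assert poleward_cutoff(prof) == 50.0

    def test_everything_frozen_gives_zero_profile(self, default_config):
        freezing = synth_scenario(cold_spec(t_eq=12.0, t_pole=-2.0), name="cold")
        prof = yearly_profile(default_config, freezing)
        assert np.all(prof.yearly_G == 0.0)
        assert np.all(prof.yearly_pct == 0.0)
        assert poleward_cutoff(prof) is None

    def test_bounds(self, default_config, warm_flat_scenario):
        prof = yearly_profile(default_config, warm_flat_scenario)
        assert np.all(prof.yearly_G >= 0.0)
        assert np.all(prof.yearly_G <= default_config.orbit.days_per_year
                      * default_config.g_max)
        assert np.all((0.0 <= prof.yearly_pct) & (prof.yearly_pct <= 100.0))

    def test_limiting_factor_labels(self):
        # hot equator (heat gate), cold crossing at 71 deg (beyond the
        # dark-day cutoff at 51), so the poleward flank shows the full
        # label sequence heat -> open -> dark_days -> multiple
        scn = synth_scenario(
            SyntheticGradientSpec(t_eq_cold=32.0, t_pole_cold=14.0,
                                  t_eq_warm=38.0, t_pole_warm=16.0,
                                  shape_exponent=2.0),
            name="hot-eq",
        )
        config = ModelConfig(
            light=LightParams(e_k=50.0, k_par=0.05, z=15.0,
                              e_lim=105.0, tolerance_days=26)
        )
        prof = yearly_profile(config, scn)
        labels = dict(zip(prof.latitudes, prof.limiting_factor))
        assert labels[0.0] == "heat"          # warmest month above 36 at equator
        assert labels[89.0] == "multiple"     # cold and dark gates both closed
        dark_lats = [la for la, lab in labels.items() if lab == "dark_days"]
        assert dark_lats and min(dark_lats) == 51.0
        assert all(la > 50.0 for la in dark_lats)

    def test_straight_loop_oracle(self, rng, warm_flat_scenario):
        """Vectorized yearly totals match an unvectorized re-implementation."""
        for _ in range(5):
            e_k = float(rng.choice([50, 100, 150, 200, 300]))
            kz = float(rng.uniform(0.15, 3.0))
            config = ModelConfig(
                light=LightParams(e_k=e_k, k_par=kz / 15.0, z=15.0,
                                  e_lim=105.0, tolerance_days=26)
            )
            prof = yearly_profile(config, warm_flat_scenario)
            for lat in rng.choice(91, size=5, replace=False):
                series = surface_par_series(float(lat), config.orbit)
                n_dark = sum(1 for v in series if v < 105.0)
                fd = 0 if n_dark > 26 else 1
                total = 0.0
                for v in series:
                    total += math.tanh(v * math.exp(-kz) / e_k)
                expected = total * fd
                got = float(prof.yearly_G[prof.latitudes == float(lat)][0])
                assert got == pytest.approx(expected, rel=1e-12, abs=1e-12)


class TestSweep:
    def test_single_point_axes_reproduce_profile(self, warm_flat_scenario,
                                                 default_config):
        res = sweep(default_config, warm_flat_scenario,
                    [50.0], [0.75], [105.0], [26])
        assert len(res.table) == 1
        direct = yearly_profile(default_config, warm_flat_scenario)
        np.testing.assert_allclose(res.profiles[0].yearly_G, direct.yearly_G)

    def test_grid_size_and_ordering(self, warm_flat_scenario, default_config):
        res = sweep(default_config, warm_flat_scenario,
                    [100.0, 50.0], [0.75, 0.15], [105.0], [26])
        assert len(res.table) == 4
        assert list(res.table["e_k"]) == [50.0, 50.0, 100.0, 100.0]
        res2 = sweep(default_config, warm_flat_scenario,
                     [50.0, 100.0], [0.15, 0.75], [105.0], [26])
        assert res.table.equals(res2.table)

    def test_more_attenuation_never_raises_G(self, warm_flat_scenario,
                                             default_config):
        res = sweep(default_config, warm_flat_scenario,
                    [50.0], [0.15, 0.75, 1.5, 3.0], [105.0], [26])
        stack = np.array([p.yearly_G for p in res.profiles])
        assert np.all(np.diff(stack, axis=0) <= 1e-9)

    def test_higher_saturation_never_raises_G(self, warm_flat_scenario,
                                              default_config):
        res = sweep(default_config, warm_flat_scenario,
                    [50.0, 100.0, 150.0, 200.0, 300.0], [0.75], [105.0], [26])
        stack = np.array([p.yearly_G for p in res.profiles])
        assert np.all(np.diff(stack, axis=0) <= 1e-9)

    def test_empty_axis_rejected(self, warm_flat_scenario, default_config):
        with pytest.raises(ValueError):
            sweep(default_config, warm_flat_scenario, [], [0.75], [105.0], [26])


class TestFit:
    def test_headline_fit(self, default_config):
        res = fit_light_cutoff(default_config, 50.0)
        assert res.feasible
        assert res.e_lim == 105.0
        assert (res.tolerance_min, res.tolerance_max) == (1, 26)

    def test_cutoff_monotone_in_elim_and_tolerance(self, warm_flat_scenario,
                                                   default_config):
        cutoffs_elim = []
        for e_lim in (60.0, 105.0, 200.0, 300.0):
            config = replace(default_config,
                             light=replace(default_config.light,
                                           e_lim=e_lim, tolerance_days=10))
            cutoffs_elim.append(
                poleward_cutoff(yearly_profile(config, warm_flat_scenario)))
        assert np.all(np.diff(cutoffs_elim) <= 0)

        cutoffs_tol = []
        for tol in (1, 10, 50, 150, 365):
            config = replace(default_config,
                             light=replace(default_config.light,
                                           e_lim=200.0, tolerance_days=tol))
            cutoffs_tol.append(
                poleward_cutoff(yearly_profile(config, warm_flat_scenario)))
        assert np.all(np.diff(cutoffs_tol) >= 0)

    def test_infeasible_target_returns_empty_result(self, default_config):
        # beyond the polar circle the polar night alone exceeds any tolerance
        # that would still permit latitude 89
        res = fit_light_cutoff(default_config, 89.0,
                               e_lim_grid=[400.0], tolerance_range=range(1, 10))
        assert not res.feasible
        assert res.e_lim is None

    def test_feasible_interval_matches_enumeration(self, default_config):
        res = fit_light_cutoff(default_config, 50.0)
        par = surface_par_series(51.0, default_config.orbit)
        n51 = count_dark_days(par, res.e_lim)
        # dark days at <= 50 deg are zero, so the interval is [1, n51 - 1]
        assert (res.tolerance_min, res.tolerance_max) == (1, n51 - 1)

    def test_disabled_dark_rule_cutoff_tracks_16C_crossing(self, default_config,
                                                           no_darkday_light):
        config = replace(default_config, light=no_darkday_light)
        for p in (1.2, 1.84, 2.5):
            scn = synth_scenario(cold_spec(t_eq=30.0, t_pole=4.0, p=p))
            crossing = crossing_latitude(scn, 16.0)
            cutoff = poleward_cutoff(yearly_profile(config, scn))
            assert cutoff == crossing - config.grid_step
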