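"""Canopy dynamics, transpiration, biomass, yield and calibration."""

import dataclasses
import math

import numpy as np
import pytest

from teacrop.soilwater import SoilProfile
from teacrop.teasim import (
    calibrate,
    canopy_cover,
    cc_star,
    daily_transpiration,
    evaluate_simulation,
    harvest_index,
    kc_tr,
    normalized_biomass,
    simulate_season,
)
from teacrop.synthetic_data import default_weather_specs, gen_weather_year, season_window

from conftest import make_constant_weather


class TestCanopyCover:
    def test_starts_at_post_pruning_cover(self, crop):
        assert canopy_cover(0.0, crop) == pytest.approx(0.20)

    def test_asymptote_is_ccx(self, crop):
        assert canopy_cover(3000.0, crop) == pytest.approx(0.95, abs=1e-6)

    def test_crossover_time_matches_bisection_oracle(self, crop):
        # root of cco*exp(cgc t) = ccx/2 found by bisection on the growth
        # branch, independent of the closed-form log expression
        lo, hi = 0.0, 1000.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if crop.cco * math.exp(crop.cgc * mid) > 0.5 * crop.ccx:
                hi = mid
            else:
                lo = mid
        t_star = 0.5 * (lo + hi)
        assert t_star == pytest.approx(123.5710624980863, abs=1e-6)
        assert canopy_cover(t_star, crop) == pytest.approx(0.475, abs=1e-9)

    def test_continuous_nondecreasing_bounded(self, crop):
        ts = np.linspace(0.0, 800.0, 4001)
        ccs = np.array([canopy_cover(float(t), crop) for t in ts])
        assert np.all(np.diff(ccs) >= -1e-12)
        assert np.all(ccs <= crop.ccx + 1e-12)
        # no jump anywhere near the branch switch
        assert np.max(np.abs(np.diff(ccs))) < 2e-3

    def test_rejects_negative_time(self, crop):
        with pytest.raises(ValueError):
            canopy_cover(-1.0, crop)


class TestCcStarAndKcTr:
    @pytest.mark.parametrize("cc,expected", [
        (0.0, 0.0),
        (1.0, 1.02),
        (0.95, 0.9887125),
    ])
    def test_polynomial_values(self, cc, expected):
        assert cc_star(cc) == pytest.approx(expected)

    def test_exceeds_cc_on_open_interval(self):
        for cc in np.linspace(0.01, 0.99, 99):
            assert cc_star(float(cc)) >= cc

    def test_kc_tr_values_and_linearity(self, crop):
        assert kc_tr(0.0, crop) == 0.0
        assert kc_tr(1.0, crop) == pytest.approx(0.95 * 1.02)
        half = dataclasses.replace(crop, kctr_x=0.5)
        for cc in (0.1, 0.5, 0.9):
            assert kc_tr(cc, half) == pytest.approx(
                0.5 / 0.95 * kc_tr(cc, crop))

    def test_cc_star_domain(self):
        with pytest.raises(ValueError):
            cc_star(1.5)


class TestDailyTranspiration:
    def test_product_form(self, crop):
        assert daily_transpiration(1.0, crop, 0.9, 5.0) == pytest.approx(4.5)
        assert daily_transpiration(1.0, crop, 0.9, 0.0) == 0.0
        assert daily_transpiration(0.0, crop, 0.9, 5.0) == 0.0

    def test_cold_stress_scales_flux(self, crop):
        cold = dataclasses.replace(crop, ks_cold=0.5)
        assert daily_transpiration(1.0, cold, 0.9, 5.0) == pytest.approx(2.25)


class TestNormalizedBiomass:
    def test_empty_series(self):
        assert normalized_biomass([], [], 18.0) == 0.0

    def test_unit_ratio_conversion(self):
        # 100 days at Tr = ET0 with WP* = 18 g/m2 -> 1800 g/m2 = 18 t/ha
        tr = [4.0] * 100
        assert normalized_biomass(tr, tr, 18.0) == pytest.approx(18.0)

    def test_matches_elementwise_loop(self):
        rng = np.random.default_rng(9)
        et0 = rng.uniform(1.0, 8.0, 50)
        tr = et0 * rng.uniform(0.0, 1.0, 50)
        expected = 18.0 * sum(t / e for t, e in zip(tr, et0)) * 0.01
        assert normalized_biomass(tr, et0, 18.0) == pytest.approx(expected)

    def test_rejects_undefined_ratio(self):
        with pytest.raises(ValueError):
            normalized_biomass([1.0], [0.0], 18.0)


class TestHarvestIndex:
    @pytest.mark.parametrize("mult,expected", [
        (1.0, 0.14),
        (2.0, 0.19),   # upper clip
        (1.2, 0.168),
    ])
    def test_multiplier_with_bounds(self, crop, mult, expected):
        assert harvest_index(mult, crop) == pytest.approx(expected)

    def test_rejects_nonpositive_multiplier(self, crop):
        with pytest.raises(ValueError):
            harvest_index(0.0, crop)


class TestSimulateSeason:
    def test_constant_conditions_match_closed_form(self, site, crop, soil):
        n = 90
        weather = make_constant_weather(n)
        res = simulate_season(weather, site, crop, soil,
                              irrigation_policy="auto_fc",
                              cc_override=crop.ccx)
        closed = (res.hi * crop.wp_star * 0.01 * n
                  * crop.kctr_x * cc_star(crop.ccx))
        assert res.yield_t_ha == pytest.approx(closed, abs=1e-9)

    def test_yield_is_hi_times_biomass(self, site, crop, soil, constant_weather):
        res = simulate_season(constant_weather, site, crop, soil)
        assert res.yield_t_ha == res.hi * res.biomass_t_ha

    def test_auto_fc_keeps_ks_at_one(self, site, crop, soil, constant_weather):
        res = simulate_season(constant_weather, site, crop, soil,
                              irrigation_policy="auto_fc")
        assert (res.daily["ks"] == 1.0).all()

    def test_stress_machinery_inert_under_auto_fc(self, site, crop, soil,
                                                  constant_weather):
        # recompute biomass from demand-side transpiration only (no Ks,
        # no bucket): identical output proves the stress path is inert
        res = simulate_season(constant_weather, site, crop, soil,
                              irrigation_policy="auto_fc")
        kctr = res.daily["kc_tr"].to_numpy()
        et0 = res.daily["et0_mm"].to_numpy()
        b_direct = normalized_biomass(kctr * et0, et0, crop.wp_star)
        assert res.biomass_t_ha == pytest.approx(b_direct, abs=1e-9)

    def test_drought_without_irrigation_reduces_yield(self, site, crop, soil):
        dry = make_constant_weather(300, rain=0.0)
        irrigated = simulate_season(dry, site, crop, soil, "auto_fc")
        rainfed = simulate_season(dry, site, crop, soil, "none")
        assert rainfed.yield_t_ha < irrigated.yield_t_ha
        assert (rainfed.daily["ks"] < 1.0).any()

    def test_zero_water_productivity_zero_yield(self, site, crop, soil,
                                                constant_weather):
        zero_wp = dataclasses.replace(crop, wp_star=1e-12)
        res = simulate_season(constant_weather, site, zero_wp, soil)
        assert res.yield_t_ha == pytest.approx(0.0, abs=1e-9)

    def test_biomass_nondecreasing_and_cc_bounded(self, site, crop, soil,
                                                  constant_weather):
        res = simulate_season(constant_weather, site, crop, soil)
        assert (res.daily["biomass_t_ha"].diff().dropna() >= -1e-12).all()
        assert res.daily["cc"].between(0.0, crop.ccx).all()

    def test_yield_monotone_in_productivity_parameters(self, site, crop, soil):
        weather = make_constant_weather(60)

        def yield_with(**kw):
            return simulate_season(weather, site,
                                   dataclasses.replace(crop, **kw),
                                   soil).yield_t_ha

        wp_sweep = [yield_with(wp_star=w) for w in (14.0, 16.0, 18.0, 20.0)]
        assert all(b > a for a, b in zip(wp_sweep, wp_sweep[1:]))
        hio_sweep = [yield_with(hio=h) for h in (0.14, 0.16, 0.18)]
        assert all(b > a for a, b in zip(hio_sweep, hio_sweep[1:]))
        kc_sweep = [yield_with(kctr_x=k) for k in (0.5, 0.75, 0.95)]
        assert all(b > a for a, b in zip(kc_sweep, kc_sweep[1:]))

    def test_error_carries_day_index(self, site, crop, soil):
        weather = make_constant_weather(5)
        bad = SoilProfile()
        with pytest.raises(ValueError, match="day 0"):
            simulate_season(weather, site, crop, bad, cc_override=2.0)


def _season_yields(crop, site, soil, seasons):
    weather = {str(s.year_label): season_window(gen_weather_year(s))
               for s in seasons}
    obs = [(label, simulate_season(w, site, crop, soil).yield_t_ha)
           for label, w in weather.items()]
    return obs, weather


WP_GRID = tuple(float(w) for w in range(15, 22))          # 15..21 g/m2
HIO_GRID = tuple(round(0.14 + 0.01 * i, 2) for i in range(6))  # 0.14..0.19


class TestCalibrate:
    def test_zero_noise_recovery_is_exact(self, site, crop, soil):
        seasons = default_weather_specs(seed=3)
        obs, weather = _season_yields(crop, site, soil, seasons)
        fitted = calibrate(
            obs, weather, site, crop, soil,
            free_params=["wp_star", "hio"],
            bounds={"wp_star": (15.0, 21.0), "hio": (0.14, 0.19)},
            grids={"wp_star": WP_GRID, "hio": HIO_GRID},
        )
        assert fitted.wp_star == 18.0
        assert fitted.hio == 0.14

    def test_noisy_recovery_within_ten_percent(self, site, crop, soil):
        seasons = default_weather_specs(seed=3)
        obs, weather = _season_yields(crop, site, soil, seasons)
        rng = np.random.default_rng(77)
        noisy = [(label, y * rng.lognormal(0.0, 0.05)) for label, y in obs]
        fitted = calibrate(
            noisy, weather, site, crop, soil,
            free_params=["wp_star"],
            bounds={"wp_star": (14.0, 22.0)},
            grids={"wp_star": tuple(np.arange(14.0, 22.01, 0.5))},
        )
        assert abs(fitted.wp_star - 18.0) / 18.0 <= 0.10

    def test_doubled_yields_double_wp_star(self, site, crop, soil):
        seasons = default_weather_specs(seed=3)[:2]
        obs, weather = _season_yields(crop, site, soil, seasons)
        doubled = [(label, 2.0 * y) for label, y in obs]
        grid = tuple(np.arange(30.0, 42.01, 0.5))
        fitted = calibrate(doubled, weather, site, crop, soil,
                           free_params=["wp_star"],
                           bounds={"wp_star": (30.0, 42.0)},
                           grids={"wp_star": grid})
        assert fitted.wp_star == pytest.approx(36.0, rel=0.02)

    def test_rejects_unknown_parameter(self, site, crop, soil):
        with pytest.raises(ValueError):
            calibrate([("a", 1.0)], {"a": []}, site, crop, soil,
                      free_params=["density"], bounds={})


class TestEvaluateSimulation:
    def test_identical_vectors_zero_error(self):
        res = evaluate_simulation([1.0, 2.0], [1.0, 2.0])
        assert (res.mae, res.mse, res.rmse) == (0.0, 0.0, 0.0)

    def test_hand_arithmetic(self):
        res = evaluate_simulation([1.0, 3.0], [2.0, 2.0])
        assert (res.mae, res.mse, res.rmse) == (1.0, 1.0, 1.0)

    def test_rmse_is_sqrt_mse(self):
        rng = np.random.default_rng(13)
        a, b = rng.normal(size=20), rng.normal(size=20)
        res = evaluate_simulation(a, b)
        assert res.rmse == pytest.approx(math.sqrt(res.mse), abs=1e-12)

    def test_rejects_length_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_simulation([1.0], [1.0, 2.0])
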