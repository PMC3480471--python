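"""Ecoclimatic Index: per-location pipeline, grids, change maps."""

import numpy as np
import pytest

from ecoclim.ei import (change_map, classify, ecoclimatic_index,
                        run_grid, run_location)
from ecoclim.growth import annual_growth_index
from ecoclim.scenario import ScenarioSpec, apply_scenario
from ecoclim.stress import StressResult
from ecoclim.synthetic import (make_constant_station, make_optimal_station,
                               make_station, make_world,
                               world_annual_tmean, world_seasonal_amplitude)


class TestEcoclimaticIndex:
    def test_perfect_year_scores_100(self):
        g = annual_growth_index(np.ones(52), np.ones(52))
        r = ecoclimatic_index(g, StressResult(0, 0, 0, 0))
        assert r.ei == 100.0
        assert r.suitability_class == "highly_suitable"

    def test_product_arithmetic(self):
        mi = np.full(52, 0.5)
        g = annual_growth_index(np.ones(52), mi)  # GI_A = 50
        r = ecoclimatic_index(g, StressResult(0.5, 0, 0, 0))  # SI = 0.5
        assert r.ei == pytest.approx(25.0)

    def test_total_stress_means_unsuitable(self):
        g = annual_growth_index(np.ones(52), np.ones(52))
        r = ecoclimatic_index(g, StressResult(1.0, 0, 0, 0))
        assert r.ei == 0.0
        assert r.suitability_class == "unsuitable"

    @pytest.mark.parametrize("ei,cls", [
        (0.0, "unsuitable"), (5.0, "marginal"), (10.0, "marginal"),
        (15.0, "suitable"), (20.0, "suitable"), (25.0, "highly_suitable"),
        (10.0 + 1e-9, "marginal"),  # rounded back onto the boundary
    ])
    def test_classification_bands(self, ei, cls):
        assert classify(ei) == cls


class TestRunLocation:
    def test_optimal_station_reaches_exactly_100(self, palm):
        r = run_location(make_optimal_station(palm), palm)
        assert r.ei == 100.0
        assert r.stresses.si == 1.0

    def test_hot_desert_archetype_is_suitable(self, palm):
        r = run_location(make_station("hot_desert"), palm)
        assert r.suitability_class in ("suitable", "highly_suitable")
        assert r.stresses.cold == 0.0
        assert r.stresses.heat == 0.0
        assert r.stresses.wet == pytest.approx(0.0, abs=1e-6)

    def test_cool_temperate_archetype_is_unsuitable(self, palm):
        r = run_location(make_station("cool_temperate"), palm)
        assert r.ei == 0.0
        assert np.all(r.growth.ti_w == 0.0)  # never reaches 14 degC

    def test_pure_and_deterministic(self, palm):
        mc = make_station("mediterranean", jitter_sd=1.0, seed=9)
        r1 = run_location(mc, palm)
        r2 = run_location(mc, palm)
        assert r1.ei == r2.ei
        np.testing.assert_array_equal(r1.growth.gi_w, r2.growth.gi_w)

    def test_ei_bounded_on_random_climates(self, palm, rng):
        # randomized monthly normals must never escape the 0-100 scale
        for _ in range(1000):
            tmean = rng.uniform(-20, 45)
            mc = make_constant_station(
                tmean, diurnal_range=rng.uniform(2, 20),
                precip_monthly=rng.uniform(0, 400, 12),
                rh=rng.uniform(5, 95))
            r = run_location(mc, palm)
            assert 0.0 <= r.ei <= 100.0
            assert (r.ei == 0.0) == (r.gi_annual == 0.0
                                     or r.stresses.si == 0.0)


class TestRunGrid:
    def test_single_cell_matches_run_location(self, palm, small_world):
        from ecoclim.climate import ClimateGrid
        g = small_world
        sub = ClimateGrid(lat=g.lat[5:6], lon=g.lon[3:4],
                          tmin=g.tmin[:, 5:6, 3:4],
                          tmax=g.tmax[:, 5:6, 3:4],
                          ptotal=g.ptotal[:, 5:6, 3:4],
                          rh09=g.rh09[:, 5:6, 3:4],
                          rh15=g.rh15[:, 5:6, 3:4])
        m = run_grid(sub, palm)
        r = run_location(g.cell(5, 3), palm)
        assert m.ei[0, 0] == r.ei

    def test_all_masked_grid_rejected(self, palm, small_world):
        import copy
        g = copy.deepcopy(small_world)
        g.mask[:] = False
        with pytest.raises(ValueError):
            run_grid(g, palm)

    def test_class_counts_cover_unmasked_cells(self, palm, small_world):
        m = run_grid(small_world, palm)
        assert sum(m.class_counts().values()) == int(m.mask.sum())

    def test_suitable_band_bounded_by_cold_limit(self, palm, world_36x72):
        # poleward of the latitude where even the warmest month stays
        # below the limiting low temperature, TI is identically zero
        m = run_grid(world_36x72, palm)
        warmest = (world_annual_tmean(m.lat)
                   + world_seasonal_amplitude(m.lat))
        # 1 degC margin absorbs the generator's 0.3 degC noise
        frozen_rows = warmest < 14.0 - 1.0
        assert np.all(m.ei[frozen_rows, :] == 0.0)
        assert (m.ei > 0).any()


class TestChangeMap:
    def test_identity_run_is_all_stable(self, palm, small_world):
        m = run_grid(small_world, palm)
        ch = change_map(m, m)
        counts = ch.category_counts()
        assert counts["gain"] == 0 and counts["loss"] == 0
        np.testing.assert_allclose(ch.delta_ei[ch.mask], 0.0)

    def test_gain_and_loss_categories(self, palm, small_world):
        base = run_grid(small_world, palm)
        fut = run_grid(apply_scenario(small_world,
                                      ScenarioSpec("MR", 2100)), palm)
        ch = change_map(base, fut)
        cat = ch.category
        gain = (base.ei == 0) & (fut.ei > 0) & ch.mask
        assert np.all(cat[gain] == 2)

    def test_mismatched_grids_rejected(self, palm, small_world):
        m1 = run_grid(small_world, palm)
        m2 = run_grid(make_world(6, 10, seed=1), palm)
        with pytest.raises(ValueError):
            change_map(m1, m2)


class TestWarmingMonotonicity:
    def test_cold_limited_cell_never_loses_from_warming(self, palm):
        # a year-round-cold station: every positive uniform warming can
        # only move weekly temperatures toward the growth band
        mc = make_constant_station(8.0, precip_monthly=60.0)
        base = run_location(mc, palm).ei
        for dt in (2.0, 5.0, 9.0):
            warmed = make_constant_station(8.0 + dt, precip_monthly=60.0)
            assert run_location(warmed, palm).ei >= base
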