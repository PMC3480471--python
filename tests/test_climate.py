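"""Monthly-to-weekly interpolation and climate grid I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecoclim.climate import (MONTH_DAYS, N_WEEKS, MonthlyClimate,
                             monthly_to_weekly, read_climate, weekly_series,
                             write_climate, grid_to_frame)
from ecoclim.synthetic import make_station, make_world

YEAR = 365.0
WEEK = YEAR / N_WEEKS
MONTH_MID = np.concatenate([[0.0], np.cumsum(MONTH_DAYS)])[:-1] \
    + MONTH_DAYS / 2.0


def circular_linear_oracle(values, day):
    """Brute-force circular piecewise-linear interpolation at one day."""
    day = day % YEAR
    # walk the 12 midpoint anchors to find the bracketing pair
    for m in range(12):
        t0 = MONTH_MID[m]
        t1 = MONTH_MID[(m + 1) % 12]
        v0, v1 = values[m], values[(m + 1) % 12]
        span = (t1 - t0) % YEAR
        offset = (day - t0) % YEAR
        if offset <= span:
            return v0 + (v1 - v0) * offset / span
    raise AssertionError("unreachable")


class TestIntensiveInterpolation:
    def test_constant_preserved(self):
        out = monthly_to_weekly([7.5] * 12, "intensive")
        assert out.shape == (52,)
        np.testing.assert_allclose(out, 7.5)

    def test_matches_independent_circular_oracle(self, rng):
        values = rng.normal(10, 8, 12)
        out = monthly_to_weekly(values, "intensive")
        expected = [circular_linear_oracle(values, (w + 0.5) * WEEK)
                    for w in range(N_WEEKS)]
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_sinusoid_within_linear_interp_error(self):
        # sample a smooth seasonal cycle at month midpoints; the weekly
        # series must track the true curve to within the chord error of
        # piecewise-linear interpolation over a ~30-day panel
        f = lambda day: 15 + 10 * np.sin(2 * np.pi * day / YEAR)
        monthly = f(MONTH_MID)
        out = monthly_to_weekly(monthly, "intensive")
        truth = f((np.arange(N_WEEKS) + 0.5) * WEEK)
        # max |f''| * h^2 / 8 with h ~ 31 d
        bound = 10 * (2 * np.pi / YEAR) ** 2 * 31**2 / 8
        assert np.max(np.abs(out - truth)) <= bound + 1e-9

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            monthly_to_weekly([np.nan] + [1.0] * 11, "intensive")


class TestExtensiveInterpolation:
    def test_annual_total_conserved(self, rng):
        monthly = rng.uniform(0, 300, 12)
        out = monthly_to_weekly(monthly, "extensive")
        assert out.sum() == pytest.approx(monthly.sum(), rel=1e-6)

    def test_uniform_year(self):
        out = monthly_to_weekly([100.0] * 12, "extensive")
        assert out.sum() == pytest.approx(1200.0, rel=1e-9)
        # weekly rate of a uniform year varies only with month length
        assert out.min() > 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_linearity_both_kinds(self, seed):
        r = np.random.default_rng(seed)
        x, y = r.normal(size=12), r.normal(size=12)
        a, b = r.normal(), r.normal()
        for kind in ("intensive", "extensive"):
            lhs = monthly_to_weekly(a * x + b * y, kind)
            rhs = (a * monthly_to_weekly(x, kind)
                   + b * monthly_to_weekly(y, kind))
            np.testing.assert_allclose(lhs, rhs, atol=1e-9)


class TestWeeklySeries:
    def test_tmax_never_below_tmin(self):
        ws = weekly_series(make_station("mediterranean", jitter_sd=1.0,
                                        seed=3))
        assert np.all(ws.tmax_w >= ws.tmin_w)
        np.testing.assert_allclose(ws.tmean_w, (ws.tmin_w + ws.tmax_w) / 2)


class TestClimateIO:
    def test_csv_round_trip(self, tmp_path):
        grid = make_world(4, 6, seed=11)
        path = tmp_path / "climate.csv"
        write_climate(grid, path)
        again = read_climate(path)
        np.testing.assert_allclose(np.sort(grid.lat), np.sort(again.lat))
        # the CSV reader sorts axes ascending, so compare via long frames
        f1 = grid_to_frame(grid).sort_values(
            ["lat", "lon", "month"]).reset_index(drop=True)
        f2 = grid_to_frame(again).sort_values(
            ["lat", "lon", "month"]).reset_index(drop=True)
        np.testing.assert_allclose(f1.to_numpy(float), f2.to_numpy(float),
                                   atol=1e-9)

    def test_netcdf_round_trip(self, tmp_path):
        grid = make_world(3, 5, seed=2)
        path = tmp_path / "climate.nc"
        write_climate(grid, path)
        again = read_climate(path)
        np.testing.assert_allclose(again.tmin, grid.tmin)
        np.testing.assert_allclose(again.ptotal, grid.ptotal)
        assert again.mask.all()

    def test_invalid_cell_masked_with_warning(self, tmp_path, caplog):
        grid = make_world(3, 4, seed=5)
        grid.tmax[:, 1, 2] = grid.tmin[:, 1, 2] - 5.0  # tmax < tmin
        path = tmp_path / "c.csv"
        write_climate(grid, path)
        import logging
        with caplog.at_level(logging.WARNING, logger="ecoclim.climate"):
            again = read_climate(path)
        assert again.mask.sum() == grid.mask.size - 1
        assert any("masking cell" in r.message for r in caplog.records)

    def test_missing_column_named(self, tmp_path):
        grid = make_world(2, 2, seed=0)
        path = tmp_path / "c.csv"
        df = grid_to_frame(grid).drop(columns=["rh15"])
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="rh15"):
            read_climate(path)


class TestMonthlyClimateInvariants:
    def test_validate_flags_problems(self):
        mc = make_station("hot_desert")
        assert mc.validate() == []
        mc.rh09[0] = 140.0
        assert any("rh09" in p for p in mc.validate())

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            MonthlyClimate(tmin=np.zeros(11), tmax=np.zeros(12),
                           ptotal=np.zeros(12), rh09=np.zeros(12),
                           rh15=np.zeros(12))
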