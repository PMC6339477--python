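"""Raster aggregation, day-pair averaging, rank standardisation and sampling."""

import datetime as dt

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fptrack import (DailyRaster, GridWindow, aggregate, covariate_correlations,
                     rank_standardise, read_ascii_grid, sample_at,
                     temporal_predictability, two_day_average, write_ascii_grid)
from fptrack.errors import OutOfWindowError

D0 = dt.date(2015, 9, 1)
WIN = GridWindow(0.0, 0.0, 1.0, 1.0)


def raster(values, cell=None, west=0.0, north=1.0, variable="sst", date=D0):
    values = np.asarray(values, dtype=float)
    if cell is None:
        cell = (north - 0.0) / values.shape[0]
    return DailyRaster(variable, date, values, west, north, cell)


class TestAggregate:
    def test_constant_source_gives_constant_target(self):
        r = raster(np.full((100, 100), 7.5), cell=0.01)
        agg = aggregate(r, WIN, 0.05)
        assert agg.shape == (20, 20)
        np.testing.assert_allclose(agg.values, 7.5)

    def test_cloud_hole_filled_by_neighbour_mean(self):
        vals = np.full((100, 100), 3.0)
        vals[10, 10] = np.nan
        agg = aggregate(raster(vals, cell=0.01), WIN, 0.05)
        assert np.isfinite(agg.values).all()
        np.testing.assert_allclose(agg.values, 3.0)

    def test_checkerboard_averages_to_half(self):
        # 2x2 source blocks per target cell hold exactly two of each colour
        idx = np.add.outer(np.arange(100), np.arange(100))
        agg = aggregate(raster((idx % 2).astype(float), cell=0.01), WIN, 0.02)
        np.testing.assert_allclose(agg.values, 0.5)

    def test_matches_exact_mean_of_enclosed_centres(self, rng):
        vals = rng.normal(size=(60, 60))
        r = raster(vals, cell=1.0 / 60)
        agg = aggregate(r, WIN, 0.2)
        # oracle: direct index arithmetic over source-cell centres
        sums = np.zeros((5, 5)); counts = np.zeros((5, 5))
        for i in range(60):
            for j in range(60):
                lat_c = 1.0 - (i + 0.5) * r.cell
                lon_c = (j + 0.5) * r.cell
                ti = 4 - int(np.floor(lat_c / 0.2))
                tj = int(np.floor(lon_c / 0.2))
                sums[ti, tj] += vals[i, j]; counts[ti, tj] += 1
        np.testing.assert_allclose(agg.values, sums / counts, atol=1e-12)

    def test_idempotent_at_same_resolution(self, rng):
        r = raster(rng.normal(size=(20, 20)), cell=0.05)
        once = aggregate(r, WIN, 0.05)
        twice = aggregate(once, WIN, 0.05)
        np.testing.assert_allclose(once.values, twice.values)

    def test_no_overlap_raises(self):
        r = raster(np.ones((10, 10)), cell=0.01, west=50.0, north=60.0)
        with pytest.raises(OutOfWindowError):
            aggregate(r, WIN, 0.05)


class TestTwoDayAverage:
    def _days(self, a, b):
        return {D0: raster(a), D0 - dt.timedelta(days=1): raster(b)}

    def test_identical_days_identity(self):
        days = self._days(np.full((4, 4), 5.0), np.full((4, 4), 5.0))
        np.testing.assert_allclose(two_day_average(days, "sst", D0).values, 5.0)

    def test_arithmetic_mean(self):
        days = self._days(np.full((4, 4), 10.0), np.full((4, 4), 20.0))
        np.testing.assert_allclose(two_day_average(days, "sst", D0).values, 15.0)

    def test_na_ignoring(self):
        a = np.full((2, 2), 7.0); a[0, 0] = np.nan
        b = np.full((2, 2), 7.0); b[1, 1] = np.nan
        out = two_day_average(self._days(a, b), "sst", D0)
        np.testing.assert_allclose(out.values, 7.0)

    def test_single_day_fallback_warns(self, caplog):
        out = two_day_average({D0: raster(np.full((2, 2), 3.0))}, "sst", D0)
        np.testing.assert_allclose(out.values, 3.0)
        assert any("only one" in r.message for r in caplog.records)

    def test_both_absent_raises(self):
        with pytest.raises(KeyError):
            two_day_average({}, "sst", D0)


class TestRankStandardise:
    def test_linear_rank_map(self):
        out = rank_standardise(raster(np.array([[1.0, 2.0, 3.0]]), cell=0.1))
        np.testing.assert_allclose(out.values, [[0.0, 10.0, 20.0]])

    def test_tie_handling_average_ranks(self):
        out = rank_standardise(raster(np.array([[5.0, 5.0, 9.0]]), cell=0.1))
        np.testing.assert_allclose(out.values, [[5.0, 5.0, 20.0]])

    def test_constant_image_degenerate(self, caplog):
        out = rank_standardise(raster(np.full((3, 3), 4.0)))
        np.testing.assert_allclose(out.values, 10.0)
        assert any("constant" in r.message for r in caplog.records)

    @given(st.integers(0, 2 ** 32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds_and_monotone_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(6, 6))
        vals[rng.random((6, 6)) < 0.2] = np.nan
        if np.isfinite(vals).sum() < 2:
            return
        a = rank_standardise(raster(vals))
        b = rank_standardise(raster(np.exp(2.0 * vals)))  # strictly monotone
        ok = np.isfinite(a.values)
        assert (a.values[ok] >= 0).all() and (a.values[ok] <= 20).all()
        np.testing.assert_allclose(a.values, b.values, equal_nan=True)

    def test_tie_free_mean_is_ten(self, rng):
        out = rank_standardise(raster(rng.permutation(25).reshape(5, 5).astype(float)))
        assert out.values.mean() == pytest.approx(10.0)


class TestSampleAt:
    def test_cell_centre(self):
        r = raster(np.arange(16.0).reshape(4, 4))
        assert sample_at(r, 0.125, 0.875) == r.values[0, 0]
        assert sample_at(r, 0.625, 0.625) == r.values[1, 2]

    def test_shared_edge_goes_east_north(self):
        r = raster(np.arange(16.0).reshape(4, 4))
        # lon exactly on the boundary between cols 1 and 2 -> east cell (col 2)
        # lat exactly on the boundary between rows 1 and 2 -> north cell (row 1)
        assert sample_at(r, 0.5, 0.5) == r.values[1, 2]

    def test_outside_raises(self):
        r = raster(np.ones((4, 4)))
        with pytest.raises(OutOfWindowError):
            sample_at(r, 1.5, 0.5)

    def test_matches_floor_index_arithmetic(self, rng):
        vals = rng.normal(size=(10, 10))
        r = raster(vals)
        for _ in range(100):
            lon, lat = rng.uniform(0, 1, 2) * 0.9999
            col = int(np.floor((lon - 0.0) / r.cell))
            row = 9 - int(np.floor((lat - 0.0) / r.cell))
            assert sample_at(r, lon, lat) == vals[row, col]

    def test_rank_then_sample_preserves_order(self, rng):
        vals = rng.normal(size=(8, 8))
        r = raster(vals)
        ranked = rank_standardise(r)
        pts = rng.uniform(0.01, 0.99, size=(30, 2))
        raw = [sample_at(r, x, y) for x, y in pts]
        rk = [sample_at(ranked, x, y) for x, y in pts]
        assert np.array_equal(np.argsort(raw, kind="stable"), np.argsort(rk, kind="stable"))


class TestTemporalPredictability:
    def _stack(self, fields):
        return {D0 + dt.timedelta(days=i): raster(f) for i, f in enumerate(fields)}

    def test_identical_images_give_one(self, rng):
        f = rng.normal(size=(6, 6))
        assert temporal_predictability(self._stack([f, f.copy(), f.copy()])) == pytest.approx(1.0)

    def test_independent_noise_near_zero(self, rng):
        vals = [temporal_predictability(self._stack(rng.normal(size=(5, 20, 20))))
                for _ in range(10)]
        assert abs(np.mean(vals)) < 0.05

    def test_generated_day_correlation_recovered(self):
        from fptrack import SimConfig, simulate_rasters

        ests = []
        for seed in range(10):
            cfg = SimConfig(day_rho=0.8, cloud_fraction=0.0)
            rngl = np.random.default_rng(seed)
            days = [D0 + dt.timedelta(days=i) for i in range(6)]
            rs = simulate_rasters(cfg, rngl, days)
            # mean over consecutive-day pairs only isolates the AR(1) rho
            sst = rs["sst"]
            cons = [np.corrcoef(sst[days[i]].values.ravel(),
                                sst[days[i + 1]].values.ravel())[0, 1]
                    for i in range(5)]
            ests.append(np.mean(cons))
        assert np.mean(ests) == pytest.approx(0.8, abs=0.1)


class TestCovariateCorrelations:
    def test_collinear_columns(self):
        import pandas as pd

        x = np.linspace(0, 20, 50)
        df = pd.DataFrame({"sst_rank": x, "turbidity_rank": x, "chla_rank": x[::-1]})
        corr = covariate_correlations(df)
        assert corr[("sst", "turbidity")] == pytest.approx(1.0)
        assert corr[("sst", "chla")] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self, rng):
        import pandas as pd

        df = pd.DataFrame({f"{v}_rank": rng.uniform(0, 20, 1000)
                           for v in ("sst", "turbidity", "chla")})
        corr = covariate_correlations(df)
        assert all(abs(v) < 0.1 for v in corr.values())

    def test_generator_cross_correlation_recovered(self):
        from fptrack import SimConfig, simulate_rasters

        cfg = SimConfig(cross_rho=0.5, cloud_fraction=0.0)
        rngl = np.random.default_rng(0)
        days = [D0 + dt.timedelta(days=i) for i in range(8)]
        rs = simulate_rasters(cfg, rngl, days)
        cors = []
        for d in days:
            a = rs["sst"][d].values.ravel()
            b = rs["turbidity"][d].values.ravel()
            cors.append(np.corrcoef(a, b)[0, 1])
        assert np.mean(cors) == pytest.approx(0.5, abs=0.15)


class TestAsciiGridRoundTrip:
    def test_round_trip(self, tmp_path, rng):
        vals = rng.normal(size=(12, 9))
        vals[0, 0] = np.nan
        r = DailyRaster("chla", D0, vals, -33.0, -3.0, 0.05)
        write_ascii_grid(r, tmp_path / "chla_20150901.asc")
        back = read_ascii_grid(tmp_path / "chla_20150901.asc", "chla", D0)
        np.testing.assert_allclose(back.values, vals, atol=1e-5, equal_nan=True)
        assert back.west == pytest.approx(-33.0) and back.north == pytest.approx(-3.0)
        assert back.cell == pytest.approx(0.05)
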