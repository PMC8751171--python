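"""AOD screening/merging/resampling and ordinary kriging."""

import numpy as np
import pytest

from mslur.aod_met import (QA_CLEAR, QA_CLOUDY, QA_POSSIBLY_CLOUDY, AODScene,
                           daily_merge, fit_exponential_variogram,
                           krige_met, krige_points, qa_filter,
                           resample_bilinear)
from mslur.geo_io import RasterGrid

from .oracles import ok_system_predict


def make_scene(aod, cloud=QA_CLEAR, coast=False, sensor="Terra", date=0):
    aod = np.asarray(aod, dtype=float)
    grid = RasterGrid(aod, 0.0, aod.shape[0] * 1000.0, 1000.0,
                      nodata=-9999.0)
    return AODScene(
        aod=grid,
        qa_cloud=np.full(aod.shape, cloud),
        qa_adjacency=np.zeros(aod.shape, dtype=int),
        coastline=np.full(aod.shape, coast, dtype=bool),
        sensor=sensor, date=date)


class TestQAFilter:
    def test_all_clear_retained(self):
        scene, mask = qa_filter(make_scene(np.full((4, 4), 0.5)))
        assert mask.all()
        assert scene.aod.valid_mask.all()

    def test_all_cloudy_dropped(self):
        with pytest.warns(UserWarning, match="no valid AOD"):
            scene, mask = qa_filter(
                make_scene(np.full((4, 4), 0.5), cloud=QA_CLOUDY))
        assert not mask.any()
        assert not scene.aod.valid_mask.any()

    def test_possibly_cloudy_retained(self):
        scene, mask = qa_filter(
            make_scene(np.full((4, 4), 0.5), cloud=QA_POSSIBLY_CLOUDY))
        assert mask.all()

    def test_cloudy_coastline_retained(self):
        scene, mask = qa_filter(
            make_scene(np.full((4, 4), 0.5), cloud=QA_CLOUDY, coast=True))
        assert mask.all()

    def test_idempotent(self):
        raw = make_scene(np.full((4, 4), 0.5), cloud=QA_CLOUDY)
        raw.qa_cloud[0, 0] = QA_CLEAR
        once, _ = qa_filter(raw)
        twice, _ = qa_filter(once)
        np.testing.assert_array_equal(once.aod.values, twice.aod.values)

    def test_retention_monotone_as_filters_tighten(self):
        rng = np.random.default_rng(0)
        raw = make_scene(rng.uniform(0, 1, (6, 6)))
        raw.qa_cloud = rng.integers(0, 3, (6, 6))
        raw.coastline = rng.random((6, 6)) < 0.3
        _, loose = qa_filter(raw)
        strict = raw
        strict.coastline = np.zeros((6, 6), dtype=bool)  # drop coast rule
        _, tight = qa_filter(strict)
        assert tight.sum() <= loose.sum()


class TestDailyMerge:
    def test_mean_of_both(self):
        merged = daily_merge(make_scene([[0.4]]), make_scene([[0.6]],
                                                             sensor="Aqua"))
        assert merged.values[0, 0] == pytest.approx(0.5)

    def test_single_sensor_fallback(self):
        terra = make_scene([[-9999.0]])
        merged = daily_merge(terra, make_scene([[0.3]], sensor="Aqua"))
        assert merged.values[0, 0] == pytest.approx(0.3)

    def test_both_missing_nodata(self):
        merged = daily_merge(make_scene([[-9999.0]]),
                             make_scene([[-9999.0]], sensor="Aqua"))
        assert merged.values[0, 0] == -9999.0

    def test_geometry_mismatch_rejected(self):
        with pytest.raises(ValueError, match="geometry"):
            daily_merge(make_scene(np.zeros((2, 2))),
                        make_scene(np.zeros((3, 3)), sensor="Aqua"))


class TestResampleBilinear:
    def test_constant_stays_constant(self):
        grid = RasterGrid(np.full((4, 4), 2.5), 0.0, 4000.0, 1000.0)
        fine = resample_bilinear(grid, 100.0)
        assert fine.cell == 100.0
        np.testing.assert_allclose(fine.values, 2.5)

    def test_midpoint_between_cells(self):
        grid = RasterGrid(np.array([[2.0, 4.0]]), 0.0, 1000.0, 1000.0)
        fine = resample_bilinear(grid, 100.0)
        # the exact midpoint (x=1000) falls on a fine-cell edge; the two
        # adjacent fine centers straddle it symmetrically -> mean 3.0
        left = fine.sample(950.0, 500.0)
        right = fine.sample(1050.0, 500.0)
        assert 0.5 * (left + right) == pytest.approx(3.0)

    def test_source_centers_preserved(self):
        # odd ratio: fine cell centers coincide with source centers
        rng = np.random.default_rng(1)
        grid = RasterGrid(rng.normal(size=(5, 5)), 0.0, 5000.0, 1000.0)
        fine = resample_bilinear(grid, 200.0)
        for r in range(5):
            for c in range(5):
                x, y = grid.rc_to_xy(r, c)
                assert fine.sample(x, y) == pytest.approx(
                    grid.values[r, c], abs=1e-9)

    def test_bounded_by_neighbors(self):
        rng = np.random.default_rng(2)
        grid = RasterGrid(rng.uniform(0, 1, (6, 6)), 0.0, 6000.0, 1000.0)
        fine = resample_bilinear(grid, 200.0)
        assert fine.values.max() <= grid.values.max() + 1e-12
        assert fine.values.min() >= grid.values.min() - 1e-12

    def test_nodata_renormalization(self):
        vals = np.array([[2.0, -9999.0], [2.0, 2.0]])
        grid = RasterGrid(vals, 0.0, 2000.0, 1000.0, nodata=-9999.0)
        fine = resample_bilinear(grid, 500.0)
        # valid fine cells only average valid neighbors -> all 2.0
        valid = fine.valid_mask
        np.testing.assert_allclose(fine.values[valid], 2.0)


SQUARE = np.array([[0.0, 0.0], [1000.0, 0.0], [0.0, 1000.0],
                   [1000.0, 1000.0]])


class TestKriging:
    def test_constant_field(self):
        grid = RasterGrid(np.zeros((5, 5)), 0.0, 1000.0, 200.0)
        out = krige_met(np.full(4, 17.0), SQUARE, grid)
        np.testing.assert_allclose(out.values, 17.0)

    def test_exact_at_stations(self):
        rng = np.random.default_rng(3)
        coords = rng.uniform(0, 1000, (8, 2))
        values = rng.uniform(10, 30, 8)
        pred = krige_points(values, coords, coords)
        rangev = values.max() - values.min()
        np.testing.assert_allclose(pred, values, atol=1e-6 * rangev)

    def test_symmetric_square_center_matches_system_oracle(self):
        values = np.array([10.0, 20.0, 30.0, 40.0])
        sill, rng_m = 50.0, 800.0
        center = np.array([[500.0, 500.0]])
        pred = krige_points(values, SQUARE, center,
                            variogram=(sill, rng_m))[0]
        oracle = ok_system_predict(SQUARE, values, (500.0, 500.0),
                                   sill, rng_m)
        assert pred == pytest.approx(oracle, abs=1e-9)
        # full symmetry -> equal weights -> plain mean
        assert pred == pytest.approx(values.mean(), abs=1e-9)

    def test_predictions_within_observed_range(self):
        rng = np.random.default_rng(4)
        coords = rng.uniform(0, 2000, (10, 2))
        values = 20 + 5 * np.sin(coords[:, 0] / 500.0)
        grid = RasterGrid(np.zeros((10, 10)), 0.0, 2000.0, 200.0)
        out = krige_met(values, coords, grid)
        assert out.values.max() <= values.max() + 1e-6
        assert out.values.min() >= values.min() - 1e-6

    def test_duplicate_coordinates_rejected(self):
        coords = np.vstack([SQUARE, SQUARE[:1]])
        with pytest.raises(ValueError, match="duplicate"):
            krige_points(np.arange(5.0), coords, np.array([[1.0, 1.0]]))

    def test_negative_met_clipped(self):
        rng = np.random.default_rng(5)
        coords = rng.uniform(0, 1000, (6, 2))
        values = np.array([0.0, 0.1, 0.0, 5.0, 0.0, 0.0])  # spotty rain
        grid = RasterGrid(np.zeros((8, 8)), 0.0, 1000.0, 125.0)
        out = krige_met(values, coords, grid, variable="RF")
        assert (out.values >= 0).all()

    def test_variogram_fit_recovers_smooth_structure(self):
        rng = np.random.default_rng(6)
        coords = rng.uniform(0, 3000, (40, 2))
        values = np.sin(coords[:, 0] / 700.0) + np.cos(coords[:, 1] / 900.0)
        sill, rng_m = fit_exponential_variogram(coords, values)
        assert sill > 0
        assert 10.0 < rng_m < 50_000.0
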