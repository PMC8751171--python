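"""Morphology indices against direct evaluation and independent oracles."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, box

from mslur.geo_io import RasterGrid
from mslur.morphology import (PointFAIParams, SVFParams, WindRose,
                              buffered_fai, decay_weight, frontal_area,
                              frontal_area_index, point_fai,
                              roughness_length, sky_view_factor, svf_grid)

from .oracles import fine_grid_point_fai, mc_svf, silhouette_frontal_area

CUBE = [(box(45, 45, 55, 55), 10.0)]  # 10 m cube centered at (50, 50)
LOT = box(0, 0, 100, 100)


class TestWindRose:
    def test_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            WindRose(np.full(8, 0.2))

    def test_direction_vectors_unit(self):
        for k in range(8):
            dx, dy = WindRose.direction_vector(k)
            assert math.hypot(dx, dy) == pytest.approx(1.0)


class TestFrontalAreaIndex:
    def test_no_buildings_zero(self):
        assert frontal_area_index([], LOT, WindRose.uniform()) == 0.0

    def test_cube_single_direction(self):
        # 10x10 m front: A_F = 100 m² in a 10^4 m² lot
        fai = frontal_area_index(CUBE, LOT, WindRose.single(0))
        assert fai == pytest.approx(0.01, abs=1e-12)

    @pytest.mark.parametrize("k", range(8))
    def test_silhouette_matches_rasterized_oracle(self, k):
        rng = np.random.default_rng(k)
        blds = [(box(x, y, x + w, y + w), h)
                for x, y, w, h in zip(rng.uniform(0, 80, 5),
                                      rng.uniform(0, 80, 5),
                                      rng.uniform(5, 15, 5),
                                      rng.uniform(5, 40, 5))]
        mine = frontal_area(blds, k)
        oracle = silhouette_frontal_area(blds, k, resolution=0.01)
        assert mine == pytest.approx(oracle, rel=5e-3)

    def test_cube_uniform_rose_matches_oracle(self):
        # diagonal silhouettes are sqrt(2) wider than cardinal ones, so
        # the 8-direction mean exceeds the cardinal-only value
        fai = frontal_area_index(CUBE, LOT, WindRose.uniform())
        oracle = sum(0.125 * silhouette_frontal_area(CUBE, k, 0.01)
                     for k in range(8)) / LOT.area
        assert fai == pytest.approx(oracle, rel=1e-3)
        assert fai == pytest.approx((4 * 100 + 4 * 100 * math.sqrt(2))
                                    / 8 / 1e4, rel=1e-9)

    def test_occlusion_merges_not_sums(self):
        # two identical cubes aligned along the wind: one silhouette
        twin = CUBE + [(box(45, 20, 55, 30), 10.0)]
        fai = frontal_area_index(twin, LOT, WindRose.single(0))
        assert fai == pytest.approx(0.01, abs=1e-12)

    def test_zero_lot_area_rejected(self):
        with pytest.raises(ValueError, match="lot area"):
            frontal_area_index(CUBE, box(0, 0, 0, 0), WindRose.uniform())


class TestBufferedFAI:
    def test_empty_buffer_zero(self):
        assert buffered_fai([], (50, 50), 250.0, WindRose.uniform()) == 0.0

    def test_linear_in_height(self):
        rose = WindRose.uniform()
        v1 = buffered_fai(CUBE, (50, 50), 250.0, rose)
        v2 = buffered_fai([(f, 2 * h) for f, h in CUBE], (50, 50), 250.0,
                          rose)
        assert v2 == pytest.approx(2 * v1, rel=1e-12)

    def test_cube_in_250m_buffer(self):
        v = buffered_fai(CUBE, (50, 50), 250.0, WindRose.single(2))
        assert v == pytest.approx(100.0 / (math.pi * 250.0 ** 2), rel=1e-9)


class TestDecayWeight:
    @pytest.mark.parametrize("l,expected", [
        (0.0, 1.0), (200.0, 0.0), (100.0, 0.25)])
    def test_values(self, l, expected):
        assert decay_weight(l, 200.0, 2.0) == pytest.approx(expected)

    def test_outside_circle_zero(self):
        assert decay_weight(250.0, 200.0, 2.0) == 0.0

    def test_strictly_decreasing(self):
        ls = np.linspace(0, 200, 50)
        w = decay_weight(ls, 200.0, 2.0)
        assert np.all(np.diff(w) < 0)


class TestPointFAI:
    def test_empty_circle_zero(self):
        p = PointFAIParams(R=200.0, step=10.0)
        assert point_fai([], (0, 0), p, WindRose.uniform()) == 0.0

    def test_adding_building_increases(self):
        p = PointFAIParams(R=200.0, step=10.0)
        rose = WindRose.uniform()
        base = point_fai(CUBE, (50, 50), p, rose)
        more = point_fai(CUBE + [(box(100, 100, 115, 110), 20.0)],
                         (50, 50), p, rose)
        assert more > base > 0

    def test_step_too_coarse_rejected(self):
        with pytest.raises(ValueError, match="too coarse"):
            PointFAIParams(R=200.0, step=30.0)

    def test_matches_fine_grid_oracle(self):
        # single cube at distance ~100 m from the test point
        blds = [(box(145, 45, 155, 55), 12.0)]
        p = PointFAIParams(R=200.0, c=2.0, step=2.0)
        mine = point_fai(blds, (50, 50), p, WindRose.uniform())
        oracle = fine_grid_point_fai(blds, (50, 50), R=200.0, c=2.0,
                                     step=1.0)
        assert mine == pytest.approx(oracle, rel=0.01)

    def test_c_to_zero_recovers_buffered_density(self):
        # with a vanishing decay exponent and a single (unoccluded)
        # building the integral reduces to the plain buffered FAI
        blds = [(box(145, 45, 155, 55), 12.0)]
        p = PointFAIParams(R=200.0, c=1e-9, step=2.0)
        v = point_fai(blds, (50, 50), p, WindRose.uniform())
        ref = buffered_fai(blds, (50, 50), 200.0, WindRose.uniform())
        assert v == pytest.approx(ref, rel=0.01)


def canyon_dsm(width_cells: int, height: float, n: int = 60,
               cell: float = 2.0) -> RasterGrid:
    """North-south street canyon: walls either side of a flat floor."""
    vals = np.full((n, n), height)
    mid = n // 2
    half = width_cells // 2
    vals[:, mid - half:mid + half + 1] = 0.0
    return RasterGrid(vals, 0.0, n * cell, cell, crs="LOCAL")


class TestSkyViewFactor:
    def test_flat_dsm_open_sky(self, grid20):
        v = sky_view_factor(grid20, (100, 100), SVFParams(d=80.0))
        assert v == 1.0

    def test_fully_enclosed_zero(self):
        # a pit: the observer cell is ringed by extremely tall walls
        vals = np.full((21, 21), 1e6)
        vals[10, 10] = 0.0
        dsm = RasterGrid(vals, 0.0, 210.0, 10.0)
        x, y = dsm.rc_to_xy(10, 10)
        v = sky_view_factor(dsm, (x, y), SVFParams(n_azimuths=16, d=50.0))
        assert v == pytest.approx(0.0, abs=1e-6)

    def test_uniform_45_degree_horizon_value(self):
        # the cos² kernel gives exactly 0.5 for a uniform 45° horizon,
        # matching the hemispheric view factor of an infinite 45° pit
        phi = math.radians(45.0)
        assert math.cos(phi) ** 2 == pytest.approx(0.5)

    def test_canyon_matches_monte_carlo(self):
        dsm = canyon_dsm(width_cells=5, height=20.0)
        x, y = dsm.rc_to_xy(30, 30)
        v = sky_view_factor(dsm, (x, y),
                            SVFParams(n_azimuths=64, d=60.0))
        mc = mc_svf(dsm, (x, y), n_rays=100_000, max_dist=60.0, seed=3)
        assert v == pytest.approx(mc, abs=0.01)

    def test_point_outside_dsm_rejected(self, grid20):
        with pytest.raises(ValueError, match="outside"):
            sky_view_factor(grid20, (1e6, 1e6), SVFParams())

    def test_monotone_in_dsm_height(self, grid20):
        p = SVFParams(n_azimuths=8, d=80.0)
        base = sky_view_factor(grid20, (105, 105), p)
        taller = grid20.with_values(grid20.values.copy())
        taller.values[5, 12] = 30.0
        assert sky_view_factor(taller, (105, 105), p) <= base

    def test_grid_matches_pointwise_on_canyon(self):
        dsm = canyon_dsm(width_cells=5, height=20.0)
        g = svf_grid(dsm, max_dist=60.0)
        r, c = 30, 30
        x, y = dsm.rc_to_xy(r, c)
        pt = sky_view_factor(dsm, (x, y),
                             SVFParams(n_azimuths=8, d=60.0))
        assert g.values[r, c] == pytest.approx(pt, abs=0.05)

    def test_translation_invariance(self):
        dsm1 = canyon_dsm(5, 20.0)
        dsm2 = RasterGrid(dsm1.values, 1000.0, 2000.0 + dsm1.y0, dsm1.cell)
        p = SVFParams(n_azimuths=8, d=60.0)
        v1 = sky_view_factor(dsm1, dsm1.rc_to_xy(30, 30), p)
        v2 = sky_view_factor(dsm2, dsm2.rc_to_xy(30, 30), p)
        assert v1 == pytest.approx(v2, abs=1e-12)


class TestRoughness:
    def test_empty_buffer(self):
        assert roughness_length([], (0, 0), 100.0) == 0.0

    def test_uniform_height(self):
        blds = [(box(i * 20, 0, i * 20 + 10, 10), 10.0) for i in range(3)]
        assert roughness_length(blds, (30, 5), 100.0) == pytest.approx(1.0)

    def test_height_mixture(self):
        blds = [(box(0, 0, 10, 10), 10.0), (box(30, 0, 40, 10), 30.0)]
        assert roughness_length(blds, (20, 5), 100.0) == pytest.approx(2.0)
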