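"""GTWR local fits, bandwidth selection, and validation diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest

from mslur.geo_io import RasterGrid
from mslur.gtwr import (STKernelSpec, aicc, fit_gtwr, loocv,
                        predict_surface, select_bandwidth, st_weights)

from .oracles import aicc_reference, ols_coefficients


def sim_data(n=200, seed=0, noise=0.5, varying=False):
    """(table, response, coords, times); optionally a slope varying in x."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 2000, (n, 2))
    times = rng.uniform(0, 48, n)
    x1 = rng.normal(size=n)
    x2 = rng.normal(size=n)
    slope = 2.0 + (3.0 * coords[:, 0] / 2000.0 if varying else 0.0)
    y = 5.0 + slope * x1 - 1.0 * x2 + noise * rng.normal(size=n)
    table = pd.DataFrame({"x1": x1, "x2": x2})
    return table, y, coords, times


class TestWeights:
    def test_zero_distance_unity(self):
        spec = STKernelSpec(h=500.0, lam=1.0)
        w = st_weights((0, 0), 0.0, np.array([[0.0, 0.0]]),
                       np.array([0.0]), spec)
        assert w[0] == 1.0

    def test_lambda_zero_is_pure_spatial(self):
        spec = STKernelSpec(h=500.0, lam=0.0)
        w1 = st_weights((0, 0), 0.0, np.array([[300.0, 400.0]]),
                        np.array([0.0]), spec)
        w2 = st_weights((0, 0), 0.0, np.array([[300.0, 400.0]]),
                        np.array([999.0]), spec)
        assert w1[0] == pytest.approx(w2[0])

    def test_gaussian_at_bandwidth(self):
        spec = STKernelSpec(h=500.0, lam=0.0)
        w = st_weights((0, 0), 0.0, np.array([[500.0, 0.0]]),
                       np.array([0.0]), spec)
        assert w[0] == pytest.approx(math.exp(-1.0), abs=1e-12)

    def test_bisquare_compact_support(self):
        spec = STKernelSpec(kernel="bisquare", h=500.0, lam=0.0)
        w = st_weights((0, 0), 0.0,
                       np.array([[600.0, 0.0], [100.0, 0.0]]),
                       np.zeros(2), spec)
        assert w[0] == 0.0
        assert 0 < w[1] < 1


class TestFit:
    def test_infinite_bandwidth_reduces_to_ols(self):
        table, y, coords, times = sim_data(n=200, seed=1)
        spec = STKernelSpec(h=1e9, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        beta_ols = ols_coefficients(table.to_numpy(), y)
        local = fit.coefficients.to_numpy()
        assert np.abs(local - beta_ols[None, :]).max() < 1e-6

    def test_constant_coefficient_recovery(self):
        reps, bias = 20, []
        for seed in range(reps):
            table, y, coords, times = sim_data(n=150, seed=seed, noise=0.5)
            spec = STKernelSpec(h=2000.0, lam=0.0)
            fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
            bias.append(fit.coefficients["x1"].mean() - 2.0)
        se = np.std(bias, ddof=1) / math.sqrt(reps)
        assert abs(np.mean(bias)) < 2 * se + 0.02

    def test_varying_slope_surface_recovered(self):
        table, y, coords, times = sim_data(n=400, seed=2, noise=0.2,
                                           varying=True)
        spec = STKernelSpec(h=400.0, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        truth = 2.0 + 3.0 * coords[:, 0] / 2000.0
        r = np.corrcoef(fit.coefficients["x1"], truth)[0, 1]
        assert r > 0.9

    def test_fitted_plus_residual_is_observed(self):
        table, y, coords, times = sim_data(n=100, seed=3)
        spec = STKernelSpec(h=800.0, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        np.testing.assert_allclose(fit.fitted + fit.residuals, y,
                                   atol=1e-10)
        assert 0 < fit.trace_s < len(y)

    def test_local_weighted_orthogonality(self):
        table, y, coords, times = sim_data(n=80, seed=4)
        spec = STKernelSpec(h=600.0, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        # at each local fit the weighted residual is orthogonal to X
        i = 17
        w = st_weights(coords[i], times[i], coords, times, spec)
        Xw = fit.X * w[:, None]
        beta_i = fit.coefficients.iloc[i].to_numpy()
        resid_i = fit.y - fit.X @ beta_i
        assert np.abs(Xw.T @ resid_i).max() < 1e-8

    def test_needs_enough_rows(self):
        table, y, coords, times = sim_data(n=4)
        with pytest.raises(ValueError, match="n > p"):
            fit_gtwr(table, y, coords, times, ["x1", "x2"],
                     STKernelSpec())


class TestAICc:
    def test_formula_matches_independent_rewrite(self):
        for rss, n, k in [(12.3, 64, 5.2), (100.0, 200, 11.0)]:
            assert aicc(rss, n, k) == pytest.approx(
                aicc_reference(rss, n, k), abs=1e-9)

    def test_undefined_when_saturated(self):
        assert aicc(1.0, 10, 9.0) == math.inf


class TestBandwidthSelection:
    def test_single_candidate_returned(self):
        table, y, coords, times = sim_data(n=60, seed=5)
        spec, profile = select_bandwidth(table, y, coords, times,
                                         ["x1", "x2"], "gaussian",
                                         [750.0], [0.0])
        assert spec.lam == 0.0
        assert len(profile) == 1

    def test_global_data_prefers_large_bandwidth(self):
        table, y, coords, times = sim_data(n=150, seed=6, noise=0.3)
        grid = [200.0, 500.0, 1000.0, 4000.0]
        spec, _ = select_bandwidth(table, y, coords, times, ["x1", "x2"],
                                   "gaussian", grid, [0.0])
        assert spec.h >= 1000.0

    def test_varying_data_prefers_finite_bandwidth(self):
        table, y, coords, times = sim_data(n=300, seed=7, noise=0.2,
                                           varying=True)
        grid = [200.0, 500.0, 1000.0, 4000.0, 16000.0]
        spec, _ = select_bandwidth(table, y, coords, times, ["x1", "x2"],
                                   "gaussian", grid, [0.0])
        assert spec.h < 16000.0


class TestLOOCV:
    def test_noiseless_linear_near_one(self):
        table, y, coords, times = sim_data(n=80, seed=8, noise=0.0)
        cv = loocv(table, y, coords, times, ["x1", "x2"],
                   STKernelSpec(h=1e9, lam=0.0))
        assert cv > 1.0 - 1e-6

    def test_cv_not_above_in_sample_r2(self):
        for seed in range(5):
            table, y, coords, times = sim_data(n=100, seed=seed, noise=1.0)
            spec = STKernelSpec(h=800.0, lam=0.0)
            fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
            cv = loocv(table, y, coords, times, ["x1", "x2"], spec)
            assert cv <= fit.diagnostics["r2"] + 1e-9

    def test_permuted_response_near_zero(self):
        table, y, coords, times = sim_data(n=100, seed=9, noise=0.5)
        rng = np.random.default_rng(10)
        yp = rng.permutation(y)
        cv = loocv(table, yp, coords, times, ["x1", "x2"],
                   STKernelSpec(h=800.0, lam=0.0))
        assert cv <= 0.1


class TestPredictSurface:
    def _constant_grids(self, n=8, cell=10.0):
        def grid(v):
            return RasterGrid(np.full((n, n), v), 0.0, n * cell, cell)
        return {"x1": grid(0.7), "x2": grid(-0.2), "AOD": grid(0.5)}

    def test_constant_grids_constant_map(self):
        table, y, coords, times = sim_data(n=60, seed=11)
        # keep calibration coords inside the grid so weights are sane
        coords = coords % 80.0
        spec = STKernelSpec(h=1e6, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        out = predict_surface(fit, self._constant_grids(), 0.0)
        vals = out.values[out.valid_mask]
        assert np.ptp(vals) < 1e-6

    def test_missing_grid_named(self):
        table, y, coords, times = sim_data(n=60, seed=12)
        spec = STKernelSpec(h=1e6, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        grids = self._constant_grids()
        del grids["x2"]
        with pytest.raises(ValueError, match="x2"):
            predict_surface(fit, grids, 0.0)

    def test_nodata_aod_propagates(self):
        table, y, coords, times = sim_data(n=60, seed=13)
        coords = coords % 80.0
        spec = STKernelSpec(h=1e6, lam=0.0)
        fit = fit_gtwr(table, y, coords, times, ["x1", "x2"], spec)
        grids = self._constant_grids()
        grids["AOD"].values[2, 3] = grids["AOD"].nodata
        out = predict_surface(fit, grids, 0.0)
        assert not out.valid_mask[2, 3]
        assert out.valid_mask.sum() == out.values.size - 1
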