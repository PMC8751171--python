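"""Seasonal/annual city-scale PM2.5 maps, the road-space ΔPM2.5 layer, and
the final overlay.

The annual map is the day-count-weighted mean of the seasonal maps over
whichever seasons are valid at each cell (renormalised when a season is
missing), with an annual pooled R² computed over the concatenated seasonal
fitted/observed pairs.  The ΔPM2.5 layer is predicted only on road-space
cells whose every retained predictor lies inside the model's stored
training range — no extrapolation — and the overlay adds Δ to the city
map where valid, flooring negative results at 0.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo_io import RasterGrid, RoadGraph
from .gtwr import predict_surface
from .neighborhood import DeltaModel
from .predictors import road_mask_grid

__all__ = [
    "seasonal_maps", "annual_combine", "delta_layer", "overlay",
    "road_cell_predictors", "quicklook",
]

log = logging.getLogger(__name__)


def seasonal_maps(fits: dict, predictor_grids: dict, period_times: dict
                  ) -> dict:
    """One prediction surface per season.

    ``fits`` maps season -> GTWRFit; ``predictor_grids`` maps season ->
    {variable: RasterGrid} (AOD at 10 m via bilinear resampling);
    ``period_times`` maps season -> representative time (day).
    """
    out = {}
    for season, fit in fits.items():
        if season not in predictor_grids:
            raise ValueError(f"no predictor grids for season {season!r}")
        out[season] = predict_surface(fit, predictor_grids[season],
                                      period_times[season])
    ref = next(iter(out.values()))
    for season, grid in out.items():
        if not grid.same_geometry(ref):
            raise ValueError(f"season {season} map misaligned")
    return out


def annual_combine(seasonal: dict, day_counts: dict,
                   fits: dict | None = None) -> tuple[RasterGrid, dict]:
    """Day-count-weighted annual mean map plus pooled diagnostics.

    At each cell only the seasons with valid data contribute, with their
    weights renormalised; cells valid in no season stay nodata.  When
    ``fits`` is given, the annual R² pools the seasonal fitted/observed
    pairs.
    """
    seasons = list(seasonal)
    ref = seasonal[seasons[0]]
    acc = np.zeros(ref.values.shape)
    wacc = np.zeros(ref.values.shape)
    for s in seasons:
        grid = seasonal[s]
        if not grid.same_geometry(ref):
            raise ValueError("seasonal maps misaligned")
        w = float(day_counts[s])
        valid = grid.valid_mask
        acc += np.where(valid, grid.values * w, 0.0)
        wacc += np.where(valid, w, 0.0)
    vals = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), ref.nodata)
    annual = ref.with_values(vals)
    diag = {}
    if fits:
        obs = np.concatenate([fits[s].y for s in seasons if s in fits])
        fitted = np.concatenate([fits[s].fitted for s in seasons
                                 if s in fits])
        rss = float(np.sum((obs - fitted) ** 2))
        tss = float(np.sum((obs - obs.mean()) ** 2))
        n = len(obs)
        k = sum(fits[s].trace_s for s in seasons if s in fits)
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        diag = {"annual_r2": r2,
                "annual_adj_r2": 1.0 - (1.0 - r2) * (n - 1)
                / max(n - k - 1, 1e-9),
                "n_pooled": n}
    return annual, diag


def delta_layer(model: DeltaModel, predictor_table: pd.DataFrame,
                rows: np.ndarray, cols: np.ndarray, template: RasterGrid
                ) -> tuple[RasterGrid, dict]:
    """Predict ΔPM2.5 on road-space cells with the no-extrapolation mask.

    ``predictor_table`` holds one row per road-space cell (same order as
    ``rows``/``cols``) with all retained predictors; cells with any
    predictor outside the training range, or any NaN, become nodata.
    Returns the Δ raster and a mask report.
    """
    vals = np.full(template.values.shape, template.nodata)
    finite = np.all(np.isfinite(
        predictor_table[model.predictors].to_numpy(dtype=float)), axis=1) \
        if model.predictors else np.ones(len(predictor_table), dtype=bool)
    inside = model.within_range(predictor_table) & finite
    pred = model.predict(predictor_table.fillna(0.0))
    vals[rows[inside], cols[inside]] = pred[inside]
    report = {
        "n_road_cells": int(len(predictor_table)),
        "n_valid": int(inside.sum()),
        "n_out_of_range": int(len(predictor_table) - inside.sum()),
    }
    return template.with_values(vals), report


def road_cell_predictors(roads: RoadGraph, seg_metrics: pd.DataFrame,
                         svf: RasterGrid, fai_point: RasterGrid,
                         halfwidth: float = 12.0):
    """Per-road-cell neighborhood predictor table for the Δ layer.

    Every cell within the street half-width of a segment inherits that
    segment's metrics (nearest segment wins) and carries its own cell SVF
    and point-FAI.  Returns (table, rows, cols).
    """
    from shapely.geometry import Point
    from shapely.strtree import STRtree

    mask = road_mask_grid(roads, svf, halfwidth=halfwidth)
    rows, cols = np.nonzero(mask)
    x, y = svf.rc_to_xy(rows, cols)
    segs = roads.segments()
    tree = STRtree([rec["geometry"] for rec in segs])
    ids = [rec["edge_id"] for rec in segs]
    pts = [Point(xi, yi) for xi, yi in zip(x, y)]
    idx_pt, idx_geom = tree.query_nearest(pts, all_matches=False)
    seg_ids = np.empty(len(pts), dtype=int)
    seg_ids[idx_pt] = [ids[g] for g in idx_geom]
    table = seg_metrics.loc[seg_ids].reset_index(drop=True)
    table["SVF"] = svf.values[rows, cols]
    table["FAI_POINT"] = fai_point.values[rows, cols]
    return table, rows, cols


def quicklook(grid: RasterGrid, path, threshold: float = 35.0,
              title: str = "") -> None:
    """PNG quicklook with a contour at *threshold* (µg/m³), default the
    35 µg/m³ annual air-quality-objective limit."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.where(grid.valid_mask, grid.values, np.nan)
    fig, ax = plt.subplots(figsize=(6, 5))
    xmin, ymin, xmax, ymax = grid.bounds
    im = ax.imshow(vals, extent=(xmin, xmax, ymin, ymax), cmap="viridis")
    if np.nanmin(vals) < threshold < np.nanmax(vals):
        ax.contour(np.flipud(vals), levels=[threshold], colors="red",
                   extent=(xmin, xmax, ymin, ymax))
    fig.colorbar(im, ax=ax, label="PM2.5 (µg/m³)")
    ax.set_title(title)
    fig.savefig(path, dpi=120)
    plt.close(fig)


def overlay(city: RasterGrid, delta: RasterGrid) -> RasterGrid:
    """Final map: city + Δ where Δ is valid, city elsewhere; negatives
    floored at 0 with a logged count."""
    if not city.same_geometry(delta):
        raise ValueError("city and delta grids are misaligned")
    dvalid = delta.valid_mask
    cvalid = city.valid_mask
    vals = np.where(cvalid & dvalid, city.values + delta.values,
                    np.where(cvalid, city.values, city.nodata))
    n_neg = int(np.sum((vals < 0) & cvalid))
    if n_neg:
        log.info("overlay floored %d negative cells at 0", n_neg)
    vals = np.where(cvalid, np.maximum(vals, 0.0), city.nodata)
    return city.with_values(vals)
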