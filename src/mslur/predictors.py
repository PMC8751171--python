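"""Buffer-based spatial predictor extraction and the city-scale table.

Every spatial predictor is computed inside circular buffers around each
long-term monitoring station, one column per (variable, radius) pair:
land-use areal fractions per class, greening cover ratio, road line
densities per road class, bus-stop counts, population density, buffered
frontal area index and roughness length, plus per-station geolocation and
per-period temporal covariates (interpolated weather and sounding indices).

Raster buffering uses the cell-center-in-circle rule (a cell belongs to the
buffer iff its center lies within the radius), which is deterministic and
matches the convolution kernels used for full-grid predictor surfaces.
Point counting is boundary-inclusive.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from shapely.geometry import Point

from .geo_io import ROAD_CLASSES, RasterGrid, RoadGraph
from .morphology import WindRose, buffered_fai, roughness_length

__all__ = [
    "LANDUSE_CLASSES",
    "CLASS_ABBR",
    "areal_fraction",
    "line_density",
    "point_count",
    "disk_kernel",
    "class_fraction_grid",
    "buffer_mean_grid",
    "road_mask_grid",
    "road_length_raster",
    "line_density_grid",
    "point_count_grid",
    "assemble_table",
]

log = logging.getLogger(__name__)

#: Five-class land-use scheme: raster code -> class name.
LANDUSE_CLASSES = {
    1: "residential",
    2: "commercial",
    3: "industrial",
    4: "government",
    5: "openspace",
}
CLASS_ABBR = {
    "residential": "RES",
    "commercial": "COM",
    "industrial": "IND",
    "government": "GOV",
    "openspace": "OPN",
}
ROAD_ABBR = {cls: f"RD{i}" for i, cls in enumerate(ROAD_CLASSES)}


# ---------------------------------------------------------------------------
# Point-buffer extraction
# ---------------------------------------------------------------------------

def _buffer_cells(grid: RasterGrid, center, radius: float):
    """(rows, cols) of cells whose center lies within the buffer."""
    cx, cy = (center.x, center.y) if hasattr(center, "x") else center
    r0, c0 = grid.xy_to_rc(cx - radius, cy + radius)
    r1, c1 = grid.xy_to_rc(cx + radius, cy - radius)
    inside_r = (max(r0, 0), min(r1, grid.nrows - 1))
    inside_c = (max(c0, 0), min(c1, grid.ncols - 1))
    if inside_r != (r0, r1) or inside_c != (c0, c1):
        warnings.warn("buffer extends beyond the raster; partial coverage")
    rows = np.arange(inside_r[0], inside_r[1] + 1)
    cols = np.arange(inside_c[0], inside_c[1] + 1)
    if len(rows) == 0 or len(cols) == 0:
        return np.empty((0,), int), np.empty((0,), int)
    x, y = grid.rc_to_xy(*np.meshgrid(rows, cols, indexing="ij"))
    mask = (x - cx) ** 2 + (y - cy) ** 2 <= radius ** 2
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    return rr[mask], cc[mask]


def areal_fraction(landuse: RasterGrid, center, radius: float,
                   class_code: int) -> float:
    """Fraction of buffer cells carrying *class_code* (cell-center rule)."""
    rows, cols = _buffer_cells(landuse, center, radius)
    if len(rows) == 0:
        raise ValueError("zero cells in buffer")
    return float(np.mean(landuse.values[rows, cols] == class_code))


def buffer_mean(grid: RasterGrid, center, radius: float) -> float:
    """Mean of valid raster values inside the buffer."""
    rows, cols = _buffer_cells(grid, center, radius)
    if len(rows) == 0:
        raise ValueError("zero cells in buffer")
    vals = grid.values[rows, cols]
    valid = ~np.isclose(vals, grid.nodata)
    return float(vals[valid].mean()) if valid.any() else float("nan")


def line_density(roads: RoadGraph, center, radius: float,
                 road_class: str | None = None) -> float:
    """Length of (class-matching) road inside the buffer per unit area,
    km/km²."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    circle = Point(center).buffer(radius, quad_segs=64)
    total_m = 0.0
    for rec in roads.segments():
        if road_class is not None and rec["road_class"] != road_class:
            continue
        geom = rec["geometry"]
        if geom.intersects(circle):
            total_m += geom.intersection(circle).length
    area_km2 = math.pi * (radius / 1000.0) ** 2
    return (total_m / 1000.0) / area_km2


def point_count(points, center, radius: float) -> int:
    """Boundary-inclusive count of points within the buffer.

    *points* is an (n, 2) array or a DataFrame with x, y columns.
    """
    if hasattr(points, "columns"):
        pts = points[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    cx, cy = (center.x, center.y) if hasattr(center, "x") else center
    d2 = (pts[:, 0] - cx) ** 2 + (pts[:, 1] - cy) ** 2
    return int(np.sum(d2 <= radius ** 2 + 1e-9))


# ---------------------------------------------------------------------------
# Full-grid predictor surfaces (convolution form of the same buffer rule)
# ---------------------------------------------------------------------------

def disk_kernel(radius: float, cell: float) -> np.ndarray:
    """Binary cell-center-in-circle kernel for buffer convolutions."""
    n = int(math.floor(radius / cell))
    offs = np.arange(-n, n + 1) * cell
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    return (dx ** 2 + dy ** 2 <= radius ** 2).astype(float)


def _disk_mean(field: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    num = fftconvolve(field, kernel, mode="same")
    den = fftconvolve(np.ones_like(field), kernel, mode="same")
    return num / np.maximum(den, 1e-12)


def class_fraction_grid(landuse: RasterGrid, class_code: int,
                        radius: float) -> RasterGrid:
    """Areal fraction of *class_code* within *radius* around every cell."""
    kernel = disk_kernel(radius, landuse.cell)
    mask = (landuse.values == class_code).astype(float)
    return landuse.with_values(np.clip(_disk_mean(mask, kernel), 0.0, 1.0))


def buffer_mean_grid(grid: RasterGrid, radius: float) -> RasterGrid:
    """Buffer mean of a value raster around every cell."""
    kernel = disk_kernel(radius, grid.cell)
    return grid.with_values(_disk_mean(grid.values, kernel))


def road_length_raster(roads: RoadGraph, grid: RasterGrid,
                       road_class: str | None = None) -> RasterGrid:
    """Metres of (class-matching) road per cell, by dense sampling along
    each segment polyline."""
    vals = np.zeros(grid.values.shape)
    for rec in roads.segments():
        if road_class is not None and rec["road_class"] != road_class:
            continue
        geom = rec["geometry"]
        n = max(2, int(geom.length / (grid.cell / 4.0)) + 1)
        ts = np.linspace(0.0, 1.0, n)
        step_len = geom.length / (n - 1)
        pts = [geom.interpolate(t, normalized=True) for t in ts]
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        ok = grid.contains(xs, ys)
        if not np.any(ok):
            continue
        rr, cc = grid.xy_to_rc(xs[ok], ys[ok])
        np.add.at(vals, (rr, cc), step_len)
    return grid.with_values(vals)


def line_density_grid(roads: RoadGraph, grid: RasterGrid, radius: float,
                      road_class: str | None = None) -> RasterGrid:
    """km/km² of road within *radius* of every cell (convolution form)."""
    length = road_length_raster(roads, grid, road_class).values
    kernel = disk_kernel(radius, grid.cell)
    total_m = fftconvolve(length, kernel, mode="same")
    area_km2 = math.pi * (radius / 1000.0) ** 2
    return grid.with_values(np.maximum(total_m, 0.0) / 1000.0 / area_km2)


def point_count_grid(points, grid: RasterGrid, radius: float) -> RasterGrid:
    """Count of points within *radius* of every cell."""
    counts = np.zeros(grid.values.shape)
    if hasattr(points, "columns"):
        pts = points[["x", "y"]].to_numpy(dtype=float)
    else:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts):
        ok = grid.contains(pts[:, 0], pts[:, 1])
        rr, cc = grid.xy_to_rc(pts[ok, 0], pts[ok, 1])
        np.add.at(counts, (rr, cc), 1.0)
    kernel = disk_kernel(radius, grid.cell)
    return grid.with_values(
        np.maximum(fftconvolve(counts, kernel, mode="same"), 0.0))


def road_mask_grid(roads: RoadGraph, grid: RasterGrid,
                   halfwidth: float = 12.0) -> np.ndarray:
    """Boolean mask of cells within *halfwidth* metres of any road line."""
    from scipy.ndimage import binary_dilation

    mask = np.zeros(grid.values.shape, dtype=bool)
    step = grid.cell / 2.0
    for rec in roads.segments():
        geom = rec["geometry"]
        n = max(2, int(geom.length / step) + 1)
        pts = [geom.interpolate(t, normalized=True)
               for t in np.linspace(0.0, 1.0, n)]
        xs = np.array([p.x for p in pts])
        ys = np.array([p.y for p in pts])
        ok = grid.contains(xs, ys)
        if not np.any(ok):
            continue
        rr, cc = grid.xy_to_rc(xs[ok], ys[ok])
        mask[rr, cc] = True
    n_dilate = int(round(halfwidth / grid.cell))
    if n_dilate > 0:
        yy, xx = np.mgrid[-n_dilate:n_dilate + 1, -n_dilate:n_dilate + 1]
        struct = (xx ** 2 + yy ** 2) <= n_dilate ** 2
        mask = binary_dilation(mask, structure=struct)
    return mask


# ---------------------------------------------------------------------------
# City-scale predictor table
# ---------------------------------------------------------------------------

def station_spatial_predictors(scene, radii) -> pd.DataFrame:
    """Per-station spatial predictors at every buffer radius.

    FAI uses a uniform wind rose here so that it is a purely spatial
    predictor like the rest of the buffer family; a seasonal rose can be
    applied downstream by re-weighting.  Returns a frame indexed by
    station id.
    """
    rows = {}
    uniform = WindRose.uniform()
    for _, st in scene.stations.iterrows():
        sid = st["station"]
        center = (st["x"], st["y"])
        rec = {"LONG": st["x"], "LAT": st["y"],
               "ELEV": float(st.get("elev", 0.0))}
        for r in radii:
            ri = int(r)
            for code, name in LANDUSE_CLASSES.items():
                rec[f"{CLASS_ABBR[name]}_{ri}"] = areal_fraction(
                    scene.landuse, center, r, code)
            rec[f"GCR_{ri}"] = buffer_mean(scene.green_cover, center, r)
            for cls in ROAD_CLASSES:
                rec[f"{ROAD_ABBR[cls]}_{ri}"] = line_density(
                    scene.roads, center, r, cls)
            rec[f"BUS_{ri}"] = point_count(scene.bus_stops, center, r)
            rec[f"POP_{ri}"] = buffer_mean(scene.population, center, r)
            rec[f"FAI_{ri}"] = buffered_fai(
                scene.buildings, center, r, uniform)
            rec[f"ROUGH_{ri}"] = roughness_length(scene.buildings, center, r)
        rows[sid] = rec
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("station")


def assemble_table(scene, aod_daily: dict, met_station: pd.DataFrame,
                   sounding: pd.DataFrame | None, periods: dict,
                   radii) -> tuple[pd.DataFrame, dict]:
    """Assemble the (station, period) predictor table.

    Parameters
    ----------
    aod_daily : mapping day -> RasterGrid of screened, merged daily AOD
        already at the analysis resolution.
    met_station : frame indexed by (station, day) with MET columns,
        interpolated station meteorology.
    sounding : daily sounding-index frame indexed by day, or None (columns
        omitted with a warning).
    periods : mapping period label -> list of day indices.

    Returns (table, schema); rows with no valid AOD coverage in a period
    are dropped and logged.  The AOD column is mandatory and non-null in
    every returned row.
    """
    spatial = station_spatial_predictors(scene, radii)
    if sounding is None:
        warnings.warn("no sounding file supplied; sounding columns omitted")
    rows = []
    index = []
    for period, days in periods.items():
        for _, st in scene.stations.iterrows():
            sid = st["station"]
            center = (st["x"], st["y"])
            aod_vals = []
            for day in days:
                grid = aod_daily.get(day)
                if grid is None or not bool(grid.contains(*center)):
                    continue
                v = float(grid.sample(*center))
                if not np.isclose(v, grid.nodata):
                    aod_vals.append(v)
            if not aod_vals:
                log.info("station %s has no valid AOD in period %s; "
                         "row dropped", sid, period)
                continue
            rec = {"AOD": float(np.mean(aod_vals))}
            rec.update(spatial.loc[sid].to_dict())
            met = met_station.loc[(sid, list(days)), :].mean()
            rec.update(met.to_dict())
            if sounding is not None:
                snd = sounding.loc[sounding.index.intersection(days)].mean()
                rec.update(snd.to_dict())
            rows.append(rec)
            index.append((sid, period))
    table = pd.DataFrame(
        rows, index=pd.MultiIndex.from_tuples(index,
                                              names=["station", "period"]))
    schema = _schema(table.columns, radii)
    return table, schema


def _schema(columns, radii) -> dict:
    radius_set = {int(r) for r in radii}
    schema = {}
    for col in columns:
        base, _, suffix = col.rpartition("_")
        if base and suffix.isdigit() and int(suffix) in radius_set:
            schema[col] = {"variable": base, "radius": int(suffix),
                           "kind": "spatial"}
        elif col in ("LONG", "LAT", "ELEV"):
            schema[col] = {"variable": col, "radius": None, "kind": "geo"}
        elif col == "AOD":
            schema[col] = {"variable": "AOD", "radius": None,
                           "kind": "mandatory"}
        else:
            schema[col] = {"variable": col, "radius": None,
                           "kind": "temporal"}
    return schema
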