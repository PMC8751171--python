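"""Satellite-AOD screening and meteorological surface interpolation.

AOD scenes carry per-pixel QA state mirroring the MAIAC categories that
matter for PM2.5 work: a cloud mask (Clear / Possibly cloudy / Cloudy), an
adjacency mask, and a near-coastline flag.  The screening rule retains
Clear and Possibly-cloudy pixels and additionally keeps pixels flagged as
within ±2 km of the coastline, to preserve coverage over coastal urban
areas; everything else becomes nodata.  Terra and Aqua overpasses of the
same day are averaged pixel-wise over whichever of the two is valid.

Station meteorology (temperature, relative humidity, wind speed, rainfall,
pressure) is interpolated to city-wide surfaces with ordinary kriging using
an exponential variogram fitted by weighted least squares to the empirical
semivariogram; with a zero nugget the surface honours the station values
exactly.  If the variogram fit fails, inverse-distance weighting is used
with a logged warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.optimize import curve_fit
from scipy.spatial.distance import cdist

from .geo_io import RasterGrid

__all__ = [
    "QA_CLEAR", "QA_POSSIBLY_CLOUDY", "QA_CLOUDY",
    "AODScene", "qa_filter", "daily_merge", "resample_bilinear",
    "krige_met", "krige_points", "fit_exponential_variogram",
    "MET_VARIABLES",
]

QA_CLEAR = 0
QA_POSSIBLY_CLOUDY = 1
QA_CLOUDY = 2

#: Met variables interpolated to surfaces; RF and WSPD are clipped at 0.
MET_VARIABLES = ("TEMP", "RH", "WSPD", "RF", "MSLP")
_NONNEGATIVE_MET = {"RH", "WSPD", "RF"}


@dataclass
class AODScene:
    """One satellite overpass of AOD (0.55 µm) with QA state."""

    aod: RasterGrid
    qa_cloud: np.ndarray       # QA_CLEAR / QA_POSSIBLY_CLOUDY / QA_CLOUDY
    qa_adjacency: np.ndarray   # 0 = Clear, 1 = Adjacent
    coastline: np.ndarray      # bool, within ±2 km of the coastline
    sensor: str = "Terra"
    date: int = 0

    def __post_init__(self) -> None:
        shp = self.aod.values.shape
        for name in ("qa_cloud", "qa_adjacency", "coastline"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != shp:
                raise ValueError(f"{name} shape {arr.shape} != AOD {shp}")
            setattr(self, name, arr)


def qa_filter(scene: AODScene) -> tuple[AODScene, np.ndarray]:
    """Screen an AOD scene; returns (filtered scene, retention mask).

    A pixel is retained iff its cloud mask is Clear or Possibly cloudy, or
    it carries the near-coastline flag.  Idempotent: nodata pixels stay
    nodata.
    """
    retain = np.isin(scene.qa_cloud, (QA_CLEAR, QA_POSSIBLY_CLOUDY)) | \
        scene.coastline.astype(bool)
    vals = np.where(retain & scene.aod.valid_mask,
                    scene.aod.values, scene.aod.nodata)
    if not np.any(vals != scene.aod.nodata):
        warnings.warn(f"qa_filter: no valid AOD pixels remain "
                      f"({scene.sensor} day {scene.date})")
    return replace(scene, aod=scene.aod.with_values(vals)), retain


def daily_merge(terra: AODScene, aqua: AODScene) -> RasterGrid:
    """Per-pixel mean of the valid Terra/Aqua values for one day."""
    if not terra.aod.same_geometry(aqua.aod):
        raise ValueError("Terra and Aqua grids have different geometry")
    if terra.date != aqua.date:
        raise ValueError("Terra and Aqua scenes are from different dates")
    a, b = terra.aod, aqua.aod
    va, vb = a.valid_mask, b.valid_mask
    total = np.where(va, a.values, 0.0) + np.where(vb, b.values, 0.0)
    count = va.astype(float) + vb.astype(float)
    out = np.where(count > 0, total / np.maximum(count, 1), a.nodata)
    return a.with_values(out)


def resample_bilinear(grid: RasterGrid, target_cell: float) -> RasterGrid:
    """Bilinear smoothing of a coarse grid onto a finer cell size.

    ``target_cell`` must divide the source cell.  Nodata neighbours are
    dropped and the remaining weights renormalised; a fine cell surrounded
    only by nodata becomes nodata.  Values at source cell centers are
    preserved exactly.
    """
    ratio = grid.cell / target_cell
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("target_cell must divide the source cell size")
    ratio = int(round(ratio))
    if ratio == 1:
        return grid.with_values(grid.values.copy())
    nrows, ncols = grid.nrows * ratio, grid.ncols * ratio
    # fractional source-grid coordinates of fine cell centers, measured in
    # source cells from the first source cell center
    fr = (np.arange(nrows) + 0.5) / ratio - 0.5
    fc = (np.arange(ncols) + 0.5) / ratio - 0.5
    r0 = np.clip(np.floor(fr).astype(int), 0, grid.nrows - 1)
    c0 = np.clip(np.floor(fc).astype(int), 0, grid.ncols - 1)
    r1 = np.clip(r0 + 1, 0, grid.nrows - 1)
    c1 = np.clip(c0 + 1, 0, grid.ncols - 1)
    wr1 = np.clip(fr - r0, 0.0, 1.0)[:, None]
    wc1 = np.clip(fc - c0, 0.0, 1.0)[None, :]
    vals = grid.values
    valid = grid.valid_mask.astype(float)
    acc = np.zeros((nrows, ncols))
    wacc = np.zeros((nrows, ncols))
    for rr, wr in ((r0, 1.0 - wr1), (r1, wr1)):
        for cc, wc in ((c0, 1.0 - wc1), (c1, wc1)):
            w = wr * wc * valid[np.ix_(rr, cc)]
            acc += w * np.where(valid[np.ix_(rr, cc)] > 0,
                                vals[np.ix_(rr, cc)], 0.0)
            wacc += w
    out = np.where(wacc > 1e-12, acc / np.maximum(wacc, 1e-12), grid.nodata)
    return RasterGrid(out, grid.x0, grid.y0, target_cell,
                      crs=grid.crs, nodata=grid.nodata)


# ---------------------------------------------------------------------------
# Ordinary kriging
# ---------------------------------------------------------------------------

def _exponential_gamma(h, sill, rng):
    """Exponential semivariogram with practical range *rng* (zero nugget)."""
    return sill * (1.0 - np.exp(-3.0 * h / np.maximum(rng, 1e-12)))


def fit_exponential_variogram(coords: np.ndarray, values: np.ndarray,
                              n_bins: int = 12):
    """WLS fit of (sill, range) to the empirical semivariogram.

    Bins pairwise half squared differences by distance and weights the fit
    by pair counts.  Raises ``RuntimeError`` when the fit cannot proceed
    (e.g. constant data).
    """
    d = cdist(coords, coords)
    iu = np.triu_indices(len(values), k=1)
    dist = d[iu]
    gamma = 0.5 * (values[:, None] - values[None, :])[iu] ** 2
    if np.allclose(gamma, 0.0):
        # constant field: any sill works; pick a degenerate flat variogram
        return 0.0, float(dist.max() or 1.0)
    edges = np.linspace(0.0, dist.max() * (1 + 1e-9), n_bins + 1)
    idx = np.digitize(dist, edges) - 1
    centers, means, counts = [], [], []
    for b in range(n_bins):
        sel = idx == b
        if np.any(sel):
            centers.append(dist[sel].mean())
            means.append(gamma[sel].mean())
            counts.append(sel.sum())
    centers, means = np.asarray(centers), np.asarray(means)
    counts = np.asarray(counts, dtype=float)
    if len(centers) < 2:
        raise RuntimeError("too few semivariogram bins")
    p0 = (float(means.max()), float(centers.max() / 2 or 1.0))
    popt, _ = curve_fit(_exponential_gamma, centers, means, p0=p0,
                        sigma=1.0 / np.sqrt(counts), maxfev=5000,
                        bounds=([0.0, 1e-6], [np.inf, np.inf]))
    return float(popt[0]), float(popt[1])


def _idw(coords, values, targets, power=2.0):
    d = cdist(targets, coords)
    with np.errstate(divide="ignore"):
        w = 1.0 / d ** power
    exact = d < 1e-12
    w[exact.any(axis=1)] = exact[exact.any(axis=1)].astype(float)
    w /= w.sum(axis=1, keepdims=True)
    return w @ values


def krige_points(station_values, station_coords, targets,
                 variogram: tuple[float, float] | None = None) -> np.ndarray:
    """Ordinary kriging predictions at arbitrary target points.

    Exact interpolation at station locations (zero nugget); prediction
    weights sum to 1 by the Lagrange constraint.
    """
    values = np.asarray(station_values, dtype=float)
    coords = np.asarray(station_coords, dtype=float)
    targets = np.asarray(targets, dtype=float)
    if len(values) < 4:
        raise ValueError("kriging needs at least 4 stations")
    d = cdist(coords, coords)
    if np.any(d[np.triu_indices(len(values), k=1)] < 1e-9):
        raise ValueError("duplicate station coordinates")
    try:
        sill, rng = (variogram if variogram is not None
                     else fit_exponential_variogram(coords, values))
        if sill == 0.0:  # constant field
            pred = np.full(len(targets), values[0])
        else:
            n = len(values)
            A = np.empty((n + 1, n + 1))
            A[:n, :n] = _exponential_gamma(d, sill, rng)
            A[n, :n] = 1.0
            A[:n, n] = 1.0
            A[n, n] = 0.0
            lu = lu_factor(A)
            B = np.empty((n + 1, len(targets)))
            B[:n] = _exponential_gamma(
                cdist(coords, targets), sill, rng)
            B[n] = 1.0
            lam = lu_solve(lu, B)[:n]
            pred = lam.T @ values
    except (RuntimeError, np.linalg.LinAlgError) as exc:
        warnings.warn(f"variogram fit failed ({exc}); "
                      "falling back to inverse-distance weighting")
        pred = _idw(coords, values, targets)
    return pred


def krige_met(station_values, station_coords, target: RasterGrid,
              variable: str | None = None,
              variogram: tuple[float, float] | None = None) -> RasterGrid:
    """Ordinary kriging of station values onto *target*'s grid geometry.

    Physically non-negative variables (RH, WSPD, RF) are clipped at 0 with
    a logged count; RH is additionally capped at 100 %.
    """
    X, Y = target.cell_centers()
    targets = np.column_stack([X.ravel(), Y.ravel()])
    pred = krige_points(station_values, station_coords, targets,
                        variogram=variogram)
    grid = pred.reshape(target.values.shape)
    if variable in _NONNEGATIVE_MET:
        n_clip = int(np.sum(grid < 0))
        if n_clip:
            warnings.warn(f"{variable}: clipped {n_clip} negative kriged "
                          "cells to 0")
        grid = np.maximum(grid, 0.0)
        if variable == "RH":
            grid = np.minimum(grid, 100.0)
    return target.with_values(grid)
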