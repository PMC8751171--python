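"""Building-morphology predictors: frontal area index, point-based FAI,
sky view factor, and roughness length.

The frontal area index (FAI) measures how much building "front" the wind
sees per unit lot area, weighted by the wind-direction probability over the
eight principal directions:

    FAI = sum_theta [ A_F(theta) / A_T ] * P(theta)

where ``A_F(theta)`` is the silhouette area of all buildings projected along
wind direction theta, and ``A_T`` the lot area.  Mutually occluding
buildings are merged, not summed: the silhouette is the union of grounded
rectangles in the projection plane.

The point-based FAI extends this with an exponential distance-decay weight
``w(l) = ((R - l)/R)^c`` around a test point, integrating the local FAI
density over a circle of radius R (default 200 m, c = 2).

The sky view factor (SVF) is the fraction of the sky hemisphere visible
from a point, computed by horizon-angle scanning over a digital surface
model (Dozier–Frew style); for a horizontal viewpoint
``SVF = (1/n) * sum_az cos^2(phi_az)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import fftconvolve
from shapely.geometry import Point, Polygon, box

from .geo_io import RasterGrid

__all__ = [
    "WindRose",
    "PointFAIParams",
    "SVFParams",
    "frontal_area",
    "frontal_area_index",
    "buffered_fai",
    "decay_weight",
    "point_fai",
    "sky_view_factor",
    "svf_grid",
    "roughness_length",
    "frontal_density_grid",
    "point_fai_grid",
]


@dataclass
class WindRose:
    """Wind-direction probabilities over the 8 principal directions.

    ``p[k]`` is the probability of wind blowing along azimuth ``45 * k``
    degrees (k = 0 is north, clockwise).
    """

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (8,):
            raise ValueError("wind rose needs exactly 8 direction weights")
        if np.any(self.p < 0):
            raise ValueError("wind probabilities must be >= 0")
        if abs(self.p.sum() - 1.0) > 1e-9:
            raise ValueError("wind probabilities must sum to 1")

    @classmethod
    def uniform(cls) -> "WindRose":
        return cls(np.full(8, 0.125))

    @classmethod
    def single(cls, k: int) -> "WindRose":
        p = np.zeros(8)
        p[k % 8] = 1.0
        return cls(p)

    @staticmethod
    def direction_vector(k: int) -> tuple[float, float]:
        """Unit vector of azimuth 45*k degrees (x east, y north)."""
        az = math.radians(45.0 * k)
        return math.sin(az), math.cos(az)


@dataclass
class PointFAIParams:
    R: float = 200.0   # decay radius, m
    c: float = 2.0     # decay exponent
    step: float = 2.0  # integration grid step, m

    def __post_init__(self) -> None:
        if self.R <= 0 or self.c <= 0:
            raise ValueError("R and c must be > 0")
        if self.step > self.R / 10:
            raise ValueError("integration too coarse: step must be <= R/10")


@dataclass
class SVFParams:
    n_azimuths: int = 16
    d: float = 100.0  # maximum horizon search distance, m

    def __post_init__(self) -> None:
        if self.n_azimuths < 8:
            raise ValueError("need at least 8 azimuths")
        if self.d <= 0:
            raise ValueError("search distance must be > 0")


# ---------------------------------------------------------------------------
# Frontal area (silhouette with occlusion)
# ---------------------------------------------------------------------------

def _projection_interval(footprint, k: int) -> tuple[float, float]:
    """Interval covered by *footprint* on the axis perpendicular to wind
    direction k (the silhouette width axis)."""
    dx, dy = WindRose.direction_vector(k)
    # axis perpendicular to the wind direction
    ux, uy = -dy, dx
    coords = np.asarray(footprint.exterior.coords)
    proj = coords[:, 0] * ux + coords[:, 1] * uy
    return float(proj.min()), float(proj.max())


def frontal_area(buildings, k: int) -> float:
    """Silhouette area (m²) of *buildings* seen along wind direction k.

    *buildings* is an iterable of ``(footprint_polygon, height_m)``.
    Overlapping silhouettes are merged: the result is the area of the union
    of grounded rectangles ``[lo, hi] x [0, h]`` in the projection plane.
    """
    rects = []
    for footprint, height in buildings:
        if footprint.is_empty or height <= 0:
            continue
        lo, hi = _projection_interval(footprint, k)
        if hi > lo:
            rects.append((lo, hi, float(height)))
    if not rects:
        return 0.0
    lo = np.array([r[0] for r in rects])
    hi = np.array([r[1] for r in rects])
    h = np.array([r[2] for r in rects])
    breaks = np.unique(np.concatenate([lo, hi]))
    mids = 0.5 * (breaks[:-1] + breaks[1:])
    cover = (lo[:, None] <= mids[None, :]) & (mids[None, :] <= hi[:, None])
    hmax = np.max(np.where(cover, h[:, None], 0.0), axis=0)
    return float(np.sum(np.diff(breaks) * hmax))


def _clip_buildings(buildings, lot) -> list:
    clipped = []
    for footprint, height in buildings:
        if not footprint.intersects(lot):
            continue
        inter = footprint.intersection(lot)
        if inter.is_empty or inter.area <= 0:
            continue
        geoms = getattr(inter, "geoms", [inter])
        for g in geoms:
            if isinstance(g, Polygon) and g.area > 0:
                clipped.append((g, height))
    return clipped


def frontal_area_index(buildings, lot_polygon, windrose: WindRose,
                       lot_area: float | None = None) -> float:
    """Wind-probability-weighted frontal area index of a lot."""
    a_t = lot_polygon.area if lot_area is None else lot_area
    if a_t <= 0:
        raise ValueError("lot area must be > 0")
    clipped = _clip_buildings(buildings, lot_polygon)
    if not clipped:
        return 0.0
    total = 0.0
    for k in range(8):
        if windrose.p[k] == 0:
            continue
        total += windrose.p[k] * frontal_area(clipped, k)
    return total / a_t


def buffered_fai(buildings, center, radius: float,
                 windrose: WindRose) -> float:
    """FAI with a circular buffer as the lot (A_T = pi r² exactly)."""
    if radius <= 0:
        raise ValueError("radius must be > 0")
    lot = Point(center).buffer(radius, quad_segs=64)
    return frontal_area_index(buildings, lot, windrose,
                              lot_area=math.pi * radius ** 2)


def decay_weight(l, R: float, c: float):
    """Exponential decay weight ((R - l)/R)^c, clipped to 0 beyond R."""
    l = np.asarray(l, dtype=float)
    if np.any(l < 0):
        raise ValueError("distance l must be >= 0")
    w = np.where(l <= R, ((R - l) / R) ** c, 0.0)
    return float(w) if w.ndim == 0 else w


def point_fai(buildings, point, params: PointFAIParams,
              windrose: WindRose) -> float:
    """Distance-decay-weighted FAI around *point*.

    Each building inside the circle of radius R contributes its
    wind-weighted frontal area ``sum_theta P(theta) h W(theta)``,
    apportioned over its footprint on a square integration grid of side
    ``params.step`` by footprint-area fraction and weighted by the decay
    of the cell-center distance to the point; the result is normalised by
    the circle area.  This discretization converges as step -> 0 and
    reduces to the buffered FAI when the decay weight is flat.  Frontal
    areas are per building (no cross-building occlusion).
    """
    px, py = (point.x, point.y) if hasattr(point, "x") else point
    R, c, step = params.R, params.c, params.step
    a_circle = math.pi * R ** 2
    circle = Point(px, py).buffer(R, quad_segs=64)
    nearby = _clip_buildings(buildings, circle)
    if not nearby:
        return 0.0
    total = 0.0
    for footprint, height in nearby:
        af = 0.0
        for k in range(8):
            if windrose.p[k] == 0:
                continue
            lo, hi = _projection_interval(footprint, k)
            af += windrose.p[k] * height * (hi - lo)
        fp_area = footprint.area
        minx, miny, maxx, maxy = footprint.bounds
        i0 = math.floor((minx - px + R) / step)
        i1 = math.floor((maxx - px + R) / step)
        j0 = math.floor((miny - py + R) / step)
        j1 = math.floor((maxy - py + R) / step)
        for i in range(i0, i1 + 1):
            for j in range(j0, j1 + 1):
                cx = px - R + (i + 0.5) * step
                cy = py - R + (j + 0.5) * step
                l = math.hypot(cx - px, cy - py)
                w = ((R - l) / R) ** c if l <= R else 0.0
                if w == 0.0:
                    continue
                cell = box(px - R + i * step, py - R + j * step,
                           px - R + (i + 1) * step,
                           py - R + (j + 1) * step)
                frac = footprint.intersection(cell).area / fp_area
                if frac > 0:
                    total += w * af * frac
    return total / a_circle


# ---------------------------------------------------------------------------
# Sky view factor
# ---------------------------------------------------------------------------

def sky_view_factor(dsm: RasterGrid, point, params: SVFParams,
                    observer_height: float | None = None) -> float:
    """Horizon-scan SVF for a horizontal viewpoint.

    Along each of ``n_azimuths`` directions the maximum elevation angle of
    the surface within distance ``d`` is found by ray marching at cell-size
    steps; ``SVF = mean(cos² phi)`` over azimuths.
    """
    px, py = (point.x, point.y) if hasattr(point, "x") else point
    if not bool(dsm.contains(px, py)):
        raise ValueError("point outside DSM extent")
    z0 = float(dsm.sample(px, py)) if observer_height is None else observer_height
    step = dsm.cell
    n_steps = max(1, int(params.d / step))
    svf_sum = 0.0
    for a in range(params.n_azimuths):
        az = 2 * math.pi * a / params.n_azimuths
        dx, dy = math.sin(az), math.cos(az)
        tan_max = 0.0
        for s in range(1, n_steps + 1):
            dist = s * step
            x, y = px + dx * dist, py + dy * dist
            if not bool(dsm.contains(x, y)):
                break
            dz = float(dsm.sample(x, y)) - z0
            if dz > 0:
                t = dz / dist
                if t > tan_max:
                    tan_max = t
        phi = math.atan(tan_max)
        svf_sum += math.cos(phi) ** 2
    return svf_sum / params.n_azimuths


_AZIMUTH_SHIFTS = [(-1, 0), (-1, 1), (0, 1), (1, 1),
                   (1, 0), (1, -1), (0, -1), (-1, -1)]


def svf_grid(dsm: RasterGrid, max_dist: float = 100.0) -> RasterGrid:
    """Vectorized 8-azimuth SVF for every cell of a DSM.

    Ground-level observers: the observer elevation is the DSM value itself,
    so rooftop cells see open sky.  Suitable for street-canyon fields; the
    point-wise :func:`sky_view_factor` is the reference implementation.
    """
    z = dsm.values
    cell = dsm.cell
    out = np.zeros_like(z)
    for dr, dc in _AZIMUTH_SHIFTS:
        diag = math.hypot(dr, dc)
        n_steps = max(1, int(max_dist / (cell * diag)))
        tan_max = np.zeros_like(z)
        for s in range(1, n_steps + 1):
            shifted = _shift(z, dr * s, dc * s)
            t = (shifted - z) / (s * cell * diag)
            np.maximum(tan_max, t, out=tan_max)
        out += 1.0 / (1.0 + tan_max ** 2)  # cos²(atan t) = 1/(1+t²)
    return dsm.with_values(out / 8.0)


def _shift(a: np.ndarray, dr: int, dc: int) -> np.ndarray:
    """Shift array, padding with -inf so off-grid never raises a horizon."""
    out = np.full_like(a, -np.inf)
    rows, cols = a.shape
    r0, r1 = max(dr, 0), min(rows + dr, rows)
    c0, c1 = max(dc, 0), min(cols + dc, cols)
    if r0 < r1 and c0 < c1:
        out[r0:r1, c0:c1] = a[r0 - dr:r1 - dr, c0 - dc:c1 - dc]
    return out


# ---------------------------------------------------------------------------
# Roughness length and gridded point-FAI
# ---------------------------------------------------------------------------

def roughness_length(buildings, center, radius: float) -> float:
    """Rule-of-thumb morphometric roughness: 0.1 x mean building height of
    buildings whose centroid lies within the buffer; 0 when empty."""
    cx, cy = (center.x, center.y) if hasattr(center, "x") else center
    heights = [h for f, h in buildings
               if math.hypot(f.centroid.x - cx, f.centroid.y - cy) <= radius]
    if not heights:
        return 0.0
    return 0.1 * float(np.mean(heights))


def frontal_density_grid(dsm: RasterGrid, ground: RasterGrid | None = None
                         ) -> RasterGrid:
    """Per-cell frontal-area density (m² of front per m² of ground).

    Direction-averaged approximation used by the gridded morphology driver:
    a building cell of height h contributes a front of ``h * cell`` over an
    area ``cell²``, i.e. density ``h / cell``.
    """
    h = dsm.values - (0.0 if ground is None else ground.values)
    return dsm.with_values(np.maximum(h, 0.0) / dsm.cell)


def point_fai_grid(dsm: RasterGrid, R: float = 200.0, c: float = 2.0,
                   ground: RasterGrid | None = None) -> RasterGrid:
    """Gridded point-FAI field via convolution with the decay kernel.

    The field at each cell equals the decay-weighted sum of per-cell
    frontal areas within R, divided by the circle area — the same
    discretization as :func:`point_fai` at step = cell size, with the
    direction-averaged frontal density of :func:`frontal_density_grid`.
    """
    cell = dsm.cell
    dens = frontal_density_grid(dsm, ground).values  # h/cell
    n = int(math.ceil(R / cell))
    offs = (np.arange(-n, n + 1)) * cell
    dy, dx = np.meshgrid(offs, offs, indexing="ij")
    dist = np.hypot(dx, dy)
    kernel = np.where(dist <= R, ((R - np.minimum(dist, R)) / R) ** c, 0.0)
    # per-cell frontal area = dens * cell²; normalise by circle area
    field = fftconvolve(dens * cell ** 2, kernel, mode="same")
    field /= math.pi * R ** 2
    return dsm.with_values(np.maximum(field, 0.0))
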