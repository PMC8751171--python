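"""Synthetic study area and ground-truth PM2.5 generator.

The generator builds a self-contained city in a local metric CRS with the
statistical structure the two-stage analysis assumes:

* a five-class land-use raster at 10 m (residential, commercial,
  industrial, government, open-space/greening) with configurable class
  fractions, realised by quantile-thresholding a smoothed Gaussian field so
  patches have a realistic ~150 m correlation length;
* building footprints with heights on built land, and the implied DSM;
* a rectilinear road graph spanning all five road classes;
* 16 long-term monitoring stations, 8 weather stations, bus stops, a
  population-density raster, and a greening-cover raster;
* a ground-truth daily PM2.5 field composed of an AR(1) seasonal
  background, a linear spatial gradient, land-use emission contributions
  at a single true buffer radius, and street-canyon morphology effects
  (sky-view factor and point-FAI) on road cells only;
* observations: noisy station series, Terra/Aqua AOD scenes with a cloud
  QA process (AOD tracks the *regional* component — background plus
  gradient — as a satellite column measure does), and 1-s pedestrian
  tracks whose raw PM2.5 is RH-inflated so the hygroscopic correction is
  exercised in reverse.

Every random draw flows from a single seeded generator recorded in the
run manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from shapely.geometry import LineString, box

from .geo_io import ROAD_CLASSES, PipelineConfig, RasterGrid, RoadGraph
from .morphology import WindRose, point_fai_grid, svf_grid
from .predictors import LANDUSE_CLASSES, road_mask_grid

__all__ = [
    "CityScene", "TruthParams", "TruthFields", "Observations",
    "generate_scene", "simulate_truth", "sample_observations",
    "study_dates", "synthetic_config", "rh_correction_factor",
]

SOUNDING_INDICES = ("KINX", "PWAT", "CINV", "LCLP", "LFCV", "VTOT")

#: Morphology field scales shared by the truth generator, the
#: neighborhood stage and the mapping stage: SVF horizon search confined
#: to the immediate street-canyon walls; point-FAI integrates building
#: mass over its standard 200 m decay radius.
SVF_SEARCH_DIST = 50.0
FAI_DECAY_RADIUS = 200.0

#: Background mean PM2.5 per season, µg/m³ (warm seasons lower: local
#: sources dominate; winter highest: regional transport).
SEASON_BACKGROUND = {"spring": 20.0, "summer": 13.0,
                     "fall": 22.0, "winter": 28.0}

#: Dominant-wind probability vectors per season (8 principal directions,
#: index 0 = N, clockwise).
SEASON_WINDROSE = {
    "spring": (0.05, 0.10, 0.30, 0.20, 0.10, 0.10, 0.10, 0.05),
    "summer": (0.05, 0.05, 0.10, 0.20, 0.30, 0.15, 0.10, 0.05),
    "fall":   (0.30, 0.20, 0.15, 0.05, 0.05, 0.05, 0.10, 0.10),
    "winter": (0.20, 0.30, 0.20, 0.10, 0.05, 0.05, 0.05, 0.05),
}

DEFAULT_FRACTIONS = {"residential": 0.30, "commercial": 0.12,
                     "industrial": 0.08, "government": 0.10,
                     "openspace": 0.40}


def synthetic_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Study configuration for the synthetic city: a 2.4 km square at 10 m
    with the 50–500 m buffer sub-series (the extent must be at least four
    times the largest radius so edge stations keep full buffers)."""
    opts = dict(seed=seed, buffer_radii=(50, 100, 200, 300, 400, 500),
                extent=2400.0, cell_size=10.0, aod_cell=300.0)
    opts.update(overrides)
    return PipelineConfig(**opts)


@dataclass
class CityScene:
    """All static layers of the (synthetic or ingested) study area."""

    landuse: RasterGrid
    green_cover: RasterGrid
    buildings: list                 # [(footprint Polygon, height m), ...]
    dsm: RasterGrid
    roads: RoadGraph
    stations: pd.DataFrame          # station, x, y, elev
    weather_stations: pd.DataFrame  # station, x, y
    population: RasterGrid          # persons/km²
    bus_stops: pd.DataFrame         # x, y
    windroses: dict                 # season -> WindRose
    config: PipelineConfig

    def __post_init__(self) -> None:
        for layer in (self.green_cover, self.dsm, self.population):
            if not layer.same_geometry(self.landuse):
                raise ValueError("scene layers must share grid geometry")
        if any(h <= 0 for _, h in self.buildings):
            raise ValueError("building heights must be > 0")
        if len(self.stations) < 8:
            raise ValueError("need at least 8 monitoring stations")


@dataclass
class TruthParams:
    """Parameters of the generative PM2.5 world.

    Units: gradients in µg/m³ per km; class strengths in µg/m³ per unit
    areal fraction at ``true_radius``; morphology coefficients in µg/m³
    per unit index (applied on road cells only); the AOD link is
    PM ≈ slope·AOD + intercept for the regional component.
    """

    gradient: tuple[float, float] = (-2.0, 1.0)
    class_strengths: dict = field(default_factory=lambda: {
        "residential": 10.0, "commercial": 0.0, "industrial": 0.0,
        "government": 0.0, "openspace": 0.0})
    true_radius: float = 300.0
    # street-canyon effects of a few µg/m³, the magnitude reported for
    # morphology terms in neighborhood PM2.5 models
    svf_coef: float = -12.0
    fai_coef: float = 40.0
    aod_slope: float = 25.0
    aod_intercept: float = 5.0
    sigma_station: float = 1.0
    sigma_aod: float = 0.06
    sigma_mobile: float = 2.0
    ar1: float = 0.6
    background_sd: float = 3.0
    hourly_bg_sd: float = 3.0
    cloud_fraction: float = 0.3
    floor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.sigma_station, self.sigma_aod, self.sigma_mobile) < 0:
            raise ValueError("noise SDs must be >= 0")
        if not -1.0 < self.ar1 < 1.0:
            raise ValueError("AR(1) coefficient must lie in (-1, 1)")

    def to_dict(self) -> dict:
        return {k: (list(v) if isinstance(v, tuple) else v)
                for k, v in self.__dict__.items()}


def study_dates(config: PipelineConfig, days_per_season: int = 12
                ) -> pd.DataFrame:
    """Day calendar: consecutive integer days labelled by season."""
    if len(config.seasons) < 2:
        raise ValueError("need at least 2 seasons")
    recs = []
    day = 0
    for season in config.seasons:
        for _ in range(days_per_season):
            recs.append({"day": day, "season": season})
            day += 1
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Scene generation
# ---------------------------------------------------------------------------

def _smooth_field(shape, rng, sigma_cells: float) -> np.ndarray:
    return gaussian_filter(rng.standard_normal(shape), sigma=sigma_cells,
                           mode="wrap")


def _landuse_raster(shape, rng, fractions, grid: RasterGrid) -> np.ndarray:
    field = _smooth_field(shape, rng, sigma_cells=15.0)
    ranks = field.ravel().argsort().argsort() / (field.size - 1)
    out = np.zeros(field.size, dtype=float)
    cum = 0.0
    for code, name in LANDUSE_CLASSES.items():
        frac = fractions[name]
        out[(ranks >= cum) & (ranks < cum + frac + 1e-12)] = code
        cum += frac
    out[out == 0] = max(LANDUSE_CLASSES)  # rank-tie remainder -> open space
    return out.reshape(shape)


def generate_scene(config: PipelineConfig,
                   fractions: dict | None = None,
                   n_stations: int = 16,
                   n_weather: int = 8) -> CityScene:
    """Generate the synthetic study area; deterministic given config.seed."""
    max_r = max(config.buffer_radii)
    if config.extent < 4 * max_r:
        raise ValueError(
            f"extent {config.extent} m too small for the largest buffer "
            f"radius {max_r} m (need >= {4 * max_r} m)")
    rng = np.random.default_rng(config.seed)
    fractions = dict(fractions or DEFAULT_FRACTIONS)
    if abs(sum(fractions.values()) - 1.0) > 1e-9:
        raise ValueError("land-use fractions must sum to 1")
    n = int(round(config.extent / config.cell_size))
    template = RasterGrid(np.zeros((n, n)), 0.0, config.extent,
                          config.cell_size, crs=config.crs)
    landuse = template.with_values(
        _landuse_raster((n, n), rng, fractions, template))

    roads = _road_network(config, rng)
    roadmask = road_mask_grid(roads, landuse, halfwidth=12.0)

    buildings, dsm_vals = _buildings(landuse, roadmask, rng, config)
    dsm = template.with_values(dsm_vals)

    green = np.where(landuse.values == 5,
                     rng.uniform(0.5, 1.0, size=(n, n)),
                     rng.uniform(0.0, 0.2, size=(n, n)))
    green_cover = template.with_values(green)

    # population follows its own smooth density field (cities mix high-rise
    # and low-rise residential forms, so density is not a land-use copy)
    pop_field = _smooth_field((n, n), rng, 12.0)
    pop_u = pop_field.ravel().argsort().argsort() / (pop_field.size - 1)
    pop = 500.0 + 9000.0 * (pop_u.reshape((n, n)) ** 2)
    population = template.with_values(pop)

    stations = _stations(config, rng, n_stations, max_r, roadmask, template)
    weather = pd.DataFrame({
        "station": [f"W{i:02d}" for i in range(n_weather)],
        "x": rng.uniform(100, config.extent - 100, n_weather),
        "y": rng.uniform(100, config.extent - 100, n_weather),
    })
    bus = _bus_stops(roads, rng)
    windroses = {s: WindRose(np.asarray(SEASON_WINDROSE[s]))
                 for s in config.seasons if s in SEASON_WINDROSE}
    for s in config.seasons:
        windroses.setdefault(s, WindRose.uniform())
    return CityScene(landuse=landuse, green_cover=green_cover,
                     buildings=buildings, dsm=dsm, roads=roads,
                     stations=stations, weather_stations=weather,
                     population=population, bus_stops=bus,
                     windroses=windroses, config=config)


def _road_network(config: PipelineConfig, rng) -> RoadGraph:
    extent = config.extent
    def positions():
        pos, x = [], rng.uniform(80, 250)
        while x < extent - 80:
            pos.append(x)
            x += rng.uniform(180, 420)
        return pos
    xs, ys = positions(), positions()
    class_cycle = list(ROAD_CLASSES)
    weights = np.array([0.08, 0.15, 0.22, 0.25, 0.30])
    roads = RoadGraph(crs=config.crs)
    lines = [("v", x) for x in xs] + [("h", y) for y in ys]
    for i, (orient, pos) in enumerate(lines):
        cls = (class_cycle[i] if i < len(class_cycle)
               else rng.choice(class_cycle, p=weights))
        crossings = sorted(ys if orient == "v" else xs)
        stops = [0.0] + [c for c in crossings] + [extent]
        for a, b in zip(stops, stops[1:]):
            if b - a < 1e-6:
                continue
            if orient == "v":
                geom = LineString([(pos, a), (pos, b)])
            else:
                geom = LineString([(a, pos), (b, pos)])
            roads.add_edge(geom, str(cls))
    return roads


def _buildings(landuse: RasterGrid, roadmask: np.ndarray, rng,
               config: PipelineConfig):
    """Rectangular buildings on built land-use classes, off the roads."""
    # compact high-rise city: tall street walls so road cells span deep
    # canyons (low SVF) as well as open stretches
    densities = {1: 0.60, 2: 0.70, 3: 0.35, 4: 0.35}
    mean_heights = {1: 45.0, 2: 60.0, 3: 15.0, 4: 25.0}
    cell = landuse.cell
    n = landuse.nrows
    buildings = []
    dsm = np.zeros_like(landuse.values)
    lattice = 3  # candidate sites every 3 cells
    for r in range(2, n - 2, lattice):
        for c in range(2, n - 2, lattice):
            code = int(landuse.values[r, c])
            if code not in densities or roadmask[r, c]:
                continue
            if rng.random() > densities[code]:
                continue
            w = rng.integers(1, 3) * cell   # 10 or 20 m
            d = rng.integers(1, 3) * cell
            h = float(rng.lognormal(math.log(mean_heights[code]), 0.5))
            cx, cy = landuse.rc_to_xy(r, c)
            fp = box(cx - w / 2, cy - d / 2, cx + w / 2, cy + d / 2)
            buildings.append((fp, h))
            rw = int(round(w / cell / 2))
            rd = int(round(d / cell / 2))
            r0, r1 = max(r - rd, 0), min(r + rd + 1, n)
            c0, c1 = max(c - rw, 0), min(c + rw + 1, n)
            dsm[r0:r1, c0:c1] = np.maximum(dsm[r0:r1, c0:c1], h)
    return buildings, dsm


def _stations(config: PipelineConfig, rng, n_stations: int, max_r: float,
              roadmask: np.ndarray, template: RasterGrid) -> pd.DataFrame:
    """Jittered-lattice station layout inside the full-buffer margin,
    snapped to cell centers.

    Stations are ambient background monitors: cells inside the street
    space are rejected (regulatory monitors are sited away from canyon
    hot-spots), re-drawing the jitter up to a few times per lattice slot.
    """
    k = int(math.ceil(math.sqrt(n_stations)))
    lo, hi = max_r, config.extent - max_r
    span = (hi - lo) / k
    recs = []
    i = 0
    for a in range(k):
        for b in range(k):
            if i >= n_stations:
                break
            for _ in range(12):
                x = lo + (a + rng.uniform(0.15, 0.85)) * span
                y = lo + (b + rng.uniform(0.15, 0.85)) * span
                cx = (math.floor(x / config.cell_size) + 0.5) \
                    * config.cell_size
                cy = (math.floor(y / config.cell_size) + 0.5) \
                    * config.cell_size
                r, c = template.xy_to_rc(cx, cy)
                if not roadmask[r, c]:
                    break
            recs.append({"station": f"S{i:02d}", "x": cx, "y": cy,
                         "elev": 0.0})
            i += 1
    return pd.DataFrame(recs)


def _bus_stops(roads: RoadGraph, rng) -> pd.DataFrame:
    recs = []
    for rec in roads.segments():
        geom = rec["geometry"]
        n_stop = int(geom.length // 250)
        for _ in range(n_stop):
            p = geom.interpolate(rng.uniform(0.05, 0.95), normalized=True)
            recs.append({"x": p.x, "y": p.y})
    return pd.DataFrame(recs, columns=["x", "y"])


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

@dataclass
class TruthFields:
    """Daily true PM2.5 as a static spatial surface plus a scalar daily
    background; ``field(day)`` materialises one day's raster."""

    static: RasterGrid          # spatial component, mean-zero background
    regional: RasterGrid        # background-gradient component seen by AOD
    background: pd.Series       # day -> µg/m³
    floor: float = 1.0
    n_clipped: int = 0

    def field(self, day: int) -> RasterGrid:
        vals = self.static.values + float(self.background.loc[day])
        clipped = vals < self.floor
        self.n_clipped += int(np.sum(clipped))
        return self.static.with_values(np.maximum(vals, self.floor))


def simulate_truth(scene: CityScene, params: TruthParams,
                   dates: pd.DataFrame,
                   rng: np.random.Generator | None = None) -> TruthFields:
    """Compose the generative PM2.5 surface and daily AR(1) background."""
    if dates["season"].nunique() < 2:
        raise ValueError("dates must cover at least 2 seasons")
    rng = rng if rng is not None else np.random.default_rng(scene.config.seed + 1)
    grid = scene.landuse
    X, Y = grid.cell_centers()
    gx, gy = params.gradient
    regional = (gx * (X - X.mean()) + gy * (Y - Y.mean())) / 1000.0

    from .predictors import class_fraction_grid
    emission = np.zeros_like(regional)
    for code, name in LANDUSE_CLASSES.items():
        s = params.class_strengths.get(name, 0.0)
        if s != 0.0:
            frac = class_fraction_grid(grid, code, params.true_radius)
            emission += s * frac.values

    roadmask = road_mask_grid(scene.roads, grid, halfwidth=12.0)
    svf = svf_grid(scene.dsm, max_dist=SVF_SEARCH_DIST).values
    fai = point_fai_grid(scene.dsm, R=FAI_DECAY_RADIUS, c=2.0).values
    morph = np.where(roadmask,
                     params.svf_coef * (svf - 1.0) + params.fai_coef * fai,
                     0.0)
    static = regional + emission + morph

    # AR(1) daily background around the season mean
    bg = {}
    anom = 0.0
    innov_sd = params.background_sd * math.sqrt(1 - params.ar1 ** 2)
    for _, row in dates.iterrows():
        anom = params.ar1 * anom + rng.normal(0.0, innov_sd)
        bg[int(row["day"])] = SEASON_BACKGROUND.get(
            row["season"], 20.0) + anom
    neg_strengths = [s for s in params.class_strengths.values() if s < 0]
    if neg_strengths:
        worst = static + min(bg.values())
        if np.mean(worst < params.floor) > 0.05:
            import warnings
            warnings.warn("negative emission strengths clip >5% of cells")
    return TruthFields(static=grid.with_values(static),
                       regional=grid.with_values(regional),
                       background=pd.Series(bg), floor=params.floor)


# ---------------------------------------------------------------------------
# Observations
# ---------------------------------------------------------------------------

def rh_correction_factor(rh):
    """Hygroscopic-growth correction factor 1 + 0.25·RH²/(1−RH) for
    light-scattering PM monitors; RH is a fraction in [0, 1)."""
    rh = np.asarray(rh, dtype=float)
    if np.any((rh < 0) | (rh >= 1)):
        raise ValueError("RH must lie in [0, 1)")
    out = 1.0 + 0.25 * rh ** 2 / (1.0 - rh)
    return float(out) if out.ndim == 0 else out


@dataclass
class Observations:
    stations: pd.DataFrame        # station, day, pm
    weather: pd.DataFrame         # station, day, TEMP..MSLP
    sounding: pd.DataFrame        # indexed by day
    aod: dict                     # day -> (terra AODScene, aqua AODScene)
    mobile: pd.DataFrame          # site, day, hour, t, x, y, pm_raw, RH, Ta
    background: pd.DataFrame     # day, hour, value (hourly bg station)
    sites: pd.DataFrame           # site, x, y


def sample_observations(truth: TruthFields, scene: CityScene,
                        params: TruthParams, dates: pd.DataFrame,
                        rng: np.random.Generator | None = None,
                        n_sites: int = 10,
                        samples_per_site: int = 500) -> Observations:
    """Draw station, satellite and mobile observations from the truth."""
    rng = rng if rng is not None else np.random.default_rng(scene.config.seed + 2)
    grid = scene.landuse

    # --- station series ---------------------------------------------------
    st_rows = []
    for _, st in scene.stations.iterrows():
        base = float(truth.static.sample(st["x"], st["y"]))
        for day in truth.background.index:
            pm = max(base + float(truth.background.loc[day])
                     + rng.normal(0.0, params.sigma_station), 0.0)
            st_rows.append({"station": st["station"], "day": int(day),
                            "pm": pm})
    stations = pd.DataFrame(st_rows)

    weather = _weather(scene, dates, rng)
    sounding = _sounding(dates, rng)
    aod = _aod_scenes(truth, scene, params, dates, rng)
    mobile, background, sites = _mobile(truth, scene, params, dates, rng,
                                        n_sites, samples_per_site)
    return Observations(stations=stations, weather=weather,
                        sounding=sounding, aod=aod, mobile=mobile,
                        background=background, sites=sites)


def _weather(scene: CityScene, dates: pd.DataFrame, rng) -> pd.DataFrame:
    base = {"spring": (22.0, 78.0), "summer": (30.0, 82.0),
            "fall": (24.0, 70.0), "winter": (16.0, 62.0)}
    rows = []
    for _, d in dates.iterrows():
        t0, rh0 = base.get(d["season"], (22.0, 75.0))
        t_day = t0 + rng.normal(0, 2.0)
        rh_day = rh0 + rng.normal(0, 5.0)
        for _, ws in scene.weather_stations.iterrows():
            rows.append({
                "station": ws["station"], "day": int(d["day"]),
                "TEMP": t_day + rng.normal(0, 0.8),
                "RH": float(np.clip(rh_day + rng.normal(0, 3.0), 20, 98)),
                "WSPD": float(rng.lognormal(math.log(2.5), 0.4)),
                "RF": float(rng.exponential(1.5) * (rng.random() < 0.3)),
                "MSLP": 1012.0 + rng.normal(0, 3.0),
            })
    return pd.DataFrame(rows)


def _sounding(dates: pd.DataFrame, rng) -> pd.DataFrame:
    rows = {}
    for _, d in dates.iterrows():
        rows[int(d["day"])] = {
            "KINX": 25.0 + rng.normal(0, 6.0),
            "PWAT": 40.0 + rng.normal(0, 8.0),
            "CINV": rng.normal(0, 1.0),
            "LCLP": 950.0 + rng.normal(0, 15.0),
            "LFCV": 800.0 + rng.normal(0, 40.0),
            "VTOT": 26.0 + rng.normal(0, 2.0),
        }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "day"
    return df


def _aod_scenes(truth: TruthFields, scene: CityScene, params: TruthParams,
                dates: pd.DataFrame, rng) -> dict:
    """Terra/Aqua overpasses on a coarse pixel grid with a seeded
    spatially-correlated cloud process and a south-coast flag band."""
    from .aod_met import (AODScene, QA_CLEAR, QA_CLOUDY,
                          QA_POSSIBLY_CLOUDY)
    cfg = scene.config
    ratio = int(round(cfg.aod_cell / cfg.cell_size))
    n_fine = scene.landuse.nrows
    n_coarse = n_fine // ratio
    regional = truth.regional.values[:n_coarse * ratio, :n_coarse * ratio]
    pix_regional = regional.reshape(n_coarse, ratio, n_coarse, ratio
                                    ).mean(axis=(1, 3))
    # coastline band: within 2 km of the southern edge, scaled to the scene
    coast_width = min(2000.0, 0.2 * cfg.extent)
    _, Yc = np.meshgrid(np.arange(n_coarse), np.arange(n_coarse))
    y_centers = cfg.extent - (Yc + 0.5) * cfg.aod_cell
    coastline = y_centers < coast_width
    out = {}
    for _, d in dates.iterrows():
        day = int(d["day"])
        scenes = []
        for sensor in ("Terra", "Aqua"):
            pm_pix = pix_regional + float(truth.background.loc[day])
            aod_vals = (pm_pix - params.aod_intercept) / params.aod_slope
            aod_vals = np.maximum(
                aod_vals + rng.normal(0, params.sigma_aod, aod_vals.shape),
                0.0)
            cloud_field = gaussian_filter(
                rng.standard_normal((n_coarse, n_coarse)), 1.0, mode="wrap")
            q_cloud = float(np.clip(1.0 - params.cloud_fraction, 0.0, 1.0))
            q_poss = float(np.clip(q_cloud - 0.1, 0.0, 1.0))
            thr = np.quantile(cloud_field, q_cloud)
            thr_poss = np.quantile(cloud_field, q_poss)
            qa_cloud = np.where(
                cloud_field >= thr, QA_CLOUDY,
                np.where(cloud_field >= thr_poss, QA_POSSIBLY_CLOUDY,
                         QA_CLEAR))
            qa_adj = (gaussian_filter(
                qa_cloud.astype(float), 0.7) > 0.8).astype(int)
            grid = RasterGrid(aod_vals, 0.0, n_coarse * cfg.aod_cell,
                              cfg.aod_cell, crs=cfg.crs)
            scenes.append(AODScene(aod=grid, qa_cloud=qa_cloud,
                                   qa_adjacency=qa_adj,
                                   coastline=coastline, sensor=sensor,
                                   date=day))
        out[day] = tuple(scenes)
    return out


def _site_locations(scene: CityScene, rng, n_sites: int) -> pd.DataFrame:
    """Sampling sites at road nodes in building-rich areas, spread out by
    greedy farthest-point selection."""
    g = scene.roads.graph
    centroids = np.array([[f.centroid.x, f.centroid.y]
                          for f, _ in scene.buildings])
    nodes = [(nid, d["x"], d["y"]) for nid, d in g.nodes(data=True)]
    margin = 250.0
    scored = []
    for nid, x, y in nodes:
        if not (margin < x < scene.config.extent - margin
                and margin < y < scene.config.extent - margin):
            continue
        n_close = int(np.sum(np.hypot(centroids[:, 0] - x,
                                      centroids[:, 1] - y) < 150.0))
        scored.append((n_close, nid, x, y))
    scored.sort(reverse=True)
    pool = scored[:max(4 * n_sites, len(scored) // 2)]
    chosen = [pool[0]]
    while len(chosen) < n_sites and len(chosen) < len(pool):
        best, best_d = None, -1.0
        for cand in pool:
            d = min(math.hypot(cand[2] - c[2], cand[3] - c[3])
                    for c in chosen)
            if d > best_d:
                best, best_d = cand, d
        chosen.append(best)
    return pd.DataFrame([{"site": f"T{i:02d}", "node": c[1],
                          "x": c[2], "y": c[3]}
                         for i, c in enumerate(chosen)])


def _mobile(truth: TruthFields, scene: CityScene, params: TruthParams,
            dates: pd.DataFrame, rng, n_sites: int, samples_per_site: int):
    """Pedestrian tracks: a random walk along road polylines at 0.8 m/s
    with 1-s logging, split over the three daily time slots."""
    sites = _site_locations(scene, rng, n_sites)
    g = scene.roads.graph
    warm = dates[dates["season"].isin(("summer", "spring"))]
    warm_days = (warm if len(warm) else dates)["day"].to_numpy()
    slots = (9, 14, 19)
    speed, dt = 0.8, 1.0
    bg_anom = {}
    rows = []
    for _, site in sites.iterrows():
        day = int(rng.choice(warm_days))
        for hour in slots:
            bg_anom.setdefault((day, hour),
                               rng.normal(0.0, params.hourly_bg_sd))
        node = site["node"]
        prev = None
        per_slot = int(math.ceil(samples_per_site / len(slots)))
        t_slot, slot_i, logged = 0, 0, 0
        rh_base = rng.uniform(0.5, 0.8)
        while logged < samples_per_site:
            nbrs = [v for v in g.neighbors(node) if v != prev] \
                or list(g.neighbors(node))
            nxt = nbrs[rng.integers(len(nbrs))]
            geom = g.edges[node, nxt]["geometry"]
            forward = math.isclose(g.nodes[node]["x"], geom.coords[0][0]) \
                and math.isclose(g.nodes[node]["y"], geom.coords[0][1])
            length = geom.length
            s = 0.0
            eps = 1e-6
            ext = scene.config.extent
            while s < length and logged < samples_per_site:
                p = geom.interpolate(s if forward else length - s)
                if not (0 <= p.x < ext - eps and eps < p.y <= ext):
                    s += speed * dt
                    continue
                hour = slots[slot_i]
                rh = float(np.clip(
                    rh_base + 0.1 * math.sin(t_slot / 300.0)
                    + rng.normal(0, 0.02), 0.30, 0.92))
                pm_true = (float(truth.static.sample(p.x, p.y))
                           + float(truth.background.loc[day])
                           + bg_anom[(day, hour)])
                pm_raw = max(pm_true * rh_correction_factor(rh)
                             + rng.normal(0.0, params.sigma_mobile), 0.0)
                rows.append({"site": site["site"], "day": day,
                             "hour": hour, "t": t_slot,
                             "x": p.x, "y": p.y, "pm_raw": pm_raw,
                             "RH": rh, "Ta": 28.0 + rng.normal(0, 0.5)})
                logged += 1
                t_slot += 1
                if t_slot >= per_slot and slot_i < len(slots) - 1:
                    slot_i += 1
                    t_slot = 0
                s += speed * dt
            prev, node = node, nxt
    mobile = pd.DataFrame(rows)
    bg_rows = [{"day": d, "hour": h, "value": 18.0 + a}
               for (d, h), a in sorted(bg_anom.items())]
    background = pd.DataFrame(bg_rows)
    return mobile, background, sites
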