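"""End-to-end pipeline over the synthetic city, with staged artifacts.

Canonical stage order::

    scene -> truth -> aod -> met -> predictors -> selection -> gtwr
          -> neighborhood -> mapping

``run_pipeline(config, stages, out_dir)`` executes a prefix of that order,
writing each stage's key outputs (ASCII-grid rasters, GeoJSON vectors,
CSV tables, JSON reports) plus a manifest recording the configuration,
seed, package/library versions and a content hash per artifact; a rerun
with the same config is bit-identical for the deterministic stages (all
of them — every random draw flows from the seeded generator).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aod_met import (MET_VARIABLES, daily_merge, krige_met, krige_points,
                      qa_filter, resample_bilinear)
from .geo_io import PipelineConfig, RasterGrid, write_raster, write_vector
from .gtwr import fit_gtwr, loocv, select_bandwidth
from .mapping import (annual_combine, delta_layer, overlay,
                      road_cell_predictors, seasonal_maps)
from .morphology import point_fai_grid, svf_grid
from .neighborhood import (attach_neighborhood_predictors, background_adjust,
                           delta_pm25, fit_delta_mlr, rh_correct)
from .predictors import (CLASS_ABBR, LANDUSE_CLASSES, ROAD_ABBR,
                         assemble_table, buffer_mean_grid,
                         class_fraction_grid, line_density_grid,
                         point_count_grid)
from .road_network import segment_metrics
from .selection import distance_decay_select, stepwise_select
from .synthetic_city import (FAI_DECAY_RADIUS, SVF_SEARCH_DIST, TruthParams,
                             generate_scene, sample_observations,
                             simulate_truth, study_dates)

__all__ = ["STAGES", "run_pipeline", "DependencyError",
           "build_predictor_grids"]

log = logging.getLogger(__name__)

STAGES = ("scene", "truth", "aod", "met", "predictors", "selection",
          "gtwr", "neighborhood", "mapping")


class DependencyError(RuntimeError):
    pass


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _season_of(dates: pd.DataFrame) -> dict:
    return {s: list(g["day"]) for s, g in dates.groupby("season", sort=False)}


def build_predictor_grids(scene, subset, schema, aod_grid: RasterGrid,
                          met_means: dict, sounding_means: dict) -> dict:
    """Materialise a 10-m surface for every variable in *subset*.

    Spatial buffer variables use the convolution form of the same
    cell-center buffer rule as the station extraction; geolocation
    variables are coordinate ramps; temporal variables are kriged
    (weather) or constant (sounding indices) surfaces for the period.
    """
    from scipy.signal import fftconvolve

    from .predictors import disk_kernel

    grid = scene.landuse
    X, Y = grid.cell_centers()
    abbr_to_code = {v: k for k, v in
                    {c: CLASS_ABBR[n] for c, n in LANDUSE_CLASSES.items()
                     }.items()}
    road_abbr = {v: k for k, v in ROAD_ABBR.items()}
    out = {"AOD": aod_grid}
    bmask = (scene.dsm.values > 0).astype(float)
    for var in subset:
        if var in out:
            continue
        info = schema[var]
        if info["kind"] == "spatial":
            base, radius = info["variable"], float(info["radius"])
            if base in abbr_to_code:
                out[var] = class_fraction_grid(grid, abbr_to_code[base],
                                               radius)
            elif base == "GCR":
                out[var] = buffer_mean_grid(scene.green_cover, radius)
            elif base in road_abbr:
                out[var] = line_density_grid(scene.roads, grid, radius,
                                             road_abbr[base])
            elif base == "BUS":
                out[var] = point_count_grid(scene.bus_stops, grid, radius)
            elif base == "POP":
                out[var] = buffer_mean_grid(scene.population, radius)
            elif base == "FAI":
                kernel = disk_kernel(radius, grid.cell)
                front = scene.dsm.values * grid.cell  # m² front per cell
                total = fftconvolve(front, kernel, mode="same")
                out[var] = grid.with_values(
                    np.maximum(total, 0.0) / (np.pi * radius ** 2))
            elif base == "ROUGH":
                kernel = disk_kernel(radius, grid.cell)
                hsum = fftconvolve(scene.dsm.values, kernel, mode="same")
                cnt = fftconvolve(bmask, kernel, mode="same")
                out[var] = grid.with_values(
                    0.1 * np.where(cnt > 0.5, hsum / np.maximum(cnt, 0.5),
                                   0.0))
            else:
                raise ValueError(f"no surface builder for {var}")
        elif info["kind"] == "geo":
            out[var] = grid.with_values(
                {"LONG": X, "LAT": Y,
                 "ELEV": np.zeros_like(X)}[info["variable"]])
        else:  # temporal
            if var in met_means:
                out[var] = met_means[var]
            elif var in sounding_means:
                out[var] = grid.with_values(
                    np.full(grid.values.shape, sounding_means[var]))
            else:
                raise ValueError(f"missing temporal surface for {var}")
    return out


def run_pipeline(config: PipelineConfig, stages=None,
                 out_dir: str | Path = "runs",
                 truth_params: TruthParams | None = None,
                 days_per_season: int = 12,
                 n_sites: int = 10,
                 samples_per_site: int = 500) -> dict:
    """Run the requested prefix of the canonical stage order.

    Returns the in-memory state dict (scene, truth, tables, fits, maps,
    reports); artifacts and the manifest land under *out_dir*.
    """
    stages = list(stages or STAGES)
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
    order = [s for s in STAGES if s in stages]
    for i, s in enumerate(order):
        want = STAGES[:STAGES.index(s)]
        if list(want) != order[:i]:
            raise DependencyError(
                f"stage {s!r} requires prior stages {list(want)}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params = truth_params or TruthParams()
    state: dict = {"config": config, "params": params}
    manifest = {
        "config": config.to_dict(),
        "truth_params": params.to_dict(),
        "versions": {"mslur": __version__, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
        "artifacts": {},
    }

    for stage in order:
        arts = _STAGE_FUNCS[stage](state, config, params, out_dir,
                                   days_per_season=days_per_season,
                                   n_sites=n_sites,
                                   samples_per_site=samples_per_site)
        manifest["stages"][stage] = sorted(a.name for a in arts)
        for a in arts:
            manifest["artifacts"][a.name] = _hash_file(a)
        (out_dir / "manifest.json").write_text(
            json.dumps(manifest, indent=1, sort_keys=True))
    state["manifest"] = manifest
    return state


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _stage_scene(state, config, params, out, **kw):
    scene = generate_scene(config)
    state["scene"] = scene
    state["dates"] = study_dates(config, kw["days_per_season"])
    arts = [
        write_raster(scene.landuse, out / "landuse.asc"),
        write_raster(scene.dsm, out / "dsm.asc"),
        write_raster(scene.population, out / "population.asc"),
        write_vector(scene.roads, out / "roads.geojson"),
        write_vector(scene.stations.to_dict("records"),
                     out / "stations.geojson", crs=config.crs),
    ]
    return [Path(a) for a in arts] + [
        Path(str(a) + ".meta.json") for a in arts if str(a).endswith(".asc")]


def _stage_truth(state, config, params, out, **kw):
    rng = np.random.default_rng(config.seed + 1)
    truth = simulate_truth(state["scene"], params, state["dates"], rng)
    obs = sample_observations(truth, state["scene"], params, state["dates"],
                              np.random.default_rng(config.seed + 2),
                              n_sites=kw["n_sites"],
                              samples_per_site=kw["samples_per_site"])
    state["truth"], state["obs"] = truth, obs
    arts = [
        write_raster(truth.static, out / "truth_static.asc"),
    ]
    obs.stations.to_csv(out / "station_pm25.csv", index=False)
    obs.weather.to_csv(out / "weather.csv", index=False)
    obs.sounding.to_csv(out / "sounding.csv")
    obs.mobile.to_csv(out / "mobile_raw.csv", index=False)
    obs.background.to_csv(out / "background.csv", index=False)
    return [Path(a) for a in arts] + [
        out / "station_pm25.csv", out / "weather.csv", out / "sounding.csv",
        out / "mobile_raw.csv", out / "background.csv"]


def _stage_aod(state, config, params, out, **kw):
    obs = state["obs"]
    daily = {}
    for day, (terra, aqua) in obs.aod.items():
        t, _ = qa_filter(terra)
        a, _ = qa_filter(aqua)
        merged = daily_merge(t, a)
        daily[day] = resample_bilinear(merged, config.cell_size)
    state["aod_daily"] = daily
    periods = _season_of(state["dates"])
    seasonal = {}
    arts = []
    for season, days in periods.items():
        stack, count = None, None
        for d in days:
            g = daily[d]
            valid = g.valid_mask
            if stack is None:
                stack = np.zeros(g.values.shape)
                count = np.zeros(g.values.shape)
            stack += np.where(valid, g.values, 0.0)
            count += valid
        ref = daily[days[0]]
        vals = np.where(count > 0, stack / np.maximum(count, 1), ref.nodata)
        seasonal[season] = ref.with_values(vals)
        arts.append(write_raster(seasonal[season],
                                 out / f"aod_{season}.asc"))
    state["aod_seasonal"] = seasonal
    return [Path(a) for a in arts]


def _stage_met(state, config, params, out, **kw):
    obs, scene = state["obs"], state["scene"]
    wcoords = scene.weather_stations[["x", "y"]].to_numpy(dtype=float)
    targets = scene.stations[["x", "y"]].to_numpy(dtype=float)
    rows = []
    for day, g in obs.weather.groupby("day"):
        g = g.set_index("station").loc[scene.weather_stations["station"]]
        for var in MET_VARIABLES:
            pred = krige_points(g[var].to_numpy(dtype=float), wcoords,
                                targets)
            for sid, v in zip(scene.stations["station"], pred):
                rows.append({"station": sid, "day": int(day),
                             "variable": var, "value": float(v)})
    met_long = pd.DataFrame(rows)
    met_station = met_long.pivot_table(
        index=["station", "day"], columns="variable", values="value")
    state["met_station"] = met_station
    met_long.to_csv(out / "met_station.csv", index=False)
    return [out / "met_station.csv"]


def _stage_predictors(state, config, params, out, **kw):
    periods = _season_of(state["dates"])
    table, schema = assemble_table(
        state["scene"], state["aod_daily"], state["met_station"],
        state["obs"].sounding, periods, config.buffer_radii)
    response = _station_response(state, periods, table.index)
    state["table"], state["schema"] = table, schema
    state["response"] = response
    table.to_csv(out / "predictor_table.csv")
    (out / "predictor_schema.json").write_text(
        json.dumps(schema, indent=1, sort_keys=True))
    return [out / "predictor_table.csv", out / "predictor_schema.json"]


def _station_response(state, periods, index) -> pd.Series:
    """Season-mean observed PM2.5 aligned to the predictor-table rows.

    PM is averaged over the *AOD-valid* days of each (station, period) —
    the same day set behind the row's AOD mean — so the satellite's
    clear-sky sampling of the background does not bias the AOD–PM link.
    """
    st = state["obs"].stations
    scene = state["scene"]
    daily = state["aod_daily"]
    xy = scene.stations.set_index("station")[["x", "y"]]
    vals = {}
    for sid, period in index:
        x, y = xy.loc[sid]
        good = []
        for day in periods[period]:
            g = daily.get(day)
            if g is None:
                continue
            v = float(g.sample(x, y))
            if not np.isclose(v, g.nodata):
                good.append(day)
        sel = st[(st["station"] == sid) & st["day"].isin(good)]
        vals[(sid, period)] = float(sel["pm"].mean())
    return pd.Series(vals).reindex(index)


def _stage_selection(state, config, params, out, **kw):
    table, schema = state["table"], state["schema"]
    y = state["response"]
    # distance-decay correlations are computed on the residual of
    # PM ~ AOD: AOD is forced into every model and carries the regional
    # background + gradient, so the buffer radius should be chosen by
    # what remains for the spatial predictors to explain
    import statsmodels.api as sm
    aod_fit = sm.OLS(y.to_numpy(),
                     sm.add_constant(table["AOD"].to_numpy())).fit()
    y_spatial = pd.Series(aod_fit.resid, index=y.index)
    families: dict[str, list[str]] = {}
    for col, info in schema.items():
        if info["kind"] == "spatial":
            families.setdefault(info["variable"], []).append(col)
    chosen, curves = [], {}
    for fam, cols in families.items():
        cols = sorted(cols, key=lambda c: schema[c]["radius"])
        try:
            col, curve = distance_decay_select(y_spatial, table, cols)
        except ValueError:
            log.info("family %s constant at all radii; dropped", fam)
            continue
        chosen.append(col)
        curves[fam] = {c: (None if np.isnan(v) else float(v))
                       for c, v in curve.items()}
    temporal = [c for c, info in schema.items()
                if info["kind"] in ("temporal", "geo")]
    result = stepwise_select(table, y, forced=("AOD",),
                             candidates=chosen + temporal)
    state["selection"] = result
    state["dd_curves"] = curves
    report = {"distance_decay": curves, **result.report()}
    (out / "selection_report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True))
    return [out / "selection_report.json"]


def _stage_gtwr(state, config, params, out, **kw):
    table = state["table"]
    y = state["response"]
    subset = [c for c in state["selection"].selected]
    periods = _season_of(state["dates"])
    coords_all = state["scene"].stations.set_index("station")[["x", "y"]]
    fits, diags = {}, {}
    for season, days in periods.items():
        rows = table.index.get_level_values("period") == season
        sub_tab = table[rows]
        sub_y = y[rows]
        coords = coords_all.loc[
            sub_tab.index.get_level_values("station")].to_numpy(dtype=float)
        times = np.full(len(sub_tab), float(np.mean(days)))
        spec, _ = select_bandwidth(sub_tab, sub_y, coords, times, subset,
                                   config.kernel, config.h_grid,
                                   config.lambda_grid)
        fit = fit_gtwr(sub_tab, sub_y, coords, times, subset, spec)
        fit.diagnostics["cv_r2"] = loocv(sub_tab, sub_y, coords, times,
                                         subset, spec)
        fits[season] = fit
        diags[season] = {k: (v if np.isfinite(v) else None)
                         for k, v in fit.diagnostics.items()}
        diags[season].update({"h": spec.h, "lambda": spec.lam,
                              "kernel": spec.kernel})
    state["gtwr_fits"] = fits
    (out / "gtwr_diagnostics.json").write_text(
        json.dumps(diags, indent=1, sort_keys=True))
    return [out / "gtwr_diagnostics.json"]


def _stage_neighborhood(state, config, params, out, **kw):
    scene, obs = state["scene"], state["obs"]
    mob = obs.mobile.copy()
    mob["pm"] = rh_correct(mob["pm_raw"], mob["RH"])
    mob = background_adjust(mob, obs.background)
    mob = delta_pm25(mob)
    segmet = segment_metrics(scene.roads)
    svf = svf_grid(scene.dsm, max_dist=SVF_SEARCH_DIST)
    fai = point_fai_grid(scene.dsm, R=FAI_DECAY_RADIUS, c=2.0)
    state["svf_grid"], state["fai_grid"] = svf, fai
    state["seg_metrics"] = segmet
    delta_tab = attach_neighborhood_predictors(mob, scene.roads, segmet,
                                               svf, fai)
    model = fit_delta_mlr(delta_tab)
    state["delta_table"] = delta_tab
    state["delta_model"] = model
    delta_tab.to_csv(out / "delta_samples.csv", index=False)
    (out / "delta_model.json").write_text(
        json.dumps(model.report(), indent=1, sort_keys=True))
    return [out / "delta_samples.csv", out / "delta_model.json"]


def _stage_mapping(state, config, params, out, **kw):
    scene = state["scene"]
    periods = _season_of(state["dates"])
    schema = state["schema"]
    subset = state["selection"].selected
    met = state["met_station"]
    snd = state["obs"].sounding
    grids_by_season, times = {}, {}
    wcoords = scene.weather_stations[["x", "y"]].to_numpy(dtype=float)
    for season, days in periods.items():
        met_means = {}
        needed_met = [v for v in subset if v in MET_VARIABLES]
        if needed_met:
            wmeans = state["obs"].weather[
                state["obs"].weather["day"].isin(days)].groupby(
                    "station")[needed_met].mean()
            wmeans = wmeans.loc[scene.weather_stations["station"]]
            for var in needed_met:
                met_means[var] = krige_met(
                    wmeans[var].to_numpy(dtype=float), wcoords,
                    scene.landuse, variable=var)
        snd_means = snd.loc[snd.index.intersection(days)].mean().to_dict()
        grids_by_season[season] = build_predictor_grids(
            scene, subset, schema, state["aod_seasonal"][season],
            met_means, snd_means)
        times[season] = float(np.mean(days))
    smaps = seasonal_maps(state["gtwr_fits"], grids_by_season, times)
    day_counts = {s: len(d) for s, d in periods.items()}
    annual, annual_diag = annual_combine(smaps, day_counts,
                                         state["gtwr_fits"])
    dtab, rows, cols = road_cell_predictors(
        scene.roads, state["seg_metrics"], state["svf_grid"],
        state["fai_grid"])
    dgrid, dreport = delta_layer(state["delta_model"], dtab, rows, cols,
                                 scene.landuse)
    final = overlay(annual, dgrid)
    state["seasonal_maps"] = smaps
    state["annual_map"] = annual
    state["delta_map"] = dgrid
    state["final_map"] = final
    state["annual_diag"] = annual_diag
    arts = []
    for season, g in smaps.items():
        arts.append(write_raster(g, out / f"pm25_{season}.asc"))
    arts.append(write_raster(annual, out / "pm25_annual.asc"))
    arts.append(write_raster(dgrid, out / "delta_pm25.asc"))
    arts.append(write_raster(final, out / "pm25_final.asc"))
    (out / "mapping_report.json").write_text(json.dumps(
        {"annual": annual_diag, "delta_mask": dreport}, indent=1,
        sort_keys=True))
    return [Path(a) for a in arts] + [out / "mapping_report.json"]


_STAGE_FUNCS = {
    "scene": _stage_scene,
    "truth": _stage_truth,
    "aod": _stage_aod,
    "met": _stage_met,
    "predictors": _stage_predictors,
    "selection": _stage_selection,
    "gtwr": _stage_gtwr,
    "neighborhood": _stage_neighborhood,
    "mapping": _stage_mapping,
}
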