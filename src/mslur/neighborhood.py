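"""Mobile-sample calibration and the neighborhood-scale ΔPM2.5 model.

Raw light-scattering PM2.5 readings are first corrected for hygroscopic
growth, ``pm = pm_raw / CF`` with ``CF = 1 + 0.25 RH²/(1 − RH)`` (RH a
fraction), then adjusted against the hourly background station series so
hour-to-hour and day-to-day drift is removed while the campaign mean is
preserved.  The response is the within-site deviation
``ΔPM2.5 = pm − mean(pm over the site)``, which is positive where a point
runs above its site average.

Each sample inherits the eight network metrics of its nearest road segment
(within a snap distance) and carries point-level sky-view factor and
point-FAI; the ΔPM2.5 model is an ordinary least-squares fit screened with
the same p < 0.05 / VIF rules as the city stage, with the numeric training
range of every retained predictor stored so mapping can refuse to
extrapolate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from shapely.geometry import Point
from shapely.strtree import STRtree

from .geo_io import RasterGrid, RoadGraph
from .road_network import CENTRALITY_COLS, SYNTAX_COLS
from .selection import StepwiseResult, stepwise_select
from .synthetic_city import rh_correction_factor

__all__ = [
    "rh_correct", "background_adjust", "delta_pm25",
    "attach_neighborhood_predictors", "fit_delta_mlr", "DeltaModel",
    "NEIGHBORHOOD_PREDICTORS",
]

log = logging.getLogger(__name__)

NEIGHBORHOOD_PREDICTORS = CENTRALITY_COLS + SYNTAX_COLS + ["SVF", "FAI_POINT"]


def rh_correct(pm_raw, rh):
    """Divide raw readings by the RH correction factor; RH in [0, 1)."""
    pm_raw = np.asarray(pm_raw, dtype=float)
    return pm_raw / rh_correction_factor(rh)


def background_adjust(samples: pd.DataFrame,
                      background: pd.DataFrame) -> pd.DataFrame:
    """Remove hourly background anomalies from sample PM.

    ``samples`` needs ``pm``, ``day`` and ``hour`` columns; ``background``
    is the hourly background-station series (day, hour, value).  Each
    sample is shifted by −(background(hour) − campaign-mean background),
    which preserves the overall mean level.
    """
    bg = background.set_index(["day", "hour"])["value"]
    keys = list(zip(samples["day"].astype(int), samples["hour"].astype(int)))
    missing = sorted({k for k in keys if k not in bg.index})
    if missing:
        raise ValueError(f"background series missing hours: {missing}")
    anomaly = np.array([bg.loc[k] for k in keys]) - bg.mean()
    out = samples.copy()
    out["pm"] = samples["pm"].to_numpy(dtype=float) - anomaly
    return out


def delta_pm25(samples: pd.DataFrame, min_samples: int = 30) -> pd.DataFrame:
    """Within-site deviation response: Δ = pm − site mean."""
    counts = samples.groupby("site").size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"singleton site(s): {list(small.index)}")
    low = counts[counts < min_samples]
    if len(low):
        raise ValueError(
            f"sites below the {min_samples}-sample minimum: "
            f"{list(low.index)}")
    out = samples.copy()
    out["delta_pm"] = samples["pm"] - samples.groupby("site")["pm"].transform("mean")
    return out


def attach_neighborhood_predictors(samples: pd.DataFrame, roads: RoadGraph,
                                   seg_metrics: pd.DataFrame,
                                   svf: RasterGrid, fai_point: RasterGrid,
                                   max_snap: float = 25.0) -> pd.DataFrame:
    """Snap samples to segments and attach network + morphology predictors.

    Samples farther than *max_snap* metres from every road are dropped
    with a logged count.  Segment metrics are shared by all samples on a
    segment; SVF and point-FAI are evaluated at the sample's own location.
    """
    segs = roads.segments()
    geoms = [rec["geometry"] for rec in segs]
    ids = [rec["edge_id"] for rec in segs]
    tree = STRtree(geoms)
    pts = [Point(x, y) for x, y in zip(samples["x"], samples["y"])]
    nearest = tree.query_nearest(pts, max_distance=max_snap,
                                 all_matches=False)
    seg_of = {}
    for pt_idx, geom_idx in zip(*nearest):
        seg_of[int(pt_idx)] = ids[int(geom_idx)]
    keep = sorted(seg_of)
    n_drop = len(samples) - len(keep)
    if n_drop:
        log.info("dropped %d unsnappable samples (> %.0f m from roads)",
                 n_drop, max_snap)
    out = samples.iloc[keep].copy()
    out["segment_id"] = [seg_of[i] for i in keep]
    metrics = seg_metrics.loc[out["segment_id"]].reset_index(drop=True)
    out = out.reset_index(drop=True)
    out[metrics.columns] = metrics
    out["SVF"] = svf.sample(out["x"].to_numpy(), out["y"].to_numpy())
    out["FAI_POINT"] = fai_point.sample(out["x"].to_numpy(),
                                        out["y"].to_numpy())
    return out


class DeltaModel:
    """Screened ΔPM2.5 MLR with stored training ranges (no extrapolation).

    The fit is performed on site-centered predictors (the response is a
    within-site deviation by construction, so between-site predictor
    scatter carries no signal and would only rotate the coefficients);
    ``center`` holds the global training means used when predicting on
    raw values.
    """

    def __init__(self, result: StepwiseResult, ranges: dict,
                 center: pd.Series):
        self.result = result
        self.ranges = ranges
        self.center = center
        self.predictors = [c for c in result.selected]

    @property
    def model(self):
        return self.result.model

    def params(self) -> pd.Series:
        return self.model.params

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        X = np.column_stack(
            [np.ones(len(table))] +
            [table[c].to_numpy(dtype=float) - self.center[c]
             for c in self.predictors])
        return X @ self.model.params.to_numpy()

    def within_range(self, table: pd.DataFrame) -> np.ndarray:
        ok = np.ones(len(table), dtype=bool)
        for c in self.predictors:
            lo, hi = self.ranges[c]
            vals = table[c].to_numpy(dtype=float)
            ok &= (vals >= lo) & (vals <= hi)
        return ok

    def report(self) -> dict:
        rep = self.result.report()
        rep["ranges"] = {k: [float(a), float(b)]
                         for k, (a, b) in self.ranges.items()}
        return rep


def fit_delta_mlr(delta_table: pd.DataFrame,
                  predictors: list[str] | None = None) -> DeltaModel:
    """Stepwise-screened OLS for ΔPM2.5 on neighborhood predictors.

    Applies the stepwise screening rules with no forced set — every
    retained term keeps p < 0.05 and VIF < 4 (the neighborhood-scale
    collinearity bound; the city stage uses the stricter < 3) — and
    records the numeric training range of each retained predictor.
    """
    predictors = list(predictors or NEIGHBORHOOD_PREDICTORS)
    predictors = [p for p in predictors if p in delta_table.columns]
    n = len(delta_table)
    if n < 10 * max(len(predictors), 1):
        raise ValueError(
            f"need at least {10 * len(predictors)} samples for "
            f"{len(predictors)} candidates, got {n}")
    usable = []
    for p in predictors:
        vals = delta_table[p].to_numpy(dtype=float)
        if np.all(np.isfinite(vals)) and np.std(vals) > 0:
            usable.append(p)
        else:
            log.info("dropping constant or non-finite predictor %s", p)
    predictors = usable
    X = delta_table[predictors].astype(float)
    # within-site design: center predictors per site (the response is
    # site-centered by construction)
    if "site" in delta_table.columns:
        Xc = X - X.groupby(delta_table["site"]).transform("mean")
    else:
        Xc = X - X.mean()
    keep = [c for c in predictors if Xc[c].std() > 0]
    for c in set(predictors) - set(keep):
        log.info("dropping %s: constant within every site", c)
    Xc = Xc[keep]
    M = np.column_stack([np.ones(n), Xc.to_numpy()])
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:  # exact linear dependence
        corr = Xc.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.stack().idxmax()
        raise ValueError(f"rank-deficient predictors, e.g. pair {worst}")
    work = Xc.copy()
    work["delta_pm"] = delta_table["delta_pm"].to_numpy()
    result = stepwise_select(work, work["delta_pm"], forced=(),
                             candidates=keep, vif_max=4.0)
    ranges = {c: (float(delta_table[c].min()), float(delta_table[c].max()))
              for c in result.selected}
    center = delta_table[result.selected].astype(float).mean() \
        if result.selected else pd.Series(dtype=float)
    return DeltaModel(result, ranges, center)
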