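"""Geographically and temporally weighted regression (GTWR).

At every observation i a weighted least-squares fit is solved with weights
that decay with spatiotemporal distance

    d²_ST(i, j) = d²_space(i, j) + lambda · d²_time(i, j)

under a gaussian kernel ``w = exp(-d²_ST / h²)`` or a bisquare kernel
``w = (1 - d²_ST/h²)²`` inside bandwidth h.  The local coefficient vector
``beta(i) = (XᵀW(i)X)⁻¹ XᵀW(i) y`` yields location/time-varying intercept
and slopes; the hat-matrix rows give the effective parameter count tr(S)
used by the small-sample-corrected AICc

    AICc = n ln(RSS/n) + n ln(2π) + n (n + tr(S)) / (n − 2 − tr(S)).

Bandwidth and the space-time scale ratio are chosen by minimising AICc on
a grid with golden-section refinement on h; model validation uses
leave-one-out CV with the self-weight removed.  As h → ∞ (gaussian) every
local fit collapses to global OLS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geo_io import RasterGrid

__all__ = [
    "STKernelSpec", "GTWRFit", "st_weights", "fit_gtwr",
    "select_bandwidth", "loocv", "predict_surface", "aicc",
]

_RIDGE = 1e-8


@dataclass
class STKernelSpec:
    kernel: str = "gaussian"      # or "bisquare"
    h: float = 1000.0             # spatial bandwidth, m
    lam: float = 0.0              # (m/day)² scaling of temporal distance

    def __post_init__(self) -> None:
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        if self.h <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def st_weights(coords_i, time_i, coords, times,
               spec: STKernelSpec) -> np.ndarray:
    """Kernel weights of observation(s) at (coords_i, time_i) against the
    calibration set; coordinates in m, times in days."""
    coords = np.asarray(coords, dtype=float)
    times = np.asarray(times, dtype=float)
    ci = np.asarray(coords_i, dtype=float)
    d2s = (coords[:, 0] - ci[0]) ** 2 + (coords[:, 1] - ci[1]) ** 2
    d2t = (times - float(time_i)) ** 2
    d2 = d2s + spec.lam * d2t
    if spec.kernel == "gaussian":
        return np.exp(-d2 / spec.h ** 2)
    inside = d2 < spec.h ** 2
    w = np.zeros_like(d2)
    w[inside] = (1.0 - d2[inside] / spec.h ** 2) ** 2
    return w


@dataclass
class GTWRFit:
    """Local coefficients and diagnostics of a GTWR calibration."""

    coefficients: pd.DataFrame     # one row per observation, incl. const
    fitted: np.ndarray
    residuals: np.ndarray
    spec: STKernelSpec
    subset: list
    coords: np.ndarray
    times: np.ndarray
    X: np.ndarray
    y: np.ndarray
    trace_s: float
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        y = self.y
        rss = float(np.sum(self.residuals ** 2))
        tss = float(np.sum((y - y.mean()) ** 2))
        n = len(y)
        r2 = 1.0 - rss / tss if tss > 0 else np.nan
        k = self.trace_s
        adj = 1.0 - (1.0 - r2) * (n - 1) / max(n - k - 1, 1e-9)
        self.diagnostics.update({
            "n": n, "r2": r2, "adj_r2": adj, "trace_s": k,
            "aicc": aicc(rss, n, k),
        })


def aicc(rss: float, n: int, trace_s: float) -> float:
    """GWR-style corrected AIC with effective parameters tr(S)."""
    if n - 2 - trace_s <= 0:
        return math.inf
    return (n * math.log(rss / n) + n * math.log(2 * math.pi)
            + n * (n + trace_s) / (n - 2 - trace_s))


def _design(table: pd.DataFrame, subset) -> np.ndarray:
    X = table[list(subset)].to_numpy(dtype=float)
    return np.column_stack([np.ones(len(X)), X])


def _local_fit(X, y, w):
    """Solve one local WLS; returns (beta, hat row ingredients)."""
    Xw = X * w[:, None]
    xtwx = X.T @ Xw
    xtwy = Xw.T @ y
    try:
        beta = np.linalg.solve(xtwx, xtwy)
        inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError:
        xtwx = xtwx + _RIDGE * np.eye(xtwx.shape[0])
        beta = np.linalg.solve(xtwx, xtwy)
        inv = np.linalg.inv(xtwx)
    return beta, inv


def fit_gtwr(table: pd.DataFrame, response, coords, times, subset,
             spec: STKernelSpec) -> GTWRFit:
    """Calibrate local coefficients at every observation."""
    coords = np.asarray(coords, dtype=float)
    times = np.asarray(times, dtype=float)
    X = _design(table, subset)
    y = np.asarray(response, dtype=float)
    if X.shape[0] <= X.shape[1] + 2:
        raise ValueError("need n > p + 2 observations")
    return _fit_core(table, X, y, coords, times, subset, spec)


def _fit_core(table, X, y, coords, times, subset, spec) -> GTWRFit:
    n, p = X.shape
    betas = np.empty((n, p))
    fitted = np.empty(n)
    s_ii = np.empty(n)
    for i in range(n):
        w = st_weights(coords[i], times[i], coords, times, spec)
        beta, inv = _local_fit(X, y, w)
        betas[i] = beta
        fitted[i] = X[i] @ beta
        s_ii[i] = X[i] @ inv @ (X[i] * w[i])
    resid = y - fitted
    cols = ["const"] + list(subset)
    coeff = pd.DataFrame(betas, columns=cols, index=table.index)
    return GTWRFit(coefficients=coeff, fitted=fitted, residuals=resid,
                   spec=spec, subset=list(subset), coords=coords,
                   times=times, X=X, y=y, trace_s=float(np.sum(s_ii)))


def loocv(table: pd.DataFrame, response, coords, times, subset,
          spec: STKernelSpec) -> float:
    """Leave-one-out CV R²: each point predicted with its self-weight
    zeroed."""
    coords = np.asarray(coords, dtype=float)
    times = np.asarray(times, dtype=float)
    X = _design(table, subset)
    y = np.asarray(response, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("LOOCV needs n >= 10")
    pred = np.empty(n)
    for i in range(n):
        w = st_weights(coords[i], times[i], coords, times, spec)
        w = w.copy()
        w[i] = 0.0
        beta, _ = _local_fit(X, y, w)
        pred[i] = X[i] @ beta
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ss_res / ss_tot


def select_bandwidth(table: pd.DataFrame, response, coords, times, subset,
                     kernel: str, h_grid, lam_grid
                     ) -> tuple[STKernelSpec, pd.DataFrame]:
    """AICc-minimising (h, lambda) grid search with golden-section
    refinement on h within the winning lambda column.

    Returns the chosen spec and the grid profile (h, lam, aicc); grid
    candidates whose AICc is undefined (tr(S) >= n - 2) are skipped.
    """
    h_grid = sorted(float(h) for h in h_grid)
    lam_grid = sorted(float(l) for l in lam_grid)
    if not h_grid or not lam_grid:
        raise ValueError("bandwidth grids must be non-empty")

    def score(h, lam):
        spec = STKernelSpec(kernel=kernel, h=h, lam=lam)
        fit = fit_gtwr(table, response, coords, times, subset, spec)
        return fit.diagnostics["aicc"]

    rows = []
    best = (math.inf, None, None)
    for lam in lam_grid:
        for h in h_grid:
            a = score(h, lam)
            rows.append({"h": h, "lam": lam, "aicc": a})
            if a < best[0]:
                best = (a, h, lam)
    if best[1] is None:
        raise ValueError("AICc undefined on the whole grid")
    _, h_star, lam_star = best
    # golden-section refinement between the grid neighbours of h_star
    idx = h_grid.index(h_star)
    lo = h_grid[max(idx - 1, 0)]
    hi = h_grid[min(idx + 1, len(h_grid) - 1)]
    if hi > lo:
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a, b = lo, hi
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc, fd = score(c, lam_star), score(d, lam_star)
        for _ in range(16):
            if fc < fd:
                b, d, fd = d, c, fc
                c = b - invphi * (b - a)
                fc = score(c, lam_star)
            else:
                a, c, fc = c, d, fd
                d = a + invphi * (b - a)
                fd = score(d, lam_star)
        h_ref = 0.5 * (a + b)
        if score(h_ref, lam_star) < best[0]:
            h_star = h_ref
    return (STKernelSpec(kernel=kernel, h=h_star, lam=lam_star),
            pd.DataFrame(rows))


def predict_surface(fit: GTWRFit, predictor_grids: dict, period_time: float,
                    nodata_from: str = "AOD") -> RasterGrid:
    """Apply local coefficients over aligned 10-m predictor grids.

    ``predictor_grids`` maps each subset variable to a RasterGrid; local
    coefficients at every valid cell are solved against the calibration
    observations at the cell's location and *period_time*.  Cells where
    the mandatory grid (default AOD) is nodata stay nodata.
    """
    missing = [v for v in fit.subset if v not in predictor_grids]
    if missing:
        raise ValueError(f"missing predictor grid(s): {missing}")
    ref = predictor_grids[fit.subset[0]]
    for name, g in predictor_grids.items():
        if not g.same_geometry(ref):
            raise ValueError(f"predictor grid {name} is not aligned")
    mask = np.ones(ref.values.shape, dtype=bool)
    if nodata_from in predictor_grids:
        mask &= predictor_grids[nodata_from].valid_mask
    Xg, Yg = ref.cell_centers()
    out = np.full(ref.values.shape, ref.nodata)
    rows, cols = np.nonzero(mask)
    # batch local solves over target cells
    cell_xy = np.column_stack([Xg[rows, cols], Yg[rows, cols]])
    P = np.column_stack(
        [np.ones(len(rows))] +
        [predictor_grids[v].values[rows, cols] for v in fit.subset])
    n, p = fit.X.shape
    preds = np.empty(len(rows))
    chunk = 2048
    for start in range(0, len(rows), chunk):
        sl = slice(start, min(start + chunk, len(rows)))
        cxy = cell_xy[sl]
        d2s = ((fit.coords[None, :, 0] - cxy[:, 0:1]) ** 2
               + (fit.coords[None, :, 1] - cxy[:, 1:2]) ** 2)
        d2t = (fit.times[None, :] - period_time) ** 2
        d2 = d2s + fit.spec.lam * d2t
        if fit.spec.kernel == "gaussian":
            W = np.exp(-d2 / fit.spec.h ** 2)
        else:
            W = np.where(d2 < fit.spec.h ** 2,
                         (1.0 - d2 / fit.spec.h ** 2) ** 2, 0.0)
        # XtWX per cell: (c, p, p); XtWy per cell: (c, p)
        XW = fit.X[None, :, :] * W[:, :, None]
        xtwx = np.einsum("np,cnq->cpq", fit.X, XW)
        xtwy = np.einsum("cnp,n->cp", XW, fit.y)
        xtwx += _RIDGE * np.eye(p)[None, :, :]
        beta = np.linalg.solve(xtwx, xtwy[:, :, None])[:, :, 0]
        preds[sl] = np.einsum("cp,cp->c", P[sl], beta)
    out[rows, cols] = preds
    return ref.with_values(out)
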