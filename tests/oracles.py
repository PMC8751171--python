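"""Independent brute-force oracles used by the test suite.

Deliberately simple, slow implementations kept free of the package's own
algorithmic code paths: dense Floyd–Warshall path counting for centrality,
Monte-Carlo hemisphere ray casting for the sky view factor, direct
fine-grid integration for the point-FAI, and closed-form solves for
ordinary kriging and OLS.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# Graph metrics by dense enumeration
# ---------------------------------------------------------------------------

def floyd_warshall(dist: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs shortest distances and shortest-path counts.

    *dist* is a dense matrix with np.inf for absent edges and 0 diagonal.
    Returns (d, counts).
    """
    n = dist.shape[0]
    d = dist.copy()
    cnt = np.where(np.isfinite(dist) & (dist > 0), 1.0, 0.0)
    np.fill_diagonal(cnt, 1.0)
    for k in range(n):
        for i in range(n):
            if i == k:
                continue
            for j in range(n):
                if j == k or j == i:
                    continue
                alt = d[i, k] + d[k, j]
                if alt < d[i, j] - 1e-12:
                    d[i, j] = alt
                    cnt[i, j] = cnt[i, k] * cnt[k, j]
                elif abs(alt - d[i, j]) <= 1e-12 and np.isfinite(alt):
                    cnt[i, j] += cnt[i, k] * cnt[k, j]
    return d, cnt


def brute_betweenness(dist: np.ndarray) -> np.ndarray:
    """Normalized shortest-path betweenness from a dense weight matrix."""
    n = dist.shape[0]
    d, cnt = floyd_warshall(dist)
    btw = np.zeros(n)
    for s in range(n):
        for t in range(n):
            if s >= t or not np.isfinite(d[s, t]) or cnt[s, t] == 0:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                if abs(d[s, v] + d[v, t] - d[s, t]) <= 1e-12:
                    btw[v] += cnt[s, v] * cnt[v, t] / cnt[s, t]
    norm = (n - 1) * (n - 2) / 2.0
    return btw / norm if norm > 0 else btw


def brute_closeness(dist: np.ndarray) -> np.ndarray:
    """(N−1)/Σd closeness per node within its component."""
    n = dist.shape[0]
    d, _ = floyd_warshall(dist)
    out = np.zeros(n)
    for i in range(n):
        reach = np.isfinite(d[i]) & (np.arange(n) != i)
        total = d[i, reach].sum()
        out[i] = reach.sum() / total if total > 0 else 0.0
    return out


def brute_mean_depth(adj: np.ndarray) -> np.ndarray:
    """Mean topological depth per node (BFS on an adjacency matrix)."""
    dist = np.where(adj > 0, 1.0, np.inf).astype(float)
    np.fill_diagonal(dist, 0.0)
    d, _ = floyd_warshall(dist)
    n = adj.shape[0]
    out = np.full(n, np.nan)
    for i in range(n):
        reach = np.isfinite(d[i]) & (np.arange(n) != i)
        if reach.sum() > 0:
            out[i] = d[i, reach].mean()
    return out


# ---------------------------------------------------------------------------
# Sky view factor by Monte-Carlo hemisphere ray casting
# ---------------------------------------------------------------------------

def mc_svf(dsm, point, n_rays: int = 100_000, max_dist: float = 100.0,
           seed: int = 0) -> float:
    """View-factor SVF: fraction of cosine-weighted sky directions whose
    ray clears the surface within *max_dist*."""
    rng = np.random.default_rng(seed)
    px, py = point
    z0 = float(dsm.sample(px, py))
    u = rng.random(n_rays)
    zenith = np.arcsin(np.sqrt(u))          # cosine-weighted solid angle
    azimuth = rng.random(n_rays) * 2 * math.pi
    elev = math.pi / 2 - zenith
    tan_e = np.tan(elev)
    step = dsm.cell
    n_steps = int(max_dist / step)
    visible = np.ones(n_rays, dtype=bool)
    sin_a, cos_a = np.sin(azimuth), np.cos(azimuth)
    for s in range(1, n_steps + 1):
        t = s * step
        x = px + sin_a * t
        y = py + cos_a * t
        ok = np.asarray(dsm.contains(x, y))
        xs = np.where(ok, x, px)
        ys = np.where(ok, y, py)
        z = np.asarray(dsm.sample(xs, ys))
        blocked = ok & (z - z0 > t * tan_e + 1e-12)
        visible &= ~blocked
    return float(visible.mean())


# ---------------------------------------------------------------------------
# Point-FAI by direct fine-grid integration (rotation-based projections)
# ---------------------------------------------------------------------------

def fine_grid_point_fai(buildings, point, R: float = 200.0, c: float = 2.0,
                        step: float = 1.0, windrose_p=None) -> float:
    """Direct fine-grid integration: each building's wind-weighted frontal
    area (height x rotated-bounds width) spread uniformly over its
    footprint, decay-weighted cell by cell."""
    import shapely.affinity as aff
    from shapely.geometry import box

    if windrose_p is None:
        windrose_p = np.full(8, 0.125)
    px, py = point
    a_circle = math.pi * R ** 2
    total = 0.0
    n = int(math.ceil(2 * R / step))
    for footprint, height in buildings:
        af = 0.0
        for k in range(8):
            if windrose_p[k] == 0:
                continue
            rot = aff.rotate(footprint, 45.0 * k, origin=(0, 0))
            minx, _, maxx, _ = rot.bounds
            af += windrose_p[k] * height * (maxx - minx)
        fp_area = footprint.area
        for i in range(n):
            for j in range(n):
                cx = px - R + (i + 0.5) * step
                cy = py - R + (j + 0.5) * step
                l = math.hypot(cx - px, cy - py)
                if l > R:
                    continue
                cell = box(px - R + i * step, py - R + j * step,
                           px - R + (i + 1) * step, py - R + (j + 1) * step)
                part = footprint.intersection(cell)
                if part.is_empty or part.area <= 0:
                    continue
                total += ((R - l) / R) ** c * af * part.area / fp_area
    return total / a_circle


def silhouette_frontal_area(buildings, k: int, resolution: float = 0.05
                            ) -> float:
    """Rasterized silhouette area along direction k: project footprints
    onto the width axis at fine resolution and integrate max height."""
    az = math.radians(45.0 * k)
    ux, uy = -math.cos(az), math.sin(az)
    spans = []
    for fp, h in buildings:
        coords = np.asarray(fp.exterior.coords)
        proj = coords[:, 0] * ux + coords[:, 1] * uy
        spans.append((proj.min(), proj.max(), h))
    if not spans:
        return 0.0
    lo = min(s[0] for s in spans)
    hi = max(s[1] for s in spans)
    xs = np.arange(lo + resolution / 2, hi, resolution)
    hmax = np.zeros_like(xs)
    for a, b, h in spans:
        sel = (xs >= a) & (xs <= b)
        hmax[sel] = np.maximum(hmax[sel], h)
    return float(hmax.sum() * resolution)


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def ols_coefficients(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Global OLS with intercept via lstsq."""
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return beta


def ok_system_predict(coords, values, target, sill, rng_m):
    """Ordinary-kriging prediction by directly assembling and solving the
    semivariogram system."""
    coords = np.asarray(coords, float)
    n = len(values)
    def gamma(h):
        return sill * (1.0 - np.exp(-3.0 * h / rng_m))
    A = np.zeros((n + 1, n + 1))
    for i in range(n):
        for j in range(n):
            A[i, j] = gamma(np.hypot(*(coords[i] - coords[j])))
        A[i, n] = 1.0
        A[n, i] = 1.0
    b = np.zeros(n + 1)
    for i in range(n):
        b[i] = gamma(np.hypot(*(coords[i] - np.asarray(target))))
    b[n] = 1.0
    lam = np.linalg.solve(A, b)
    return float(lam[:n] @ np.asarray(values, float))


def aicc_reference(rss: float, n: int, k: float) -> float:
    """Independent rewrite of the corrected AIC used for GWR models."""
    return n * (math.log(2 * math.pi * rss / n)) \
        + n * ((n + k) / (n - 2 - k))
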