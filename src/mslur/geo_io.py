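"""Gridded and vector geodata containers and plain-text I/O.

All geometry lives in a single projected metric CRS.  Geographic (degree)
inputs are rejected rather than reprojected, because buffer areas and line
densities in metres are central to every predictor in the pipeline.

Raster convention used by every module
--------------------------------------
Row 0 is the northern edge; values are located at cell centers; extents are
half-open, ``[x0, x0 + ncols*cell) x (y0 - nrows*cell, y0]`` with ``(x0, y0)``
the north-west *corner*.  World coordinate ``(x, y)`` maps to
``col = floor((x - x0)/cell)``, ``row = floor((y0 - y)/cell)``.

Rasters are stored as ESRI ASCII grids (plain text) with a small JSON sidecar
(``<path>.meta.json``) carrying the CRS id and exact nodata value; vectors as
GeoJSON with coordinates in metres.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import networkx as nx
import numpy as np
import yaml
from shapely.geometry import LineString, Point, mapping, shape

__all__ = [
    "RasterGrid",
    "RoadGraph",
    "PipelineConfig",
    "ROAD_CLASSES",
    "read_raster",
    "write_raster",
    "read_vector",
    "write_vector",
    "require_projected",
]

#: Road classes in decreasing hierarchy, as used for per-class line densities.
ROAD_CLASSES = ("trunk", "primary", "secondary", "tertiary", "ordinary")

#: CRS ids accepted as projected & metric.  "LOCAL" is the synthetic city's
#: own Cartesian metre frame.
_GEOGRAPHIC_CRS = {"EPSG:4326", "OGC:CRS84", "WGS84", "CRS84"}


def require_projected(crs: str) -> str:
    """Validate that *crs* is a projected metric CRS id; return it.

    Raises ``ValueError`` with a "projected CRS required" message for known
    geographic identifiers.  Unknown ids are accepted on trust: the pipeline
    cannot reproject, so the contract is simply that coordinates are metres.
    """
    if crs is None or str(crs).strip().upper() in _GEOGRAPHIC_CRS:
        raise ValueError(
            f"projected CRS required, got geographic CRS {crs!r}; "
            "reproject inputs to a metric CRS before use"
        )
    return str(crs)


@dataclass
class RasterGrid:
    """A single-band raster in a projected metric CRS.

    ``x0, y0`` are the coordinates of the north-west corner, ``cell`` the
    square cell size in metres.
    """

    values: np.ndarray
    x0: float
    y0: float
    cell: float
    crs: str = "LOCAL"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell <= 0:
            raise ValueError("cell size must be > 0")
        require_projected(self.crs)

    # -- geometry -----------------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the half-open extent."""
        return (
            self.x0,
            self.y0 - self.nrows * self.cell,
            self.x0 + self.ncols * self.cell,
            self.y0,
        )

    def same_geometry(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.x0 - other.x0) <= tol
            and abs(self.y0 - other.y0) <= tol
            and abs(self.cell - other.cell) <= tol
            and self.crs == other.crs
        )

    def xy_to_rc(self, x, y):
        """World coordinates -> (row, col) under the cell-center convention."""
        col = np.floor((np.asarray(x) - self.x0) / self.cell).astype(int)
        row = np.floor((self.y0 - np.asarray(y)) / self.cell).astype(int)
        return row, col

    def rc_to_xy(self, row, col):
        """(row, col) -> cell-center world coordinates."""
        x = self.x0 + (np.asarray(col) + 0.5) * self.cell
        y = self.y0 - (np.asarray(row) + 0.5) * self.cell
        return x, y

    def cell_centers(self):
        """Meshgrid arrays (X, Y) of all cell-center coordinates."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x0 + (cols + 0.5) * self.cell
        y = self.y0 - (rows + 0.5) * self.cell
        return np.meshgrid(x, y)

    def contains(self, x, y):
        xmin, ymin, xmax, ymax = self.bounds
        x = np.asarray(x)
        y = np.asarray(y)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    def sample(self, x, y):
        """Nearest-cell lookup of world coordinates (scalar or array)."""
        row, col = self.xy_to_rc(x, y)
        return self.values[row, col]

    # -- values -------------------------------------------------------------
    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isclose(self.values, self.nodata) & ~np.isnan(self.values)

    def with_values(self, values: np.ndarray) -> "RasterGrid":
        return replace(self, values=np.asarray(values, dtype=float))


class RoadGraph:
    """An undirected road network with polyline edge geometry.

    Thin wrapper over ``networkx.Graph``: nodes carry ``x, y`` (metres),
    edges carry ``edge_id``, ``road_class`` (one of :data:`ROAD_CLASSES`),
    ``geometry`` (shapely ``LineString``) and ``length`` (metres).
    """

    SNAP_TOL = 1e-6  # endpoints closer than this collapse to one node

    def __init__(self, crs: str = "LOCAL"):
        self.crs = require_projected(crs)
        self.graph = nx.Graph()
        self._node_index: dict[tuple[float, float], int] = {}

    def _node_for(self, x: float, y: float) -> int:
        key = (round(x / self.SNAP_TOL) * self.SNAP_TOL,
               round(y / self.SNAP_TOL) * self.SNAP_TOL)
        if key not in self._node_index:
            nid = len(self._node_index)
            self._node_index[key] = nid
            self.graph.add_node(nid, x=float(x), y=float(y))
        return self._node_index[key]

    def add_edge(self, geometry: LineString, road_class: str,
                 edge_id: int | None = None) -> int:
        if road_class not in ROAD_CLASSES:
            raise ValueError(f"unknown road class {road_class!r}")
        if geometry.length <= 0:
            raise ValueError("zero-length road segment")
        (x0, y0) = geometry.coords[0]
        (x1, y1) = geometry.coords[-1]
        u = self._node_for(x0, y0)
        v = self._node_for(x1, y1)
        if edge_id is None:
            edge_id = self.graph.number_of_edges()
        self.graph.add_edge(
            u, v, edge_id=edge_id, road_class=road_class,
            geometry=geometry, length=float(geometry.length),
        )
        return edge_id

    def segments(self) -> list[dict]:
        """Edge records sorted by edge_id."""
        recs = []
        for u, v, data in self.graph.edges(data=True):
            recs.append({"u": u, "v": v, **data})
        return sorted(recs, key=lambda r: r["edge_id"])

    def node_xy(self, nid: int) -> tuple[float, float]:
        d = self.graph.nodes[nid]
        return d["x"], d["y"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def total_length(self) -> float:
        return sum(d["length"] for _, _, d in self.graph.edges(data=True))


@dataclass
class PipelineConfig:
    """Run configuration shared by all pipeline stages.

    ``buffer_radii`` defaults to the standard ten-radius series used for
    every buffered spatial predictor.  ``lambda_grid`` scales squared
    temporal distance (days²) into squared metres for the space-time kernel.
    """

    seed: int = 0
    buffer_radii: tuple[float, ...] = (
        50, 100, 200, 300, 400, 500, 750, 1000, 1500, 2000)
    cell_size: float = 10.0
    seasons: tuple[str, ...] = ("spring", "summer", "fall", "winter")
    kernel: str = "gaussian"
    h_grid: tuple[float, ...] = (500.0, 1000.0, 2000.0, 4000.0, 8000.0)
    lambda_grid: tuple[float, ...] = (0.0, 1e4, 1e6)
    extent: float = 2400.0  # side length of the synthetic study square, m
    aod_cell: float = 300.0  # synthetic stand-in for the 1-km AOD pixel
    crs: str = "LOCAL"

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.buffer_radii)
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("buffer_radii must be strictly increasing")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.kernel not in ("gaussian", "bisquare"):
            raise ValueError(f"unknown kernel {self.kernel!r}")
        self.buffer_radii = radii
        require_projected(self.crs)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        for key in ("buffer_radii", "seasons", "h_grid", "lambda_grid"):
            if key in data and isinstance(data[key], list):
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "buffer_radii": list(self.buffer_radii),
            "cell_size": self.cell_size,
            "seasons": list(self.seasons),
            "kernel": self.kernel,
            "h_grid": list(self.h_grid),
            "lambda_grid": list(self.lambda_grid),
            "extent": self.extent,
            "aod_cell": self.aod_cell,
            "crs": self.crs,
        }


# ---------------------------------------------------------------------------
# Raster I/O: ESRI ASCII grid + JSON sidecar (crs, exact nodata)
# ---------------------------------------------------------------------------

def write_raster(grid: RasterGrid, path: str | Path) -> Path:
    """Write *grid* as an ESRI ASCII grid with a JSON metadata sidecar."""
    path = Path(path)
    vals = np.where(np.isnan(grid.values), grid.nodata, grid.values)
    xmin, ymin, _, _ = grid.bounds
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {xmin!r}\n"
        f"yllcorner {ymin!r}\n"
        f"cellsize {grid.cell!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    sidecar = {"crs": grid.crs, "nodata": grid.nodata}
    Path(str(path) + ".meta.json").write_text(json.dumps(sidecar))
    return path

def read_raster(path: str | Path) -> RasterGrid:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = val
        values = np.loadtxt(fh, dtype=float)
    values = np.atleast_2d(values)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if values.shape != (nrows, ncols):
        raise ValueError(
            f"raster body shape {values.shape} != header ({nrows}, {ncols})")
    cell = float(header["cellsize"])
    nodata = float(header["nodata_value"])
    crs = "LOCAL"
    side = Path(str(path) + ".meta.json")
    if side.exists():
        meta = json.loads(side.read_text())
        crs = meta.get("crs", crs)
        nodata = meta.get("nodata", nodata)
    return RasterGrid(
        values=values,
        x0=float(header["xllcorner"]),
        y0=float(header["yllcorner"]) + nrows * cell,
        cell=cell,
        crs=require_projected(crs),
        nodata=nodata,
    )


# ---------------------------------------------------------------------------
# Vector I/O: GeoJSON in a projected CRS
# ---------------------------------------------------------------------------

def _check_geojson_crs(obj: dict) -> str:
    crs = obj.get("crs", "LOCAL")
    if isinstance(crs, dict):  # legacy named-CRS member
        crs = crs.get("properties", {}).get("name", "LOCAL")
    return require_projected(crs)


def write_vector(obj, path: str | Path, crs: str | None = None) -> Path:
    """Write a :class:`RoadGraph` or a list of point records to GeoJSON."""
    path = Path(path)
    if isinstance(obj, RoadGraph):
        crs = crs or obj.crs
        features = [
            {
                "type": "Feature",
                "id": rec["edge_id"],
                "properties": {"road_class": rec["road_class"]},
                "geometry": mapping(rec["geometry"]),
            }
            for rec in obj.segments()
        ]
    else:  # iterable of dicts with x, y + attributes
        crs = crs or "LOCAL"
        features = []
        for i, rec in enumerate(obj):
            props = {k: v for k, v in rec.items() if k not in ("x", "y")}
            features.append({
                "type": "Feature",
                "id": i,
                "properties": props,
                "geometry": mapping(Point(rec["x"], rec["y"])),
            })
    doc = {"type": "FeatureCollection", "crs": crs, "features": features}
    path.write_text(json.dumps(doc))
    return path


def read_vector(path: str | Path):
    """Read GeoJSON into a :class:`RoadGraph` (linestrings) or point list.

    Line features require a ``road_class`` property; a missing one raises an
    error naming the offending feature id.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    doc = json.loads(path.read_text())
    crs = _check_geojson_crs(doc)
    features = doc.get("features", [])
    if not features:
        warnings.warn(f"{path}: empty feature collection")
        return RoadGraph(crs=crs)
    geom_types = {f["geometry"]["type"] for f in features}
    if geom_types <= {"LineString", "MultiLineString"}:
        rg = RoadGraph(crs=crs)
        for f in features:
            fid = f.get("id")
            props = f.get("properties") or {}
            if "road_class" not in props:
                raise ValueError(
                    f"feature {fid!r} is missing the road_class attribute")
            geom = shape(f["geometry"])
            lines = [geom] if isinstance(geom, LineString) else list(geom.geoms)
            for line in lines:
                rg.add_edge(line, props["road_class"],
                            edge_id=fid if len(lines) == 1 else None)
        return rg
    points = []
    for f in features:
        geom = shape(f["geometry"])
        rec = {"x": geom.x, "y": geom.y}
        rec.update(f.get("properties") or {})
        points.append(rec)
    return points
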