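"""Planar raster grids and light-weight vector I/O.

All spatial data live in a single planar metric frame (meters, no
geographic projection): rasters are row-major arrays whose row 0 is the
northernmost row, anchored by the x/y of the upper-left *corner*; vector
features are shapely geometries in the same frame.  Rasters are stored as
ESRI ASCII grid text files, vectors as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import shapely
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape

__all__ = [
    "Grid",
    "CovariateStack",
    "read_ascii_grid",
    "write_ascii_grid",
    "read_geojson",
    "write_geojson",
]


@dataclass
class Grid:
    """A single-band planar raster.

    Parameters
    ----------
    values : ndarray (nrows, ncols)
        Cell values; NaN marks nodata for float grids.
    origin : (float, float)
        (x, y) of the upper-left corner in meters.
    cell_size : float
        Cell edge length in meters (> 0), square cells.
    nodata : float
        Marker written to disk for NaN cells.
    """

    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 30.0
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("grid values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- frame helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent_m(self) -> tuple[float, float]:
        """(width, height) of the raster in meters."""
        return (self.ncols * self.cell_size, self.nrows * self.cell_size)

    def x_coords(self) -> np.ndarray:
        """East coordinates of cell centers, one per column."""
        x0 = self.origin[0]
        return x0 + (np.arange(self.ncols) + 0.5) * self.cell_size

    def y_coords(self) -> np.ndarray:
        """North coordinates of cell centers, one per row (descending)."""
        y0 = self.origin[1]
        return y0 - (np.arange(self.nrows) + 0.5) * self.cell_size

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid (X, Y) of all cell centers."""
        return np.meshgrid(self.x_coords(), self.y_coords())

    def world_to_cell(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map world coordinates to (row, col) indices.

        Membership uses the half-open convention: a point on the shared
        edge of two cells belongs to the cell with the larger index on x
        and the larger row (more southern) on y.
        """
        col = np.floor((np.asarray(x) - self.origin[0]) / self.cell_size).astype(int)
        row = np.floor((self.origin[1] - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        row, col = self.world_to_cell(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def sample(self, x, y) -> np.ndarray:
        """Nearest-cell values at world coordinates (NaN outside)."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        row, col = self.world_to_cell(x, y)
        ok = (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)
        out = np.full(x.shape, np.nan)
        out[ok] = self.values[row[ok], col[ok]]
        return out

    def like(self, values: np.ndarray) -> "Grid":
        """A new grid sharing this grid's frame."""
        values = np.asarray(values)
        if values.shape != self.shape:
            raise ValueError("shape mismatch with template grid")
        return Grid(values, self.origin, self.cell_size, self.nodata)

    def same_frame(self, other: "Grid", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.cell_size - other.cell_size) <= atol
            and abs(self.origin[0] - other.origin[0]) <= atol
            and abs(self.origin[1] - other.origin[1]) <= atol
        )

    @property
    def cell_area_km2(self) -> float:
        return self.cell_size**2 / 1e6


def write_ascii_grid(grid: Grid, path: str | Path) -> None:
    """Write a grid as an ESRI ASCII raster (text)."""
    path = Path(path)
    vals = np.asarray(grid.values, dtype=float).copy()
    vals[~np.isfinite(vals)] = grid.nodata
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin[0]:.6f}\n"
        f"yllcorner {grid.origin[1] - grid.nrows * grid.cell_size:.6f}\n"
        f"cellsize {grid.cell_size:.6f}\n"
        f"NODATA_value {grid.nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.6f")


def read_ascii_grid(path: str | Path) -> Grid:
    """Read an ESRI ASCII raster; nodata cells become NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, _, val = line.partition(" ")
            key = key.strip().lower()
            if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                       "nodata_value"}:
                header[key] = float(val)
                pos = fh.tell()
            else:  # optional NODATA line absent
                break
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    if vals.shape != (nrows, ncols):
        raise ValueError(f"raster body {vals.shape} disagrees with header")
    cell = header["cellsize"]
    origin = (header["xllcorner"], header["yllcorner"] + nrows * cell)
    nodata = header.get("nodata_value", -9999.0)
    vals[vals == nodata] = np.nan
    return Grid(vals, origin, cell, nodata)


def write_geojson(geometries: Iterable, path: str | Path,
                  properties: Sequence[Mapping] | None = None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection."""
    geometries = list(geometries)
    if properties is None:
        properties = [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": geom_mapping(g), "properties": dict(p)}
        for g, p in zip(geometries, properties, strict=True)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path) -> tuple[list, list[dict]]:
    """Read a GeoJSON FeatureCollection -> (geometries, properties)."""
    with open(path) as fh:
        doc = json.load(fh)
    geoms = [geom_shape(f["geometry"]) for f in doc["features"]]
    props = [f.get("properties") or {} for f in doc["features"]]
    return geoms, props


@dataclass
class CovariateStack:
    """Named co-registered covariate grids used by the selection model.

    The canonical layer names are ``elevation``, ``slope_deg``, ``tri_m``,
    ``aspect_deg``, ``south_deviation_deg``, ``ndvi``, ``dist_cliff_m``,
    ``dist_stream_m``, ``dist_settlement_m``, ``dist_trail_m`` and
    ``livestock_presence`` (0/1), but any mapping of names to grids on a
    shared frame is accepted.
    """

    grids: dict[str, Grid] = field(default_factory=dict)

    def __post_init__(self) -> None:
        grids = dict(self.grids)
        if grids:
            ref = next(iter(grids.values()))
            for name, g in grids.items():
                if not ref.same_frame(g):
                    raise ValueError(f"layer {name!r} is not co-registered")
        self.grids = grids

    @property
    def names(self) -> list[str]:
        return list(self.grids)

    @property
    def template(self) -> Grid:
        if not self.grids:
            raise ValueError("empty covariate stack")
        return next(iter(self.grids.values()))

    def __getitem__(self, name: str) -> Grid:
        return self.grids[name]

    def __contains__(self, name: str) -> bool:
        return name in self.grids

    def add(self, name: str, grid: Grid) -> None:
        if self.grids and not self.template.same_frame(grid):
            raise ValueError(f"layer {name!r} is not co-registered")
        self.grids[name] = grid

    def sample(self, x, y) -> "dict[str, np.ndarray]":
        return {name: g.sample(x, y) for name, g in self.grids.items()}

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, g in self.grids.items():
            write_ascii_grid(g, directory / f"{name}.asc")

    @classmethod
    def load(cls, directory: str | Path) -> "CovariateStack":
        directory = Path(directory)
        grids = {p.stem: read_ascii_grid(p) for p in sorted(directory.glob("*.asc"))}
        if not grids:
            raise FileNotFoundError(f"no .asc rasters under {directory}")
        return cls(grids)
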