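"""Regular raster grids and plain-text geospatial I/O.

All rasters in the package live on a :class:`GridSpec`: a regular grid in a
projected metric CRS, row 0 at the northern edge, square cells, values
referring to whole cells, and point-in-cell sampling at cell centres.
Rasters are plain ``numpy`` arrays (``float`` layers use NaN as nodata);
they are serialised as ESRI ASCII grids (.asc), vectors as GeoJSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """A regular raster grid in a projected metric CRS.

    ``origin_x``/``origin_y`` are the coordinates of the *top-left corner*
    of the grid (north-west), so ``origin_y`` is the maximum y. ``crs_label``
    is an opaque identifier; no reprojection is performed anywhere.
    """

    origin_x: float
    origin_y: float
    cell_size: float
    n_rows: int
    n_cols: int
    crs_label: str = "local-metric"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(minx, miny, maxx, maxy) of the grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.cell_size,
            self.origin_x + self.n_cols * self.cell_size,
            self.origin_y,
        )

    @property
    def bounds_polygon(self) -> BaseGeometry:
        return shapely.box(*self.bounds)

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def x_centers(self) -> np.ndarray:
        return self.origin_x + (np.arange(self.n_cols) + 0.5) * self.cell_size

    def y_centers(self) -> np.ndarray:
        """Cell-centre y coordinates, row 0 first (north to south)."""
        return self.origin_y - (np.arange(self.n_rows) + 0.5) * self.cell_size

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) holding cell centres."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def point_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices.

        Cells are half-open: a point on a shared edge belongs to the cell
        to its right / below, making assignment deterministic.
        """
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((self.origin_y - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def contains_points(self, x, y) -> np.ndarray:
        row, col = self.point_to_rowcol(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def snap_to_centers(self, x, y, cell_size: float | None = None):
        """Snap points to the centres of the (sub)grid anchored at the origin.

        Used to emulate satellite detections reported at sensor-grid cell
        centres; ``cell_size`` defaults to this grid's own resolution.
        """
        cs = self.cell_size if cell_size is None else cell_size
        col = np.floor((np.asarray(x) - self.origin_x) / cs)
        row = np.floor((self.origin_y - np.asarray(y)) / cs)
        return self.origin_x + (col + 0.5) * cs, self.origin_y - (row + 0.5) * cs

    def coarsen(self, factor: int) -> "GridSpec":
        """A grid with ``factor``-times larger cells over the same origin."""
        if factor < 1:
            raise ValueError("factor must be >= 1")
        return GridSpec(
            self.origin_x,
            self.origin_y,
            self.cell_size * factor,
            max(1, self.n_rows // factor),
            max(1, self.n_cols // factor),
            self.crs_label,
        )


def check_same_grid(*grids: GridSpec) -> None:
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise ValueError(f"grids are not aligned: {g} != {first}")


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O (plain-text raster interchange)
# ---------------------------------------------------------------------------

def write_ascii_grid(path: str | Path, values: np.ndarray, grid: GridSpec,
                     nodata: float = NODATA) -> None:
    values = np.asarray(values, dtype=float)
    if values.shape != grid.shape:
        raise ValueError("raster shape does not match grid")
    out = np.where(np.isnan(values), nodata, values)
    minx, miny, _, _ = grid.bounds
    header = (
        f"ncols {grid.n_cols}\n"
        f"nrows {grid.n_rows}\n"
        f"xllcorner {minx}\n"
        f"yllcorner {miny}\n"
        f"cellsize {grid.cell_size}\n"
        f"NODATA_value {nodata}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.6g")


def read_ascii_grid(path: str | Path,
                    crs_label: str = "local-metric") -> tuple[np.ndarray, GridSpec]:
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    values = values.reshape(n_rows, n_cols)
    cs = header["cellsize"]
    grid = GridSpec(
        origin_x=header["xllcorner"],
        origin_y=header["yllcorner"] + n_rows * cs,
        cell_size=cs,
        n_rows=n_rows,
        n_cols=n_cols,
        crs_label=crs_label,
    )
    values[values == header["nodata_value"]] = np.nan
    return values, grid


# ---------------------------------------------------------------------------
# GeoJSON vector I/O
# ---------------------------------------------------------------------------

def write_geojson(path: str | Path, geometries, properties=None) -> None:
    properties = properties or [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path: str | Path) -> list[BaseGeometry]:
    with open(path) as fh:
        data = json.load(fh)
    return [shape(f["geometry"]) for f in data["features"]]
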