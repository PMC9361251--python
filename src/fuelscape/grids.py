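"""Raster grid specification and plain-text spatial I/O.

Rasters are stored as (GridSpec, 2-D ndarray) pairs with row 0 at the
northern edge, matching the usual raster convention.  On disk they are
ESRI ASCII grids (``.asc``), a text format readable by every GIS.
Vector fire perimeters are GeoJSON, read and written with shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import mapping, shape

NODATA = -9999.0


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a north-up raster grid in a projected CRS (meters).

    Parameters
    ----------
    xmin, ymax : float
        Coordinates of the outer corner of the top-left cell.
    cell : float
        Cell size in meters (cells are square).
    nrows, ncols : int
        Grid dimensions; ``array[0, 0]`` is the north-west cell.
    crs : str
        Free-form CRS tag carried through for provenance.
    """

    xmin: float
    ymax: float
    cell: float
    nrows: int
    ncols: int
    crs: str = "local-projected"

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.nrows <= 0 or self.ncols <= 0:
            raise ValueError("grid dimensions must be positive")

    @property
    def ymin(self) -> float:
        return self.ymax - self.nrows * self.cell

    @property
    def xmax(self) -> float:
        return self.xmin + self.ncols * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nrows, self.ncols)

    @property
    def cell_area_ha(self) -> float:
        """Cell area in hectares (0.04 ha for the standard 20-m grid)."""
        return self.cell * self.cell / 1e4

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (X, Y) arrays of cell-center coordinates, shape (nrows, ncols)."""
        x = self.xmin + (np.arange(self.ncols) + 0.5) * self.cell
        y = self.ymax - (np.arange(self.nrows) + 0.5) * self.cell
        return np.meshgrid(x, y)

    def index_of(self, x, y):
        """Row/col indices of the cells containing points (x, y).

        Cells are half-open: ``xmin + j*cell <= x < xmin + (j+1)*cell``.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xmin) / self.cell).astype(int)
        row = np.floor((self.ymax - y) / self.cell).astype(int)
        return row, col

    def contains(self, x, y):
        row, col = self.index_of(x, y)
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def aligned_like(self, other: "GridSpec") -> bool:
        return (
            self.xmin == other.xmin
            and self.ymax == other.ymax
            and self.cell == other.cell
            and self.shape == other.shape
        )

    @staticmethod
    def snapped(xmin: float, ymax: float, cell: float, nrows: int, ncols: int,
                crs: str = "local-projected") -> "GridSpec":
        """Grid spec with origin snapped outward to multiples of the cell size."""
        x0 = np.floor(xmin / cell) * cell
        y0 = np.ceil(ymax / cell) * cell
        return GridSpec(x0, y0, cell, nrows, ncols, crs)


def require_aligned(a: GridSpec, b: GridSpec, what: str = "grids") -> None:
    if not a.aligned_like(b):
        raise ValueError(f"{what} are not aligned: {a} vs {b}")


def write_ascii_grid(path, spec: GridSpec, array: np.ndarray, nodata: float = NODATA) -> None:
    """Write a 2-D array as an ESRI ASCII grid; NaN cells become *nodata*."""
    arr = np.asarray(array, dtype=float)
    if arr.shape != spec.shape:
        raise ValueError(f"array shape {arr.shape} != grid shape {spec.shape}")
    out = np.where(np.isnan(arr), nodata, arr)
    header = (
        f"ncols {spec.ncols}\n"
        f"nrows {spec.nrows}\n"
        f"xllcorner {spec.xmin!r}\n"
        f"yllcorner {spec.ymin!r}\n"
        f"cellsize {spec.cell!r}\n"
        f"NODATA_value {nodata!r}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, out, fmt="%.8g")


def read_ascii_grid(path, crs: str = "local-projected") -> tuple[GridSpec, np.ndarray]:
    """Read an ESRI ASCII grid; nodata cells come back as NaN."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh)
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    data = data.reshape(nrows, ncols)
    spec = GridSpec(
        xmin=header["xllcorner"],
        ymax=header["yllcorner"] + nrows * header["cellsize"],
        cell=header["cellsize"],
        nrows=nrows,
        ncols=ncols,
        crs=crs,
    )
    nodata = header.get("nodata_value", NODATA)
    data = np.where(data == nodata, np.nan, data)
    return spec, data


def write_multilayer(path_prefix, spec: GridSpec, layers: dict) -> list[str]:
    """Write a dict of named layers as ``<prefix>.<name>.asc`` files."""
    paths = []
    for name, arr in layers.items():
        p = f"{path_prefix}.{name}.asc"
        write_ascii_grid(p, spec, arr)
        paths.append(p)
    return paths


def write_geojson(path, geometries, properties=None) -> None:
    """Write shapely geometries (+ parallel list of property dicts) as GeoJSON."""
    properties = properties or [{} for _ in geometries]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": p}
        for g, p in zip(geometries, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path) -> tuple[list, list[dict]]:
    """Read a GeoJSON FeatureCollection into (shapely geometries, property dicts)."""
    with open(path) as fh:
        fc = json.load(fh)
    geoms = [shape(f["geometry"]) for f in fc["features"]]
    props = [f.get("properties") or {} for f in fc["features"]]
    return geoms, props
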