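"""Rasterize fire perimeter polygons into fire-history grids.

Years-since-fire (YSF) and number-of-past-fires (NPF) are computed for a
reference year from perimeter polygons carrying a calendar year, using the
cell-center coverage rule: a cell belongs to a fire iff the perimeter
polygon covers the cell center.  A fire in the reference year itself counts
with YSF 0.  Never-burned cells have NPF 0 and missing (NaN) YSF; for model
features the documented finite fill is the record length plus one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry

from .grids import GridSpec, read_geojson, write_geojson

DEFAULT_RECORD_WINDOW = (1984, 2019)


@dataclass
class FireEvent:
    """One mapped fire: perimeter polygon, calendar year, optional severity
    (dNBR-like) raster aligned to the working grid."""

    polygon: BaseGeometry
    year: int
    severity: np.ndarray | None = None
    fire_id: str = ""

    def __post_init__(self) -> None:
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise ValueError("fire polygon must be non-empty and valid")


@dataclass
class FireHistoryGrids:
    """YSF/NPF rasters for one reference year.

    ``ysf`` is NaN where never burned within the record window; ``npf`` is
    the count of past fires covering the cell center.
    """

    spec: GridSpec
    ysf: np.ndarray
    npf: np.ndarray
    ref_year: int
    record_window: tuple[int, int] = DEFAULT_RECORD_WINDOW

    @property
    def record_length(self) -> int:
        return self.record_window[1] - self.record_window[0] + 1

    @property
    def never_burned_fill(self) -> float:
        """Finite YSF stand-in for never-burned cells ("at least this long")."""
        return float(self.ref_year - self.record_window[0] + 1)

    def ysf_filled(self) -> np.ndarray:
        return np.where(np.isnan(self.ysf), self.never_burned_fill, self.ysf)

    def burned_mask(self) -> np.ndarray:
        return self.npf >= 1


def rasterize_history(fires, spec: GridSpec, ref_year: int,
                      record_window: tuple[int, int] = DEFAULT_RECORD_WINDOW,
                      ) -> FireHistoryGrids:
    """Build YSF/NPF grids from fire events by cell-center coverage.

    Fires dated after *ref_year* or outside the record window are excluded
    with a warning.  YSF = ref_year - (most recent covering fire year);
    result is independent of the order of the fire list.
    """
    X, Y = spec.cell_centers()
    npf = np.zeros(spec.shape, dtype=int)
    last_year = np.full(spec.shape, -np.inf)
    for f in fires:
        if f.year > ref_year or not (record_window[0] <= f.year <= record_window[1]):
            warnings.warn(
                f"fire {f.fire_id or f.year} outside record window or after "
                f"reference year {ref_year}; excluded",
                stacklevel=2,
            )
            continue
        covered = shapely.contains_xy(f.polygon, X.ravel(), Y.ravel()).reshape(spec.shape)
        npf += covered
        last_year = np.where(covered, np.maximum(last_year, f.year), last_year)
    ysf = np.where(npf > 0, ref_year - last_year, np.nan)
    return FireHistoryGrids(spec=spec, ysf=ysf, npf=npf, ref_year=ref_year,
                            record_window=record_window)


def extract_at_points(grids: FireHistoryGrids, x, y, fill_never_burned: bool = True):
    """Nearest-cell YSF/NPF at plot coordinates.

    Returns (ysf, npf) arrays; with *fill_never_burned* the finite fill
    replaces NaN YSF so the values are model-ready.
    """
    x = np.atleast_1d(np.asarray(x, float))
    y = np.atleast_1d(np.asarray(y, float))
    row, col = grids.spec.index_of(x, y)
    bad = (row < 0) | (row >= grids.spec.nrows) | (col < 0) | (col >= grids.spec.ncols)
    if bad.any():
        raise ValueError(f"points outside grid at indices {np.where(bad)[0].tolist()}")
    ysf = (grids.ysf_filled() if fill_never_burned else grids.ysf)[row, col]
    npf = grids.npf[row, col]
    return ysf, npf


def fires_to_geojson(path, fires) -> None:
    write_geojson(
        path,
        [f.polygon for f in fires],
        [{"year": int(f.year), "fire_id": f.fire_id} for f in fires],
    )


def fires_from_geojson(path) -> list[FireEvent]:
    geoms, props = read_geojson(path)
    return [
        FireEvent(polygon=g, year=int(p["year"]), fire_id=str(p.get("fire_id", "")))
        for g, p in zip(geoms, props)
    ]
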