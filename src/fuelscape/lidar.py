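"""Height normalization and strata metrics for airborne lidar point clouds.

The metric vocabulary follows the standard canopy/understory convention:
nonground returns are > 0 m above ground, canopy returns > 2 m, understory
returns strictly between 0 and 2 m.  A return at exactly 2 m is assigned to
the canopy stratum (documented boundary decision — the strict definitions
would leave it in neither stratum and silently drop it).

Metrics per stratum: MAX, AVG, STD (n-1 denominator), SKE (m3/m2^1.5,
bias-uncorrected sample moments), KUR (m4/m2^2, not excess), and order
percentiles P05..P95 with linear interpolation at rank p*(n-1)/100 + 1
(numpy's default "linear" rule).  Density metrics D00..D07 are percentages
of nonground returns in height bands [0,0.5), [0.5,1), [1,2), [2,4),
[4,8), [8,16), [16,32), [32,48); D00.lt2..D04.lt2 are percentages of
understory returns in [0,0.05), [0.05,0.15), [0.15,0.5), [0.5,1), [1,2).
Undefined statistics (empty stratum, n too small for a moment) are NaN at
this layer; grid/feature assembly applies the documented zero-fill with an
"empty" mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.stats import kurtosis, skew

from .grids import GridSpec

GROUND_CLASS = 2

PERCENTILE_PROBS = (5, 10, 25, 50, 75, 90, 95)

NONGROUND_BANDS = (0.0, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0, 32.0, 48.0)
UNDERSTORY_BANDS = (0.0, 0.05, 0.15, 0.5, 1.0, 2.0)

_STAT_NAMES = ("MAX", "AVG", "STD", "SKE", "KUR") + tuple(
    f"P{p:02d}" for p in PERCENTILE_PROBS
)

#: Names of all strata metrics, in canonical order.
METRIC_NAMES = (
    tuple(f"{s}.gt2" for s in _STAT_NAMES)
    + tuple(f"{s}.lt2" for s in _STAT_NAMES)
    + tuple(f"D{i:02d}" for i in range(8))
    + tuple(f"D{i:02d}.lt2" for i in range(5))
)


@dataclass
class NormalizedCloud:
    """Classified lidar returns with heights above ground.

    ``height`` is z minus the interpolated ground elevation; ground returns
    have height ~0 at exact terrain nodes.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    height: np.ndarray
    classification: np.ndarray  # GROUND_CLASS = ground, anything else nonground

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "z", "height", "classification"):
            if len(getattr(self, name)) != n:
                raise ValueError("cloud arrays must have equal length")
        if not np.all(np.isfinite(self.height)):
            raise ValueError("heights must be finite")

    def __len__(self) -> int:
        return len(self.x)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.x,
                "y": self.y,
                "z": self.z,
                "height": self.height,
                "classification": self.classification,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "NormalizedCloud":
        df = pd.read_csv(path)
        return cls(
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            z=df["z"].to_numpy(float),
            height=df["height"].to_numpy(float),
            classification=df["classification"].to_numpy(int),
        )


def normalize_heights(x, y, z, classification, dtm=None) -> NormalizedCloud:
    """Compute heights above ground for a classified point cloud.

    Ground elevation at each (x, y) is taken from *dtm* (a
    ``(GridSpec, elevation array)`` pair, bilinearly interpolated) when
    supplied, otherwise from linear interpolation within a Delaunay
    triangulation of the ground-classified returns; points outside the
    triangulation fall back to the nearest ground point.

    Raises
    ------
    ValueError
        If no DTM is given and there are fewer than 3 non-collinear ground
        points — the acquisition is unusable for normalization.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    classification = np.asarray(classification, int)

    if dtm is not None:
        spec, elev = dtm
        ground = _bilinear_dtm(spec, elev, x, y)
    else:
        gmask = classification == GROUND_CLASS
        gx, gy, gz = x[gmask], y[gmask], z[gmask]
        if gmask.sum() < 3:
            raise ValueError("need >=3 ground points or a DTM to normalize heights")
        pts = np.column_stack([gx, gy])
        try:
            lin = LinearNDInterpolator(pts, gz)
        except Exception as exc:  # collinear ground points -> Qhull failure
            raise ValueError("ground points are degenerate (collinear?)") from exc
        ground = lin(x, y)
        outside = np.isnan(ground)
        if outside.any():
            near = NearestNDInterpolator(pts, gz)
            ground[outside] = near(x[outside], y[outside])
    return NormalizedCloud(x, y, z, z - ground, classification)


def _bilinear_dtm(spec: GridSpec, elev: np.ndarray, x, y) -> np.ndarray:
    """Bilinear interpolation of a DTM at points, clamped to the grid edge."""
    fx = (x - spec.xmin) / spec.cell - 0.5
    fy = (spec.ymax - y) / spec.cell - 0.5
    c0 = np.clip(np.floor(fx).astype(int), 0, spec.ncols - 2)
    r0 = np.clip(np.floor(fy).astype(int), 0, spec.nrows - 2)
    tx = np.clip(fx - c0, 0.0, 1.0)
    ty = np.clip(fy - r0, 0.0, 1.0)
    z00 = elev[r0, c0]
    z01 = elev[r0, c0 + 1]
    z10 = elev[r0 + 1, c0]
    z11 = elev[r0 + 1, c0 + 1]
    return (
        z00 * (1 - tx) * (1 - ty)
        + z01 * tx * (1 - ty)
        + z10 * (1 - tx) * ty
        + z11 * tx * ty
    )


def stratify(heights) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Boolean masks (canopy, understory, nonground) for height-above-ground values.

    Canopy: height >= 2 m (a return at exactly 2 m goes to canopy, see module
    docstring); understory: 0 < height < 2; nonground: height > 0.
    """
    h = np.asarray(heights, float)
    nonground = h > 0
    canopy = h >= 2.0
    understory = nonground & (h < 2.0)
    return canopy, understory, nonground


def height_statistics(values) -> dict[str, float]:
    """Moment statistics of a height sample: MAX, AVG, STD, SKE, KUR.

    STD uses the n-1 denominator; SKE/KUR use bias-uncorrected sample
    moments (KUR is Pearson kurtosis, 3.0 for a normal sample in the limit).
    Undefined cases (n < 2 for STD, n < 3 or zero variance for SKE/KUR)
    return NaN.
    """
    v = np.asarray(values, float)
    n = v.size
    out = {k: np.nan for k in ("MAX", "AVG", "STD", "SKE", "KUR")}
    if n == 0:
        return out
    out["MAX"] = float(v.max())
    out["AVG"] = float(v.mean())
    if n >= 2:
        out["STD"] = float(v.std(ddof=1))
    if n >= 3 and v.std() > 0:
        out["SKE"] = float(skew(v, bias=True))
        out["KUR"] = float(kurtosis(v, fisher=False, bias=True))
    return out


def height_percentiles(values, probs=PERCENTILE_PROBS) -> dict[str, float]:
    """Order-statistic percentiles with linear interpolation between ranks."""
    v = np.asarray(values, float)
    if v.size == 0:
        return {f"P{p:02d}": np.nan for p in probs}
    qs = np.percentile(v, probs)  # linear rule: rank p*(n-1)/100 + 1
    return {f"P{p:02d}": float(q) for p, q in zip(probs, qs)}


def density_bins(heights, stratum: str) -> dict[str, float]:
    """Percentage of stratum returns per height band.

    ``stratum='nonground'`` gives D00..D07 over the eight nonground bands
    (returns above 48 m fall in no band, so the sum can be < 100);
    ``stratum='understory'`` gives D00.lt2..D04.lt2, which sum to 100
    whenever the stratum is occupied.  An empty stratum yields 0 for every
    bin (callers track emptiness separately).
    """
    h = np.asarray(heights, float)
    if stratum == "nonground":
        bands, suffix = NONGROUND_BANDS, ""
    elif stratum == "understory":
        bands, suffix = UNDERSTORY_BANDS, ".lt2"
    else:
        raise ValueError(f"unknown stratum {stratum!r}")
    names = [f"D{i:02d}{suffix}" for i in range(len(bands) - 1)]
    if h.size == 0:
        return {name: 0.0 for name in names}
    counts, _ = np.histogram(h, bins=bands)  # half-open, low-inclusive
    # np.histogram closes the last bin on the right; exclude exact top-edge hits
    counts[-1] -= int(np.sum(h == bands[-1]))
    pct = 100.0 * counts / h.size
    return dict(zip(names, pct.astype(float)))


def compute_strata_metrics(heights) -> dict[str, float]:
    """Full strata-metric vector for a set of height-above-ground values."""
    h = np.asarray(heights, float)
    canopy, understory, nonground = stratify(h)
    out: dict[str, float] = {}
    stats = height_statistics(h[canopy])
    stats.update(height_percentiles(h[canopy]))
    out.update({f"{k}.gt2": v for k, v in stats.items()})
    stats = height_statistics(h[understory])
    stats.update(height_percentiles(h[understory]))
    out.update({f"{k}.lt2": v for k, v in stats.items()})
    out.update(density_bins(h[nonground], "nonground"))
    out.update(density_bins(h[understory], "understory"))
    out["empty.gt2"] = float(not canopy.any())
    out["empty.lt2"] = float(not understory.any())
    out["empty.ng"] = float(not nonground.any())
    return out


def metrics_for_footprint(cloud: NormalizedCloud, center, radius: float) -> dict[str, float]:
    """Strata metrics over returns within *radius* m of *center* (x, y)."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    cx, cy = center
    d2 = (cloud.x - cx) ** 2 + (cloud.y - cy) ** 2
    inside = d2 <= radius * radius
    return compute_strata_metrics(cloud.height[inside])


@dataclass
class MetricGrid:
    """Per-cell strata metrics on a regular grid: one 2-D layer per metric.

    ``layers`` also carries ``empty.gt2`` / ``empty.lt2`` / ``empty.ng``
    mask layers (1 where the stratum had no returns; metric layers are
    zero-filled there).
    """

    spec: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.layers[name]

    def __contains__(self, name: str) -> bool:
        return name in self.layers

    def names(self) -> list[str]:
        return list(self.layers)


def metrics_grid(cloud: NormalizedCloud, spec: GridSpec, fill: float = 0.0) -> MetricGrid:
    """Bin returns into grid cells and compute strata metrics per cell.

    Cells are half-open (``cell_x <= x < cell_x + cell``).  Cells with no
    returns in a stratum carry *fill* (default 0) in that stratum's metric
    layers and 1 in the corresponding ``empty.*`` mask layer.
    """
    row, col = spec.index_of(cloud.x, cloud.y)
    inb = (row >= 0) & (row < spec.nrows) & (col >= 0) & (col < spec.ncols)
    cell_id = row[inb] * spec.ncols + col[inb]
    heights = cloud.height[inb]

    order = np.argsort(cell_id, kind="stable")
    cell_id = cell_id[order]
    heights = heights[order]
    uniq, starts = np.unique(cell_id, return_index=True)
    bounds = np.append(starts, len(cell_id))

    names = list(METRIC_NAMES) + ["empty.gt2", "empty.lt2", "empty.ng"]
    layers = {name: np.full(spec.shape, np.nan) for name in names}
    for i, cid in enumerate(uniq):
        r, c = divmod(int(cid), spec.ncols)
        m = compute_strata_metrics(heights[bounds[i] : bounds[i + 1]])
        for name in names:
            layers[name][r, c] = m[name]

    # cells with no returns at all: everything empty
    no_pts = np.isnan(layers["empty.ng"])
    for name in ("empty.gt2", "empty.lt2", "empty.ng"):
        layers[name][no_pts] = 1.0
    for name in METRIC_NAMES:
        layers[name] = np.where(np.isnan(layers[name]), fill, layers[name])
    return MetricGrid(spec=spec, layers=layers)


def metrics_at_plots(cloud: NormalizedCloud, centers, radius: float,
                     fill: float = 0.0) -> pd.DataFrame:
    """Strata-metric feature table for a list of circular plot footprints.

    NaN statistics (empty strata) are replaced by *fill* so the table is
    ready for model fitting; ``empty.*`` columns preserve the mask.
    """
    rows = []
    for cx, cy in centers:
        m = metrics_for_footprint(cloud, (cx, cy), radius)
        rows.append(m)
    df = pd.DataFrame(rows)
    metric_cols = [c for c in df.columns if not c.startswith("empty.")]
    df[metric_cols] = df[metric_cols].fillna(fill)
    return df
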