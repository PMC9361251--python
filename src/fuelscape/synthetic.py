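"""Synthetic fire-prone landscape generator with known ground truth.

Everything the mapping pipeline consumes can be generated here: a terrain
surface with an elevation-driven productivity gradient, a multi-decade fire
history of overlapping perimeter polygons, true per-cell fuel fields that
follow an asymptotic accumulation curve in years since fire, tree lists and
planar-intercept transect tallies consistent with the true loads, lidar
point clouds whose strata densities track canopy and understory structure,
and a severity-driven fire that consumes surface fuel in proportion to a
dNBR-like index.

The accumulation model is the offset exponential

    L(t) = A(elev) + (L0 - A(elev)) * exp(-k t),

with the asymptote A increasing linearly in elevation (wetter, more
productive sites hold more fuel), L0 the immediate post-fire load, and k
the recovery rate per year; cells never burned in the record sit at the
asymptote.  Available canopy fuel is driven by a canopy-cover surface and
is independent of years since fire.

Randomness: one global integer seed fans out to fixed named substreams so
each component can be regenerated independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon

from .fieldfuels import (
    DEFAULT_CONSTANTS,
    PI2_8,
    AllometryTable,
    FuelConstants,
    TransectTally,
    TreeRecord,
    slope_correction,
)
from .firehistory import DEFAULT_RECORD_WINDOW, FireEvent, rasterize_history
from .grids import GridSpec
from .lidar import _bilinear_dtm

# fixed substream ids for the global-seed fan-out
_STREAMS = {
    "terrain": 11,
    "fires": 23,
    "fuels": 37,
    "canopy": 41,
    "trees": 53,
    "transect": 67,
    "cloud": 79,
    "severity": 83,
    "fire_effects": 97,
    "plots": 101,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent, reproducible RNG stream for one generator component."""
    return np.random.default_rng([int(seed), _STREAMS[name]])


@dataclass
class Terrain:
    """Elevation raster: grid spec + elevation (m)."""

    spec: GridSpec
    elevation: np.ndarray

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, float)
        if self.elevation.shape != self.spec.shape:
            raise ValueError("elevation shape must match grid spec")
        if not np.all(np.isfinite(self.elevation)):
            raise ValueError("elevation must be finite")


@dataclass
class TrueFuelField:
    """Per-cell true fuel loads (Mg/ha) plus the structure surfaces that
    drive the synthetic lidar returns."""

    spec: GridSpec
    total_surface: np.ndarray
    woody_1_1000h: np.ndarray
    litter_duff: np.ndarray
    canopy_fuel: np.ndarray
    canopy_cover: np.ndarray
    tree_height: np.ndarray
    understory_density: np.ndarray

    def __post_init__(self) -> None:
        for name in ("total_surface", "woody_1_1000h", "litter_duff", "canopy_fuel"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be nonnegative")
        if not np.allclose(self.total_surface, self.woody_1_1000h + self.litter_duff):
            raise ValueError("total surface fuel must equal woody + litter/duff")


@dataclass
class SimConfig:
    """Study conditions for the synthetic landscape.

    Fuel parameters target the conditions of a dry-conifer plateau: stable
    surface loads around 90-130 Mg/ha across the elevation gradient,
    recovery to within 5% of the asymptote at roughly 10-15 years post
    fire, mean available canopy fuel near 7 Mg/ha, and a moderate
    (r ~ 0.3-0.4) correlation between consumption and burn severity.
    """

    seed: int = 0
    # terrain
    extent_m: tuple = (1000.0, 1000.0)
    cell_m: float = 20.0
    base_elev_m: float = 2150.0
    elev_gradient: tuple = (0.3, 0.0)  # m elevation per m east / north
    relief_m: float = 40.0
    # fire history
    n_fires: int = 8
    record_window: tuple = DEFAULT_RECORD_WINDOW
    # surface fuel accumulation
    asymptote_mg_ha: float = 110.0  # A at the reference elevation
    ref_elev_m: float = 2300.0
    elev_slope_mg_ha_per_m: float = 0.13
    rate_per_yr: float = 0.25  # k
    initial_load_mg_ha: float = 15.0  # L0
    fuel_noise_sigma: float = 0.25  # lognormal sigma, mean-one noise
    woody_fraction: float = 0.55  # woody share of total surface fuel
    woody_split: tuple = (0.08, 0.20, 0.22, 0.50)  # 1h/10h/100h/1000h shares
    litter_fraction_of_ld: float = 0.45
    # canopy
    canopy_fuel_per_cover: float = 16.0  # Mg/ha at full cover
    canopy_noise_sigma: float = 0.30
    max_tree_height_m: float = 30.0
    # lidar
    pulse_density: float = 8.0  # pulses per m^2
    # consumption vs severity
    consumption_slope: float = 0.08  # Mg/ha per dNBR unit
    consumption_intercept: float = 2.0
    consumption_noise_sd: float = 16.0
    high_severity_dnbr: float = 440.0
    severity_mean: float = 150.0
    severity_sd: float = 120.0
    # field sampling
    n_plots: int = 160
    plot_area_ha: float = 0.03
    transects_per_plot: int = 2

    def __post_init__(self) -> None:
        if self.rate_per_yr <= 0:
            raise ValueError("accumulation rate k must be positive")
        if not (self.asymptote_mg_ha > self.initial_load_mg_ha >= 0):
            raise ValueError("need asymptote A > initial load L0 >= 0")
        if self.pulse_density <= 0:
            raise ValueError("pulse density must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("extent_m", "elev_gradient", "record_window", "woody_split"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("extent_m", "elev_gradient", "record_window", "woody_split"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)


def accumulation_curve(t, A, L0, k):
    """Offset-exponential fuel accumulation L(t) = A + (L0 - A) exp(-k t)."""
    return A + (L0 - A) * np.exp(-k * np.asarray(t, float))


def generate_terrain(extent_m, cell_m: float, relief_m: float, seed: int,
                     base_elev_m: float = 2150.0,
                     gradient=(0.3, 0.0)) -> Terrain:
    """Smooth elevation surface: a planar gradient plus low-frequency noise.

    *relief_m* scales the noise component; relief 0 with zero gradient gives
    a constant grid.
    """
    w, h = extent_m
    if w <= 0 or h <= 0:
        raise ValueError("extent must be positive")
    if cell_m <= 0:
        raise ValueError("cell size must be positive")
    ncols = int(round(w / cell_m))
    nrows = int(round(h / cell_m))
    spec = GridSpec(xmin=0.0, ymax=nrows * cell_m, cell=cell_m, nrows=nrows, ncols=ncols)
    X, Y = spec.cell_centers()
    elev = base_elev_m + gradient[0] * X + gradient[1] * Y
    if relief_m > 0:
        rng = substream(seed, "terrain")
        noise = rng.standard_normal(spec.shape)
        noise = gaussian_filter(noise, sigma=max(2.0, nrows / 12), mode="nearest")
        sd = noise.std()
        if sd > 0:
            noise *= relief_m / (4 * sd)  # ~95% of cells within +/- relief/2
        elev = elev + noise
    return Terrain(spec=spec, elevation=elev)


def generate_fire_history(terrain: Terrain, n_fires: int, year_range,
                          seed: int) -> list[FireEvent]:
    """Random convex-ish fire perimeters with years; overlaps permitted."""
    if n_fires < 0:
        raise ValueError("n_fires must be nonnegative")
    y0, y1 = year_range
    rng = substream(seed, "fires")
    spec = terrain.spec
    # years cover the record evenly (shuffled) so years-since-fire spans the
    # window instead of clustering by chance
    if n_fires > 0:
        years = np.floor(np.linspace(y0, y1, n_fires)).astype(int)
        rng.shuffle(years)
    fires = []
    for i in range(n_fires):
        cx = rng.uniform(spec.xmin + 0.1 * spec.cell, spec.xmax)
        cy = rng.uniform(spec.ymin, spec.ymax)
        radius = rng.uniform(0.12, 0.35) * min(spec.xmax - spec.xmin,
                                               spec.ymax - spec.ymin)
        ang = np.sort(rng.uniform(0, 2 * np.pi, 16))
        r = radius * (1.0 + 0.3 * (rng.uniform(size=16) - 0.5))
        pts = np.column_stack([cx + r * np.cos(ang), cy + r * np.sin(ang)])
        poly = Polygon(pts).convex_hull
        fires.append(FireEvent(polygon=poly, year=int(years[i]), fire_id=f"F{i:02d}"))
    return fires


def asymptote_surface(cfg: SimConfig, elevation: np.ndarray) -> np.ndarray:
    """Elevation-dependent stable fuel load A(elev), floored above L0."""
    A = cfg.asymptote_mg_ha + cfg.elev_slope_mg_ha_per_m * (elevation - cfg.ref_elev_m)
    return np.maximum(A, cfg.initial_load_mg_ha + 1.0)


def _mean_one_lognormal(rng, sigma: float, shape) -> np.ndarray:
    if sigma <= 0:
        return np.ones(shape)
    return np.exp(rng.normal(-0.5 * sigma**2, sigma, size=shape))


def generate_true_fuels(terrain: Terrain, fires, ref_year: int,
                        cfg: SimConfig) -> TrueFuelField:
    """True fuel fields at *ref_year* from terrain and fire history.

    Surface fuel follows the accumulation curve in years since fire with
    elevation-dependent asymptote and mean-one lognormal noise; cells never
    burned sit at the asymptote.  Canopy fuel is proportional to a smooth
    canopy-cover surface and independent of years since fire.
    """
    if any(f.year > ref_year for f in fires):
        raise ValueError("reference year must be >= all fire years")
    spec = terrain.spec
    hist = rasterize_history(fires, spec, ref_year, cfg.record_window)
    A = asymptote_surface(cfg, terrain.elevation)
    mean_load = np.where(
        hist.burned_mask(),
        accumulation_curve(np.nan_to_num(hist.ysf), A, cfg.initial_load_mg_ha,
                           cfg.rate_per_yr),
        A,
    )
    rng = substream(cfg.seed, "fuels")
    total = mean_load * _mean_one_lognormal(rng, cfg.fuel_noise_sigma, spec.shape)
    woody = cfg.woody_fraction * total
    litter_duff = total - woody

    crng = substream(cfg.seed, "canopy")
    elev_norm = (terrain.elevation - terrain.elevation.min()) / max(
        np.ptp(terrain.elevation), 1.0
    )
    cover_noise = gaussian_filter(crng.standard_normal(spec.shape), sigma=2.0,
                                  mode="nearest")
    cover = np.clip(0.25 + 0.4 * elev_norm + 0.25 * cover_noise, 0.02, 0.9)
    canopy_fuel = (
        cfg.canopy_fuel_per_cover
        * cover
        * _mean_one_lognormal(crng, cfg.canopy_noise_sigma, spec.shape)
    )
    tree_height = np.clip(
        cfg.max_tree_height_m * (0.25 + 0.75 * cover)
        + 2.0 * crng.standard_normal(spec.shape),
        2.5,
        cfg.max_tree_height_m * 1.2,
    )
    understory = np.clip(0.05 + 0.35 * total / np.maximum(A.max(), 1.0)
                         + 0.05 * crng.standard_normal(spec.shape), 0.0, 0.6)
    return TrueFuelField(
        spec=spec,
        total_surface=total,
        woody_1_1000h=woody,
        litter_duff=litter_duff,
        canopy_fuel=canopy_fuel,
        canopy_cover=cover,
        tree_height=tree_height,
        understory_density=understory,
    )


# ---------------------------------------------------------------------------
# field-data generators


def generate_tree_list(plot_area_ha: float, canopy_fuel_target: float,
                       allometry: AllometryTable, seed: int,
                       dead_fraction: float = 0.1) -> list[TreeRecord]:
    """Tree list whose allometric available canopy fuel matches the target.

    DBH values are drawn from a truncated lognormal (> 15 cm protocol
    minimum), then jointly rescaled about the 15-cm floor so that the live
    trees' available canopy fuel equals *canopy_fuel_target* (Mg/ha) to
    numerical precision.  A *dead_fraction* of extra snags is appended;
    dead trees carry no available canopy fuel.
    """
    if canopy_fuel_target < 0:
        raise ValueError("canopy fuel target must be nonnegative")
    if not allometry.species:
        raise ValueError("allometry table must not be empty")
    if canopy_fuel_target == 0:
        return []
    rng = np.random.default_rng([int(seed), _STREAMS["trees"]])
    target_kg = canopy_fuel_target * plot_area_ha * 1000.0

    species = rng.choice(allometry.species, size=256)
    dbh = 15.0 + rng.lognormal(mean=2.3, sigma=0.55, size=256)
    per_tree = np.array(
        [float(allometry.available_canopy_fuel_kg(s, d)) for s, d in zip(species, dbh)]
    )
    n = int(np.clip(round(target_kg / per_tree.mean()), 1, 256))
    species, dbh = species[:n], dbh[:n]

    def acf_at_scale(s: float) -> float:
        d = 15.0 + s * (dbh - 15.0)
        return sum(
            float(allometry.available_canopy_fuel_kg(sp, di))
            for sp, di in zip(species, d)
        )

    lo, hi = 1e-6, 1.0
    while acf_at_scale(hi) < target_kg and hi < 64:
        hi *= 2
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if acf_at_scale(mid) < target_kg:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    dbh = 15.0 + scale * (dbh - 15.0)

    trees = []
    for sp, d in zip(species, dbh):
        h = float(np.clip(1.37 + 0.9 * d**0.85, 3.0, 45.0))
        cb = float(h * rng.uniform(0.25, 0.55))
        trees.append(TreeRecord(status="live", dbh_cm=float(d), height_m=h,
                                crown_base_m=cb, species=str(sp)))
    n_dead = int(round(dead_fraction * n))
    for _ in range(n_dead):
        d = 15.0 + float(rng.lognormal(2.3, 0.55))
        h = float(np.clip(1.37 + 0.9 * d**0.85, 3.0, 45.0))
        trees.append(TreeRecord(status="dead", dbh_cm=d, height_m=h,
                                crown_base_m=h * 0.5,
                                species=str(rng.choice(allometry.species))))
    return trees


#: default 1000-h piece-diameter model: 7.62 cm + Exponential(scale) cm
CWD_DIAMETER_EXP_SCALE = 2.5


def sample_transect(true_loads: dict, slope_pct: float, seed: int,
                    constants: FuelConstants = DEFAULT_CONSTANTS,
                    n_depth_stations: int = 10) -> TransectTally:
    """Simulate one planar-intercept transect over known component loads.

    Expected tallies per fine class invert the planar-intercept load
    equation at the class quadratic-mean diameter; realized counts are
    Poisson.  1000-h pieces are a compound-Poisson draw of individual
    diameters (7.62 cm + exponential) whose expected squared-diameter sum
    matches the generating load.  Litter/duff depths are gamma draws whose
    mean is load / bulk density.  The estimator applied to these tallies is
    therefore unbiased for the generating loads.
    """
    for key, w in true_loads.items():
        if w < 0:
            raise ValueError(f"negative load for {key}")
    rng = np.random.default_rng([int(seed), _STREAMS["transect"]])
    k = constants
    c = slope_correction(slope_pct)

    counts = {}
    for cls_ in ("1h", "10h", "100h"):
        w = true_loads.get(cls_, 0.0)
        L = k.segment_length_m[cls_]
        denom = PI2_8 * k.specific_gravity[cls_] * k.angle_correction[cls_] * c \
            * k.qmd_cm[cls_] ** 2
        expected = w * L / denom
        counts[cls_] = int(rng.poisson(expected))

    w1000 = true_loads.get("1000h", 0.0)
    L = k.segment_length_m["1000h"]
    denom = PI2_8 * k.specific_gravity["1000h"] * k.angle_correction["1000h"] * c
    target_sum_d2 = w1000 * L / denom
    dmin = 7.62
    s = CWD_DIAMETER_EXP_SCALE
    e_d2 = dmin**2 + 2 * dmin * s + 2 * s**2
    n_pieces = int(rng.poisson(target_sum_d2 / e_d2)) if target_sum_d2 > 0 else 0
    diameters = (dmin + rng.exponential(s, size=n_pieces)).tolist()

    depths = {}
    for comp, bd in (("litter", k.litter_bulk_density), ("duff", k.duff_bulk_density)):
        w = true_loads.get(comp, 0.0)
        mean_depth_cm = 10.0 * w / bd  # inverts depth/100 * BD * 10
        if mean_depth_cm > 0:
            shape = 5.0
            depths[comp] = rng.gamma(shape, mean_depth_cm / shape,
                                     size=n_depth_stations).tolist()
        else:
            depths[comp] = [0.0] * n_depth_stations

    return TransectTally(
        count_1h=counts["1h"],
        count_10h=counts["10h"],
        count_100h=counts["100h"],
        diameters_1000h_cm=diameters,
        litter_depths_cm=depths["litter"],
        duff_depths_cm=depths["duff"],
        slope_pct=slope_pct,
        azimuth_deg=float(rng.uniform(0, 360)),
    )


def split_surface_components(cfg: SimConfig, woody: float, litter_duff: float) -> dict:
    """Distribute woody and litter/duff totals over sampled components."""
    f1, f10, f100, f1000 = cfg.woody_split
    return {
        "1h": f1 * woody,
        "10h": f10 * woody,
        "100h": f100 * woody,
        "1000h": f1000 * woody,
        "litter": cfg.litter_fraction_of_ld * litter_duff,
        "duff": (1 - cfg.litter_fraction_of_ld) * litter_duff,
    }


def planted_signal_dataset(n: int, target_r2: float, seed: int,
                           n_noise: int = 4):
    """Feature table with a known planted signal at a prescribed R^2.

    Three informative features drive the response through an additive
    piecewise-constant surface (exactly representable by axis-aligned tree
    splits, so forest skill approaches the prescribed R^2 as n grows);
    *n_noise* pure-noise features are appended; Gaussian noise is scaled so
    the population R^2 equals *target_r2*.  Returns
    ``(features DataFrame, response, signal)``.  Used for planted-signal
    recovery checks of the fuel models.
    """
    import pandas as pd

    rng = np.random.default_rng([int(seed), 7919])
    X = rng.standard_normal((n, 3 + n_noise))
    signal = (2.0 * (X[:, 0] > 0.0) + 1.5 * (X[:, 1] > 0.5)
              + 1.0 * (X[:, 2] > -0.5))
    if not 0 < target_r2 < 1:
        raise ValueError("target R^2 must be in (0, 1)")
    noise_sd = np.std(signal) * np.sqrt((1 - target_r2) / target_r2)
    y = signal + rng.normal(0, noise_sd, size=n)
    cols = [f"S{i}" for i in range(3)] + [f"N{i}" for i in range(n_noise)]
    return pd.DataFrame(X, columns=cols), y, signal


# ---------------------------------------------------------------------------
# point clouds and fire effects


def generate_point_cloud(terrain: Terrain, canopy_cover, tree_height,
                         understory_density, pulse_density: float, seed: int,
                         stream: str = "cloud"):
    """Simulate a classified point cloud over the terrain.

    Per cell the expected return count is pulse density times cell area;
    each return is canopy (within the crown envelope, between 40% and 100%
    of the cell's tree height) with probability = canopy cover, understory
    (0.03-1.9 m) with probability = understory density, otherwise ground.
    Returns (x, y, z, classification) with ground = class 2.
    """
    if pulse_density <= 0:
        raise ValueError("pulse density must be positive")
    spec = terrain.spec
    for grid in (canopy_cover, tree_height, understory_density):
        if np.asarray(grid).shape != spec.shape:
            raise ValueError("structure grids must align with terrain")
    rng = np.random.default_rng([int(seed), _STREAMS[stream]])
    lam = pulse_density * spec.cell**2
    n_per_cell = rng.poisson(lam, size=spec.shape)
    total = int(n_per_cell.sum())
    rows = np.repeat(np.arange(spec.nrows), n_per_cell.sum(axis=1))
    cols = np.repeat(
        np.tile(np.arange(spec.ncols), spec.nrows), n_per_cell.ravel()
    )
    x = spec.xmin + (cols + rng.uniform(size=total)) * spec.cell
    y = spec.ymax - (rows + rng.uniform(size=total)) * spec.cell
    ground_z = _bilinear_dtm(spec, terrain.elevation, x, y)

    cover = np.asarray(canopy_cover, float)[rows, cols]
    under = np.asarray(understory_density, float)[rows, cols]
    th = np.asarray(tree_height, float)[rows, cols]
    u = rng.uniform(size=total)
    is_canopy = u < cover
    is_under = (~is_canopy) & (u < cover + under)

    h = np.zeros(total)
    h[is_canopy] = th[is_canopy] * rng.uniform(0.4, 1.0, size=int(is_canopy.sum()))
    h[is_under] = rng.uniform(0.03, 1.9, size=int(is_under.sum()))
    z = ground_z + h
    classification = np.where(is_canopy | is_under, 1, 2)
    return x, y, z, classification


def generate_severity(terrain: Terrain, fire_polygon, seed: int,
                      cfg: SimConfig) -> np.ndarray:
    """dNBR-like severity raster: smooth positive field inside the fire
    perimeter, NaN outside (unburned)."""
    import shapely

    rng = substream(seed, "severity")
    spec = terrain.spec
    raw = gaussian_filter(rng.standard_normal(spec.shape), sigma=2.5, mode="nearest")
    sd = raw.std() or 1.0
    sev = np.clip(cfg.severity_mean + cfg.severity_sd * raw / sd, 0.0, 1200.0)
    X, Y = spec.cell_centers()
    inside = shapely.contains_xy(fire_polygon, X.ravel(), Y.ravel()).reshape(spec.shape)
    return np.where(inside, sev, np.nan)


def apply_fire(pre_cloud, pre_fuels: TrueFuelField, severity: np.ndarray,
               cfg: SimConfig, growth_years: float = 1.0,
               terrain: Terrain | None = None):
    """Burn the landscape: reduce surface fuel with severity, thin canopy
    where severity is high, and let unburned cells accrue fuel.

    True consumption in burned cells is ``slope*severity + intercept`` plus
    Gaussian noise, clamped from above by the available fuel; unburned
    cells accrue litterfall for *growth_years*, which shows up as negative
    consumption.  In the post-fire cloud, understory returns are removed
    with probability equal to the consumed fraction of the cell's surface
    fuel (when *terrain* is supplied to separate the strata), and canopy
    returns are thinned only above the high-severity threshold.  Returns
    ``(post_cloud, post_fuels, true_consumption)``.
    """
    spec = pre_fuels.spec
    severity = np.asarray(severity, float)
    if severity.shape != spec.shape:
        raise ValueError("severity grid must align with the fuel field")
    rng = substream(cfg.seed, "fire_effects")
    burned = ~np.isnan(severity)
    sev = np.nan_to_num(severity)

    consumption = np.where(
        burned,
        cfg.consumption_slope * sev + cfg.consumption_intercept
        + rng.normal(0.0, cfg.consumption_noise_sd, size=spec.shape),
        0.0,
    )
    consumption = np.minimum(consumption, pre_fuels.total_surface)
    # unburned cells keep accruing litterfall -> apparent negative consumption
    growth = np.maximum(
        rng.normal(cfg.rate_per_yr * growth_years * 8.0, 1.0, size=spec.shape), 0.0
    )
    consumption = np.where(burned, consumption, -growth)

    post_total = np.maximum(pre_fuels.total_surface - consumption, 0.0)
    consumption = pre_fuels.total_surface - post_total  # exact bookkeeping
    post_woody = cfg.woody_fraction * post_total
    post_ld = post_total - post_woody

    x, y, z, cls_ = pre_cloud
    row, col = spec.index_of(x, y)
    row = np.clip(row, 0, spec.nrows - 1)
    col = np.clip(col, 0, spec.ncols - 1)
    sev_at = np.nan_to_num(severity)[row, col]
    nonground = cls_ != 2
    if terrain is not None:
        h = z - _bilinear_dtm(spec, terrain.elevation, x, y)
        is_under = nonground & (h < 2.0)
        is_canopy = nonground & ~is_under
    else:  # without ground elevations the strata cannot be separated
        is_under = np.zeros(len(x), bool)
        is_canopy = nonground
    # understory returns disappear with the consumed fraction of surface fuel
    consumed_frac = np.clip(
        consumption / np.maximum(pre_fuels.total_surface, 1e-9), 0.0, 0.95
    )
    p_drop = np.where(is_under, consumed_frac[row, col], 0.0)
    # canopy thinned only above the high-severity threshold
    thin_p = np.clip((sev_at - cfg.high_severity_dnbr) / 400.0, 0.0, 0.9)
    p_drop = np.where(is_canopy, thin_p, p_drop)
    keep = rng.uniform(size=len(x)) >= p_drop
    post_cloud = (x[keep], y[keep], z[keep], cls_[keep])

    post_canopy = pre_fuels.canopy_fuel * np.where(
        sev > cfg.high_severity_dnbr, 0.5, 1.0
    )
    post_fuels = TrueFuelField(
        spec=spec,
        total_surface=post_total,
        woody_1_1000h=post_woody,
        litter_duff=post_ld,
        canopy_fuel=post_canopy,
        canopy_cover=pre_fuels.canopy_cover,
        tree_height=pre_fuels.tree_height,
        understory_density=np.clip(
            pre_fuels.understory_density * post_total
            / np.maximum(pre_fuels.total_surface, 1e-9),
            0.0,
            0.6,
        ),
    )
    return post_cloud, post_fuels, consumption
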