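"""Plot-level fuel loads from field measurements.

Two estimators feed the mapping models as response variables:

* **Available canopy fuel** — foliage biomass plus half of fine-branch
  biomass of live overstory trees, from per-species log-linear allometries
  ``ln(B_kg) = b0 + b1 ln(DBH_cm)``, expressed per hectare.
* **Surface fuel** — the planar-intercept (line-intersect) estimator for
  downed woody timelag classes,

      W [Mg/ha] = (pi^2 / 8) * G * a * c * (sum d^2 [cm^2]) / L [m],

  with G the particle specific gravity, a the nonhorizontal-lean angle
  correction, c = sqrt(1 + (slope%/100)^2) the slope correction, and L the
  sampled transect length.  Fine classes (1-h, 10-h, 100-h) use tallied
  counts times a squared quadratic-mean diameter; the 1000-h class sums
  squared diameters of individual pieces.  Litter and duff come from depth
  times bulk density.

Class constants (specific gravities, angle corrections, quadratic-mean
diameters, segment lengths, bulk densities) are exposed as a configurable
table with composite conifer defaults; exact published composite values
vary by forest type, so every constant can be overridden per project.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

PI2_8 = np.pi**2 / 8  # 1.2337

TIMELAG_CLASSES = ("1h", "10h", "100h", "1000h")

#: diameter breakpoints (cm) naming the timelag classes
CLASS_DIAMETER_RANGES = {
    "1h": (0.0, 0.64),
    "10h": (0.64, 2.54),
    "100h": (2.54, 7.62),
    "1000h": (7.62, np.inf),
}


@dataclass(frozen=True)
class FuelConstants:
    """Composite constants for the planar-intercept estimator.

    Defaults are canonical composite-conifer values: specific gravities
    0.48 (sound fine fuels) and 0.40 (larger pieces), angle correction 1.13
    for fine classes, quadratic-mean diameters 0.4 / 1.3 / 3.8 cm for the
    1-/10-/100-h classes, measurement segments 1.83 m (1-h, 10-h), 3.66 m
    (100-h), full 15.24 m (1000-h), and bulk densities 44 (litter) and
    88 kg/m^3 (duff).
    """

    specific_gravity: dict = field(
        default_factory=lambda: {"1h": 0.48, "10h": 0.48, "100h": 0.40, "1000h": 0.40}
    )
    angle_correction: dict = field(
        default_factory=lambda: {"1h": 1.13, "10h": 1.13, "100h": 1.13, "1000h": 1.00}
    )
    qmd_cm: dict = field(default_factory=lambda: {"1h": 0.4, "10h": 1.3, "100h": 3.8})
    segment_length_m: dict = field(
        default_factory=lambda: {"1h": 1.83, "10h": 1.83, "100h": 3.66, "1000h": 15.24}
    )
    litter_bulk_density: float = 44.0  # kg/m^3
    duff_bulk_density: float = 88.0  # kg/m^3

    @classmethod
    def from_yaml(cls, path) -> "FuelConstants":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = cls()
        merged = {}
        for name in ("specific_gravity", "angle_correction", "qmd_cm", "segment_length_m"):
            d = dict(getattr(base, name))
            d.update(raw.get(name, {}))
            merged[name] = d
        merged["litter_bulk_density"] = raw.get("litter_bulk_density", base.litter_bulk_density)
        merged["duff_bulk_density"] = raw.get("duff_bulk_density", base.duff_bulk_density)
        return cls(**merged)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "specific_gravity": self.specific_gravity,
                    "angle_correction": self.angle_correction,
                    "qmd_cm": self.qmd_cm,
                    "segment_length_m": self.segment_length_m,
                    "litter_bulk_density": self.litter_bulk_density,
                    "duff_bulk_density": self.duff_bulk_density,
                },
                fh,
            )


DEFAULT_CONSTANTS = FuelConstants()


@dataclass(frozen=True)
class TreeRecord:
    """One overstory tree (fixed-radius plot protocol: DBH > 15 cm)."""

    status: str  # "live" | "dead"
    dbh_cm: float
    height_m: float
    crown_base_m: float
    species: str
    crown_class: str = "codominant"

    def __post_init__(self) -> None:
        if self.crown_base_m > self.height_m:
            raise ValueError("crown base cannot exceed tree height")


class AllometryTable:
    """Per-species log-linear biomass equations ln(B) = b0 + b1 ln(DBH).

    Two components per species: foliage and fine (small) branch biomass,
    both in kg per tree with DBH in cm.
    """

    def __init__(self, coefficients: dict[str, dict[str, tuple[float, float]]]):
        if not coefficients:
            raise ValueError("allometry table must not be empty")
        self._coef = coefficients

    @classmethod
    def default(cls) -> "AllometryTable":
        """Synthetic conifer-like default species set (not species-specific
        published equations; the interface is the point)."""
        return cls(
            {
                "PIPO": {"foliage": (-3.0, 1.70), "fine_branch": (-3.6, 1.80)},
                "PSME": {"foliage": (-2.8, 1.65), "fine_branch": (-3.4, 1.75)},
                "ABCO": {"foliage": (-2.9, 1.72), "fine_branch": (-3.5, 1.78)},
            }
        )

    @property
    def species(self) -> list[str]:
        return list(self._coef)

    def _component(self, species: str, comp: str, dbh_cm) -> np.ndarray:
        if species not in self._coef:
            raise KeyError(f"species {species!r} missing from allometry table")
        b0, b1 = self._coef[species][comp]
        return np.exp(b0 + b1 * np.log(np.asarray(dbh_cm, float)))

    def foliage_kg(self, species: str, dbh_cm) -> np.ndarray:
        return self._component(species, "foliage", dbh_cm)

    def fine_branch_kg(self, species: str, dbh_cm) -> np.ndarray:
        return self._component(species, "fine_branch", dbh_cm)

    def available_canopy_fuel_kg(self, species: str, dbh_cm) -> np.ndarray:
        """Foliage plus 50% of fine-branch biomass, kg per tree."""
        return self.foliage_kg(species, dbh_cm) + 0.5 * self.fine_branch_kg(species, dbh_cm)


def canopy_fuel_from_trees(trees, plot_area_ha: float,
                           allometry: AllometryTable) -> float:
    """Available canopy fuel (Mg/ha) of a tree list on a plot.

    Only live trees contribute ("available" fuel is the canopy portion
    consumable in crown fire).
    """
    if plot_area_ha <= 0:
        raise ValueError("plot area must be positive")
    total_kg = 0.0
    for t in trees:
        if t.status != "live":
            continue
        total_kg += float(allometry.available_canopy_fuel_kg(t.species, t.dbh_cm))
    return total_kg / plot_area_ha / 1000.0  # kg/ha -> Mg/ha


def slope_correction(slope_pct: float) -> float:
    """c = sqrt(1 + (slope%/100)^2): plan-length to slope-length correction."""
    return float(np.sqrt(1.0 + (slope_pct / 100.0) ** 2))


def fwd_load(count: int, qmd_cm: float, length_m: float, specific_gravity: float,
             angle_corr: float, slope_pct: float = 0.0) -> float:
    """Fine-woody-debris load (Mg/ha) from a planar-intercept tally."""
    if count < 0:
        raise ValueError("count must be nonnegative")
    if length_m <= 0:
        raise ValueError("transect length must be positive")
    c = slope_correction(slope_pct)
    return PI2_8 * specific_gravity * angle_corr * c * count * qmd_cm**2 / length_m


def cwd_load(diameters_cm, length_m: float, specific_gravity: float,
             angle_corr: float, slope_pct: float = 0.0) -> float:
    """Coarse (1000-h) load (Mg/ha) from individual piece diameters."""
    d = np.asarray(diameters_cm, float)
    if d.size and np.any(d <= 0):
        raise ValueError("piece diameters must be positive")
    if length_m <= 0:
        raise ValueError("transect length must be positive")
    c = slope_correction(slope_pct)
    return float(PI2_8 * specific_gravity * angle_corr * c * np.sum(d**2) / length_m)


def litter_duff_load(depths_cm, bulk_density_kg_m3: float) -> float:
    """Load (Mg/ha) from depth measurements: mean depth (m) x BD x 10."""
    if bulk_density_kg_m3 <= 0:
        raise ValueError("bulk density must be positive")
    d = np.asarray(depths_cm, float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return np.nan  # all depths missing: undefined, flagged by NaN
    return float(d.mean() / 100.0 * bulk_density_kg_m3 * 10.0)


@dataclass
class TransectTally:
    """Raw measurements from one planar-intercept transect.

    Counts are over the class segment lengths (1-h and 10-h over the first
    1.83 m, 100-h over the first 3.66 m); 1000-h pieces are recorded as
    individual diameters over the full 15.24 m; litter/duff depths are the
    station measurements (cm).
    """

    count_1h: int
    count_10h: int
    count_100h: int
    diameters_1000h_cm: list[float] = field(default_factory=list)
    litter_depths_cm: list[float] = field(default_factory=list)
    duff_depths_cm: list[float] = field(default_factory=list)
    slope_pct: float = 0.0
    azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        if min(self.count_1h, self.count_10h, self.count_100h) < 0:
            raise ValueError("tally counts must be nonnegative")
        if any(d <= CLASS_DIAMETER_RANGES["1000h"][0] for d in self.diameters_1000h_cm):
            raise ValueError("1000-h pieces must exceed 7.62 cm diameter")


def transect_loads(tally: TransectTally,
                   constants: FuelConstants = DEFAULT_CONSTANTS) -> dict[str, float]:
    """Component loads (Mg/ha) for one transect."""
    k = constants
    loads = {}
    for cls_, count in (("1h", tally.count_1h), ("10h", tally.count_10h),
                        ("100h", tally.count_100h)):
        loads[cls_] = fwd_load(
            count, k.qmd_cm[cls_], k.segment_length_m[cls_],
            k.specific_gravity[cls_], k.angle_correction[cls_], tally.slope_pct,
        )
    loads["1000h"] = cwd_load(
        tally.diameters_1000h_cm, k.segment_length_m["1000h"],
        k.specific_gravity["1000h"], k.angle_correction["1000h"], tally.slope_pct,
    )
    loads["litter"] = litter_duff_load(tally.litter_depths_cm, k.litter_bulk_density)
    loads["duff"] = litter_duff_load(tally.duff_depths_cm, k.duff_bulk_density)
    return loads


@dataclass
class FuelObservation:
    """Plot-level fuel loads (Mg/ha), the model response variables."""

    plot_id: str
    canopy_fuel: float  # available canopy fuel; NaN where no overstory plot
    woody_1_1000h: float
    litter_duff: float
    total_surface: float
    year: int = 0

    def __post_init__(self) -> None:
        expect = self.woody_1_1000h + self.litter_duff
        if np.isfinite(expect) and abs(self.total_surface - expect) > 1e-9:
            raise ValueError("total surface fuel must equal woody + litter/duff")


def aggregate_plot(tallies, plot_id: str = "plot", year: int = 0,
                   canopy_fuel: float = np.nan,
                   constants: FuelConstants = DEFAULT_CONSTANTS) -> FuelObservation:
    """Average component loads across a plot's one or two transects.

    Missing litter/duff (NaN) on a transect is ignored in the average; if
    every transect is missing a component it contributes 0 to the plot
    total and the observation carries NaN for that component's share.
    """
    tallies = list(tallies)
    if not tallies:
        raise ValueError("at least one transect required")
    per = [transect_loads(t, constants) for t in tallies]
    woody = float(np.mean([sum(p[c] for c in TIMELAG_CLASSES) for p in per]))
    ld_vals = [p["litter"] + p["duff"] for p in per]
    ld_vals = [v for v in ld_vals if np.isfinite(v)]
    litter_duff = float(np.mean(ld_vals)) if ld_vals else 0.0
    return FuelObservation(
        plot_id=plot_id,
        canopy_fuel=canopy_fuel,
        woody_1_1000h=woody,
        litter_duff=litter_duff,
        total_surface=woody + litter_duff,
        year=year,
    )


def observations_to_frame(observations) -> pd.DataFrame:
    rows = [
        {
            "plot_id": o.plot_id,
            "canopy_fuel": o.canopy_fuel,
            "woody_1_1000h": o.woody_1_1000h,
            "litter_duff": o.litter_duff,
            "total_surface": o.total_surface,
            "year": o.year,
        }
        for o in observations
    ]
    return pd.DataFrame(rows)
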