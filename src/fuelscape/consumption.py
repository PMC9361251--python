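"""Fuel maps, pre/post-fire differencing, and consumption reporting.

A fitted fuel-load model applied to a metric grid yields a fuel map;
differencing maps for two acquisitions gives per-cell consumption
(negative values — apparent accumulation — are retained).  Fire-level
summaries include the cells whose centers fall inside the fire perimeter
and outside any exclusion polygon, the total consumed mass in Gg with a
confidence interval of total x %RMSE/100, per-severity-class statistics,
and the Pearson correlation between consumption and the severity index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .firehistory import FireHistoryGrids
from .grids import GridSpec, require_aligned
from .lidar import MetricGrid

SEVERITY_CLASSES = ("unburned_to_low", "low", "moderate", "high")

#: default dNBR breakpoints between the four severity classes
DEFAULT_SEVERITY_THRESHOLDS = (100.0, 270.0, 440.0)


@dataclass
class FuelGrid:
    """Predicted fuel load map (Mg/ha) on a 20-m grid."""

    spec: GridSpec
    load: np.ndarray
    response_name: str
    year: int = 0
    model_id: str = ""

    def __post_init__(self) -> None:
        if self.load.shape != self.spec.shape:
            raise ValueError("load layer must match grid spec")
        if np.nanmin(self.load) < 0:
            raise ValueError("predicted loads must be nonnegative")


def predict_grid(results, metrics: MetricGrid, history: FireHistoryGrids | None = None,
                 year: int = 0) -> FuelGrid:
    """Apply a fitted fuel model across a metric grid.

    Feature layers are looked up by name in the metric grid, with YSF/NPF
    supplied by *history* (YSF uses the finite never-burned fill).  Cells
    empty in every stratum are masked to NaN; negative predictions are
    clamped to zero (a no-op safeguard for forests, which cannot predict
    below the training minimum).
    """
    layers = dict(metrics.layers)
    if history is not None:
        require_aligned(metrics.spec, history.spec, "metric and history grids")
        layers["YSF"] = history.ysf_filled()
        layers["NPF"] = history.npf.astype(float)
    missing = [f for f in results.features if f not in layers]
    if missing:
        raise KeyError(f"missing predictor layers {missing}")
    spec = metrics.spec
    table = pd.DataFrame(
        {name: layers[name].ravel() for name in results.features}
    )
    pred = results.predict(table).reshape(spec.shape)
    pred = np.maximum(pred, 0.0)
    if "empty.ng" in metrics.layers:
        pred = np.where(metrics.layers["empty.ng"] >= 1.0, np.nan, pred)
    return FuelGrid(spec=spec, load=pred, response_name=results.response_name,
                    year=year, model_id=results.response_name)


def difference_maps(pre: FuelGrid, post: FuelGrid) -> np.ndarray:
    """Consumption = pre - post, per cell; negative values retained."""
    require_aligned(pre.spec, post.spec, "pre/post fuel grids")
    return pre.load - post.load


@dataclass
class ConsumptionReport:
    """Fire-level consumption summary."""

    fire_id: str
    mean_mg_ha: float
    total_gg: float
    ci_gg: float
    n_cells: int
    n_excluded: int
    severity_table: pd.DataFrame | None = None
    dnbr_r: float = np.nan
    pct_rmse: float = np.nan

    def to_dict(self) -> dict:
        d = {
            "fire_id": self.fire_id,
            "mean_mg_ha": self.mean_mg_ha,
            "total_gg": self.total_gg,
            "ci_gg": self.ci_gg,
            "n_cells": self.n_cells,
            "n_excluded": self.n_excluded,
            "dnbr_r": None if np.isnan(self.dnbr_r) else self.dnbr_r,
            "pct_rmse": None if np.isnan(self.pct_rmse) else self.pct_rmse,
        }
        if self.severity_table is not None:
            d["severity_table"] = self.severity_table.to_dict(orient="index")
        return d

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def summary(self) -> str:
        lines = [
            f"Consumption report: {self.fire_id}",
            "=" * 46,
            f"included cells:   {self.n_cells} ({self.n_excluded} excluded)",
            f"mean consumption: {self.mean_mg_ha:8.1f} Mg/ha",
            f"total consumed:   {self.total_gg:8.1f} +/- {self.ci_gg:.1f} Gg",
        ]
        if not np.isnan(self.dnbr_r):
            lines.append(f"r vs dNBR:        {self.dnbr_r:8.2f}")
        if self.severity_table is not None:
            lines.append("-" * 46)
            lines.append("consumption by severity class (Mg/ha):")
            for cls_, row in self.severity_table.iterrows():
                lines.append(
                    f"  {cls_:<16s} {row['mean']:6.1f} ({row['sd']:.1f})  n={int(row['n'])}"
                )
        return "\n".join(lines)


def _inclusion_mask(spec: GridSpec, fire_polygon, exclusions=()) -> tuple[np.ndarray, int]:
    X, Y = spec.cell_centers()
    inside = shapely.contains_xy(fire_polygon, X.ravel(), Y.ravel()).reshape(spec.shape)
    excluded = np.zeros(spec.shape, bool)
    for ex in exclusions or ():
        excluded |= shapely.contains_xy(ex, X.ravel(), Y.ravel()).reshape(spec.shape)
    n_excluded = int((inside & excluded).sum())
    return inside & ~excluded, n_excluded


def summarize_fire(consumption: np.ndarray, spec: GridSpec, fire_polygon,
                   pct_rmse: float, exclusions=(), fire_id: str = "fire",
                   severity: np.ndarray | None = None,
                   severity_thresholds=DEFAULT_SEVERITY_THRESHOLDS) -> ConsumptionReport:
    """Summarize mapped consumption within a fire perimeter.

    Cells are included by the cell-center-in-polygon rule, consistent with
    the fire-history rasterization; exclusion polygons (e.g. an older fire
    nested inside the perimeter) remove cells from all statistics.  The
    total is the sum of per-cell consumption times the cell area derived
    from the grid spec, converted to Gg; the confidence interval is
    total x %RMSE / 100.
    """
    include, n_excluded = _inclusion_mask(spec, fire_polygon, exclusions)
    include &= ~np.isnan(consumption)
    n = int(include.sum())
    if n == 0:
        raise ValueError("no grid cells inside the fire perimeter")
    vals = consumption[include]
    mean = float(vals.mean())
    total_gg = float(vals.sum() * spec.cell_area_ha / 1000.0)  # Mg -> Gg
    ci = abs(total_gg) * pct_rmse / 100.0
    sev_table = None
    r = np.nan
    if severity is not None:
        sev_vals = severity[include]
        sev_table = severity_summary(vals, classify_severity(sev_vals, severity_thresholds))
        r = correlate_dnbr(vals, sev_vals)
    return ConsumptionReport(
        fire_id=fire_id,
        mean_mg_ha=mean,
        total_gg=total_gg,
        ci_gg=ci,
        n_cells=n,
        n_excluded=n_excluded,
        severity_table=sev_table,
        dnbr_r=r,
        pct_rmse=pct_rmse,
    )


def classify_severity(dnbr, thresholds=DEFAULT_SEVERITY_THRESHOLDS) -> np.ndarray:
    """Map a dNBR-like index to the four burn-severity classes (0..3).

    NaN severity stays NaN (outside the burn)."""
    d = np.asarray(dnbr, float)
    out = np.full(d.shape, np.nan)
    valid = ~np.isnan(d)
    out[valid] = np.digitize(d[valid], thresholds)
    return out


def severity_summary(consumption, severity_class) -> pd.DataFrame:
    """Mean and SD of consumption per burn-severity class.

    Returns a frame indexed by class name with columns mean, sd, n; empty
    classes appear with n = 0 and NaN statistics.
    """
    cons = np.asarray(consumption, float)
    cls_ = np.asarray(severity_class, float)
    rows = {}
    for i, name in enumerate(SEVERITY_CLASSES):
        m = cls_ == i
        if m.sum() == 0:
            rows[name] = {"mean": np.nan, "sd": np.nan, "n": 0}
        else:
            rows[name] = {
                "mean": float(cons[m].mean()),
                "sd": float(cons[m].std(ddof=1)) if m.sum() > 1 else 0.0,
                "n": int(m.sum()),
            }
    return pd.DataFrame.from_dict(rows, orient="index")


def correlate_dnbr(consumption, dnbr) -> float:
    """Pearson correlation between consumption and the severity index.

    NaN where undefined (fewer than 3 paired cells or zero variance)."""
    c = np.asarray(consumption, float).ravel()
    d = np.asarray(dnbr, float).ravel()
    if c.shape != d.shape:
        raise ValueError("grids must be aligned")
    ok = ~(np.isnan(c) | np.isnan(d))
    c, d = c[ok], d[ok]
    if c.size < 3 or c.std() == 0 or d.std() == 0:
        return np.nan
    return float(np.corrcoef(c, d)[0, 1])
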