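"""Surface-fuel accumulation versus years since fire.

Burned pixels of a predicted fuel map are pooled by integer years since
fire and fitted with the three-parameter offset-exponential accumulation
model

    L(t) = A + (L0 - A) * exp(-k t),

where A is the stable (asymptotic) fuel load, L0 the load immediately
after fire, and k the recovery rate per year.  The fit is nonlinear least
squares over per-pixel (YSF, load) pairs with every pixel weighted
equally; R^2 is 1 - SSE/SST on those pairs, and a linear fit is reported
alongside for comparison.  The conceptual lineage is the classic
negative-exponential litter-accumulation model (Olson).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .consumption import FuelGrid
from .firehistory import FireHistoryGrids
from .grids import require_aligned
from .synthetic import accumulation_curve


def pool_by_ysf(fuel: FuelGrid, history: FireHistoryGrids) -> pd.DataFrame:
    """Per-pixel (ysf, load) pairs over burned pixels (NPF >= 1).

    Returns a DataFrame with columns ``ysf`` (integer years) and ``load``;
    never-burned and masked pixels are excluded.  Raises if nothing burned.
    """
    require_aligned(fuel.spec, history.spec, "fuel and history grids")
    burned = history.burned_mask() & ~np.isnan(fuel.load) & ~np.isnan(history.ysf)
    if not burned.any():
        raise ValueError("no burned pixels to pool")
    return pd.DataFrame(
        {"ysf": history.ysf[burned].astype(int), "load": fuel.load[burned]}
    )


def ysf_bin_counts(pairs: pd.DataFrame) -> pd.Series:
    """Pixel counts per integer YSF (the bottom bars of the trend figure)."""
    return pairs.groupby("ysf")["load"].size()


@dataclass
class AsymptoticFitResults:
    """Fitted accumulation curve and its diagnostics."""

    asymptote: float  # A, Mg/ha
    initial_load: float  # L0, Mg/ha
    rate: float  # k, 1/yr
    r_squared: float
    linear_r_squared: float
    n_pixels: int
    bin_counts: pd.Series = field(repr=False, default=None)
    converged: bool = True
    linear_coef: tuple = (np.nan, np.nan)  # slope, intercept fallback

    def predict(self, t) -> np.ndarray:
        return accumulation_curve(t, self.asymptote, self.initial_load, self.rate)

    def time_to_stability(self, fraction: float = 0.95) -> float:
        """Years until the gap to the asymptote has closed by *fraction*:
        t* = -ln(1 - fraction)/k."""
        if not self.converged or self.rate <= 0:
            return np.nan
        if not 0 < fraction < 1:
            raise ValueError("fraction must be in (0, 1)")
        return float(-np.log(1.0 - fraction) / self.rate)

    def summary(self) -> str:
        lines = [
            "Asymptotic fuel accumulation fit",
            "=" * 46,
            f"n pixels:            {self.n_pixels}",
            f"converged:           {self.converged}",
            f"asymptote A:         {self.asymptote:8.1f} Mg/ha",
            f"initial load L0:     {self.initial_load:8.1f} Mg/ha",
            f"rate k:              {self.rate:8.3f} /yr",
            f"R^2 (asymptotic):    {self.r_squared:8.3f}",
            f"R^2 (linear):        {self.linear_r_squared:8.3f}",
            f"t95 (to stability):  {self.time_to_stability():8.1f} yr",
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "asymptote": self.asymptote,
            "initial_load": self.initial_load,
            "rate": self.rate,
            "r_squared": self.r_squared,
            "linear_r_squared": self.linear_r_squared,
            "n_pixels": self.n_pixels,
            "converged": self.converged,
            "time_to_stability_95": self.time_to_stability(),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=float)

    def plot(self, pairs: pd.DataFrame | None = None, ax=None):
        """Fitted accumulation curve, optionally over the pooled pixels."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if pairs is not None:
            ax.plot(pairs["ysf"], pairs["load"], ".", ms=2, alpha=0.2,
                    color="gray", label="pixels")
        tmax = float(pairs["ysf"].max()) if pairs is not None else 40.0
        t = np.linspace(0, tmax, 200)
        ax.plot(t, self.predict(t), "r-",
                label=f"A={self.asymptote:.0f}, k={self.rate:.2f}/yr")
        ax.set_xlabel("years since fire")
        ax.set_ylabel("total surface fuel (Mg/ha)")
        ax.legend()
        return ax


class AsymptoticAccumulationModel:
    """Three-parameter asymptotic regression of fuel load on years since fire.

    Parameters
    ----------
    ysf : array-like
        Years since fire per pixel.
    load : array-like
        Fuel load (Mg/ha) per pixel.
    """

    def __init__(self, ysf, load):
        self.ysf = np.asarray(ysf, float)
        self.load = np.asarray(load, float)
        if self.ysf.shape != self.load.shape:
            raise ValueError("ysf and load must have equal length")
        ok = ~(np.isnan(self.ysf) | np.isnan(self.load))
        self.ysf, self.load = self.ysf[ok], self.load[ok]

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame) -> "AsymptoticAccumulationModel":
        return cls(pairs["ysf"], pairs["load"])

    @classmethod
    def from_grids(cls, fuel: FuelGrid, history: FireHistoryGrids):
        model = cls.from_pairs(pool_by_ysf(fuel, history))
        return model

    def _linear_fit(self) -> tuple[float, float, float]:
        slope, intercept = np.polyfit(self.ysf, self.load, 1)
        pred = slope * self.ysf + intercept
        sst = float(np.sum((self.load - self.load.mean()) ** 2))
        sse = float(np.sum((self.load - pred) ** 2))
        r2 = 1.0 - sse / sst if sst > 0 else 0.0
        return float(slope), float(intercept), r2

    def fit(self, k_init: float = 0.2) -> AsymptoticFitResults:
        """Nonlinear least squares with data-driven initialization.

        Start values: A at the 95th load percentile, L0 at the mean load of
        the smallest YSF, k at *k_init*; k is constrained positive.  On
        non-convergence (or fewer than 3 distinct YSF values) the result is
        flagged and carries the linear fallback.
        """
        t, y = self.ysf, self.load
        slope, intercept, lin_r2 = self._linear_fit()
        bins = pd.DataFrame({"ysf": t, "load": y}).groupby("ysf")["load"].size()
        if len(np.unique(t)) < 3:
            return AsymptoticFitResults(
                asymptote=np.nan, initial_load=np.nan, rate=np.nan,
                r_squared=np.nan, linear_r_squared=lin_r2, n_pixels=len(y),
                bin_counts=bins, converged=False, linear_coef=(slope, intercept),
            )
        a0 = float(np.percentile(y, 95))
        l0 = float(y[t == t.min()].mean())
        try:
            popt, _ = curve_fit(
                accumulation_curve, t, y,
                p0=[a0, l0, k_init],
                bounds=([-np.inf, -np.inf, 1e-8], [np.inf, np.inf, 10.0]),
                maxfev=20000,
            )
            A, L0, k = (float(v) for v in popt)
            pred = accumulation_curve(t, A, L0, k)
            sst = float(np.sum((y - y.mean()) ** 2))
            sse = float(np.sum((y - pred) ** 2))
            r2 = 1.0 - sse / sst if sst > 0 else 0.0
            converged = True
        except RuntimeError:
            A = L0 = k = np.nan
            r2 = np.nan
            converged = False
        degenerate = converged and (np.std(y) == 0)
        if degenerate:
            converged = False
        return AsymptoticFitResults(
            asymptote=A, initial_load=L0, rate=k,
            r_squared=r2, linear_r_squared=lin_r2,
            n_pixels=len(y), bin_counts=bins, converged=converged,
            linear_coef=(slope, intercept),
        )


def fit_asymptotic(ysf, load, k_init: float = 0.2) -> AsymptoticFitResults:
    """Functional wrapper: fit the accumulation model to (YSF, load) pairs."""
    return AsymptoticAccumulationModel(ysf, load).fit(k_init=k_init)
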