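"""Random-forest fuel-load models with variable selection and OOB evaluation.

The modelling interface follows the statsmodels convention: build a
:class:`FuelLoadModel` from a response vector and a feature table, call
``fit()``, and receive a :class:`FuelLoadResults` carrying the retained
predictors with their normalized importances (MIR, scaled so the most
important variable scores 1 and the least 0), the out-of-bag predictions,
and the error metrics used throughout the mapping stage (variance
explained, MBE, RMSE, %RMSE).

The fitting protocol:

1. drop one member of every cluster of highly correlated predictors
   (|Pearson r| > 0.9), keeping the most important representative;
2. score the survivors by permutation importance, normalize to MIR, and
   form nested candidate subsets at MIR thresholds 0, 0.1, ..., 0.9;
3. keep the subset minimizing OOB mean squared error;
4. fit the final regression forest with ntree = 500 and
   mtry = floor(p/3) (>= 1), evaluating on out-of-bag predictions only.

Step 2-3 reconstruct the behaviour of MIR-threshold model selection as
commonly practised with regression forests; the reconstruction is
documented in the methods note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.inspection import permutation_importance

MIR_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))


def evaluate(observed, predicted) -> dict[str, float]:
    """Error metrics for observed vs predicted loads.

    MBE = mean(pred) - mean(obs); RMSE = sqrt(mean((obs - pred)^2));
    %RMSE = 100 * RMSE / mean(obs) (NaN-flagged when mean(obs) = 0);
    varexp = 100 * (1 - MSE / var(obs)).
    """
    obs = np.asarray(observed, float)
    pred = np.asarray(predicted, float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted must have equal length")
    resid = obs - pred
    mse = float(np.mean(resid**2))
    rmse = float(np.sqrt(mse))
    mbe = float(pred.mean() - obs.mean())
    mean_obs = float(obs.mean())
    pct_rmse = 100.0 * rmse / mean_obs if mean_obs != 0 else np.nan
    var_obs = float(np.var(obs))
    varexp = 100.0 * (1.0 - mse / var_obs) if var_obs > 0 else np.nan
    return {"varexp": varexp, "mbe": mbe, "rmse": rmse, "pct_rmse": pct_rmse}


def _default_mtry(p: int) -> int:
    return max(1, p // 3)


def _make_forest(p: int, ntree: int, mtry: int | None, seed: int) -> RandomForestRegressor:
    return RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry if mtry is not None else _default_mtry(p),
        oob_score=True,
        bootstrap=True,
        random_state=int(seed),
        n_jobs=1,
    )


def correlation_filter(features: pd.DataFrame, threshold: float = 0.9,
                       response=None, seed: int = 0) -> list[str]:
    """Retain one representative per cluster of highly correlated predictors.

    Candidates are ranked (when *response* is given) by the impurity
    importance of a single forest fit on all of them, then greedily kept if
    their |Pearson r| with every already-kept column is <= *threshold*.
    Ties in importance break alphabetically; without a response the ranking
    is alphabetical, making the pass deterministic either way.  Constant
    columns (undefined r) are dropped with a warning.  The returned list
    preserves the original column order.
    """
    if features.shape[1] < 2:
        return list(features.columns)
    X = features.astype(float)
    const = [c for c in X.columns if X[c].nunique() <= 1]
    if const:
        warnings.warn(f"dropping constant columns {const}", stacklevel=2)
        X = X.drop(columns=const)
    if X.shape[1] == 0:
        return []
    if response is not None and X.shape[1] >= 2:
        rf = RandomForestRegressor(n_estimators=200, random_state=int(seed), n_jobs=1)
        rf.fit(X.to_numpy(), np.asarray(response, float))
        score = pd.Series(rf.feature_importances_, index=X.columns)
    else:
        score = pd.Series(0.0, index=X.columns)
    order = sorted(X.columns, key=lambda c: (-score[c], c))
    corr = X.corr().abs()
    kept: list[str] = []
    for col in order:
        if all(corr.loc[col, k] <= threshold for k in kept):
            kept.append(col)
    return [c for c in features.columns if c in kept]


def select_variables(features: pd.DataFrame, response, seed: int = 0,
                     ntree: int = 500, n_repeats: int = 5):
    """MIR-threshold variable selection.

    Permutation importances of a full forest are normalized to MIR scores
    in [0, 1]; nested subsets keep variables with MIR >= each threshold in
    {0, 0.1, ..., 0.9}; the subset whose forest minimizes OOB MSE wins.
    Returns ``(selected columns, MIR series over all candidates)``.
    """
    y = np.asarray(response, float)
    cols = list(features.columns)
    if len(cols) < 2:
        return cols, pd.Series(1.0, index=cols)
    X = features.to_numpy(float)
    rf = _make_forest(len(cols), ntree, None, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rf.fit(X, y)
    imp = permutation_importance(
        rf, X, y, n_repeats=n_repeats, random_state=int(seed), n_jobs=1
    ).importances_mean
    imp = np.maximum(imp, 0.0)
    if imp.max() > 0:
        mir = pd.Series(imp / imp.max(), index=cols)
    else:
        mir = pd.Series(0.0, index=cols)

    best_subset, best_mse = cols, np.inf
    for thr in MIR_THRESHOLDS:
        subset = [c for c in cols if mir[c] >= thr]
        if len(subset) < 1 or len(subset) == len(cols) and thr > 0:
            continue
        sub_rf = _make_forest(len(subset), ntree, None, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sub_rf.fit(features[subset].to_numpy(float), y)
        mse = float(np.mean((y - sub_rf.oob_prediction_) ** 2))
        if mse < best_mse - 1e-12:
            best_subset, best_mse = subset, mse
    return best_subset, mir


@dataclass
class FuelLoadResults:
    """Fitted fuel-load forest: retained predictors, importances, OOB skill."""

    response_name: str
    features: list[str]
    mir: pd.Series
    ntree: int
    mtry: int
    seed: int
    oob_predicted: np.ndarray
    observed: np.ndarray
    metrics: dict[str, float]
    estimator: RandomForestRegressor = field(repr=False, default=None)
    model: "FuelLoadModel" = field(repr=False, default=None)

    @property
    def varexp(self) -> float:
        return self.metrics["varexp"]

    @property
    def rmse(self) -> float:
        return self.metrics["rmse"]

    @property
    def mbe(self) -> float:
        return self.metrics["mbe"]

    @property
    def pct_rmse(self) -> float:
        return self.metrics["pct_rmse"]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.features if c not in features.columns]
        if missing:
            raise KeyError(f"missing predictor columns {missing}")
        return self.estimator.predict(features[self.features].to_numpy(float))

    def summary(self) -> str:
        lines = [
            f"Fuel load model: {self.response_name}",
            "=" * 46,
            f"n plots:        {len(self.observed)}",
            f"ntree:          {self.ntree}",
            f"mtry:           {self.mtry} (floor(p/3), p = {len(self.features)})",
            f"OOB varexp:     {self.varexp:8.1f} %",
            f"MBE:            {self.mbe:8.2f} Mg/ha",
            f"RMSE:           {self.rmse:8.2f} Mg/ha",
            f"%RMSE:          {self.pct_rmse:8.1f} %",
            "-" * 46,
            "retained predictors (MIR):",
        ]
        sel = self.mir[self.features].sort_values(ascending=False)
        for name, score in sel.items():
            lines.append(f"  {name:<12s} {score:5.2f}")
        return "\n".join(lines)

    def plot_observed_vs_predicted(self, ax=None):
        """OOB predicted vs observed loads with the 1:1 line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.observed, self.oob_predicted, "o", ms=4, alpha=0.6)
        lim = [0, max(self.observed.max(), self.oob_predicted.max()) * 1.05]
        ax.plot(lim, lim, "k-", lw=1)
        ax.set_xlabel(f"observed {self.response_name} (Mg/ha)")
        ax.set_ylabel("OOB predicted (Mg/ha)")
        ax.set_title(f"varexp {self.varexp:.0f}%, RMSE {self.rmse:.1f} Mg/ha")
        return ax

    def save(self, path) -> None:
        """Serialize the model description (predictors, MIR, metrics, refit
        recipe) as JSON; the forest itself is refit from seed on load."""
        payload = {
            "response_name": self.response_name,
            "features": self.features,
            "mir": {k: float(v) for k, v in self.mir.items()},
            "ntree": self.ntree,
            "mtry": self.mtry,
            "seed": self.seed,
            "metrics": self.metrics,
            "observed": np.asarray(self.observed).tolist(),
            "oob_predicted": np.asarray(self.oob_predicted).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


class FuelLoadModel:
    """Random-forest regression of plot fuel loads on landscape metrics.

    Parameters
    ----------
    endog : array-like
        Plot fuel loads (Mg/ha), the response.
    exog : DataFrame
        Candidate predictor table (strata metrics, topographic metrics,
        fire-history variables), one row per plot, no missing values.
    response_name : str
        Label used in reports.
    """

    def __init__(self, endog, exog: pd.DataFrame, response_name: str = "fuel"):
        self.endog = np.asarray(endog, float)
        if not isinstance(exog, pd.DataFrame):
            raise TypeError("exog must be a pandas DataFrame of named features")
        if len(self.endog) != len(exog):
            raise ValueError("endog and exog lengths differ")
        if exog.isna().any().any():
            raise ValueError("feature table contains missing values; apply fill policy first")
        self.exog = exog.astype(float)
        self.response_name = response_name

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, response: str,
                       feature_columns=None) -> "FuelLoadModel":
        features = (
            data[feature_columns]
            if feature_columns is not None
            else data.drop(columns=[response])
        )
        return cls(data[response], features, response_name=response)

    def fit(self, ntree: int = 500, mtry: int | None = None, seed: int = 0,
            select: bool = True, corr_threshold: float = 0.9) -> FuelLoadResults:
        """Run the filter/select/fit protocol and return results.

        With ``select=False`` the forest uses every non-collinear candidate.
        Requires at least 10 plots.
        """
        if len(self.endog) < 10:
            raise ValueError("need at least 10 plots to fit a fuel model")
        kept = correlation_filter(self.exog, threshold=corr_threshold,
                                  response=self.endog, seed=seed)
        X = self.exog[kept]
        if select and len(kept) >= 2:
            selected, mir = select_variables(X, self.endog, seed=seed, ntree=ntree)
        else:
            selected, mir = kept, pd.Series(1.0, index=kept)
        p = len(selected)
        m = mtry if mtry is not None else _default_mtry(p)
        rf = _make_forest(p, ntree, m, seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rf.fit(X[selected].to_numpy(float), self.endog)
        oob = rf.oob_prediction_
        return FuelLoadResults(
            response_name=self.response_name,
            features=selected,
            mir=mir,
            ntree=ntree,
            mtry=m,
            seed=seed,
            oob_predicted=oob,
            observed=self.endog,
            metrics=evaluate(self.endog, oob),
            estimator=rf,
            model=self,
        )
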