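# Methods

This note documents the models, estimators, numerical conventions, and
design decisions behind fuelscape, and what the synthetic-data validation
does and does not demonstrate.

## Fuel accumulation model

Surface fuel recovery after fire is modelled with the offset exponential

    L(t) = A + (L0 − A) · exp(−k t)

where `t` is years since fire (YSF), `A` the stable (asymptotic) load,
`L0` the load immediately after fire, and `k` the recovery rate. This is
the classic negative-exponential litter-accumulation form (Olson lineage):
litterfall input balances decomposition as the stand recovers. Fitting is
nonlinear least squares (`scipy.optimize.curve_fit`) over per-pixel
(YSF, load) pairs, every pixel weighted equally; we deliberately do not fit
bin means, because the per-YSF pixel distributions carry the information
about scatter. Initialization is data-driven — `A` at the 95th load
percentile, `L0` at the mean load of the smallest YSF, `k = 0.2 yr⁻¹` —
and `k` is constrained positive. Reported R² is `1 − SSE/SST` on the fitted
pairs, which makes the asymptotic and linear fits directly comparable.
Degenerate inputs (fewer than 3 distinct YSF values, zero load variance)
and optimizer non-convergence return a flagged result carrying the linear
fallback. Time to stability is `t* = −ln(1 − f)/k`, the time to close a
fraction `f` (default 95%) of the gap to the asymptote.

Several self-starting asymptotic parameterizations exist; the offset
exponential above is the one implemented, and its parameters are what the
recovery checks measure.

## Field fuel estimators

Downed woody load from a planar-intercept transect:

    W [Mg/ha] = (π²/8) · G · a · c · (Σ d² [cm²]) / L [m]

with specific gravity `G`, nonhorizontal-lean correction `a`, slope
correction `c = sqrt(1 + (slope%/100)²)`, and sampled length `L`. The fine
classes (1-h, 10-h, 100-h) use `n · QMD²` at class quadratic-mean
diameters; the 1000-h class sums individual piece diameters. Defaults:
`G` = 0.48/0.48/0.40/0.40, `a` = 1.13/1.13/1.13/1.00,
QMD = 0.4/1.3/3.8 cm, segment lengths 1.83/1.83/3.66/15.24 m, litter and
duff bulk densities 44 and 88 kg m⁻³. These are canonical composite-conifer
values; published composites vary by forest type, so every constant is a
configurable table (YAML) rather than a hard-coded truth. Litter/duff load
is mean station depth × bulk density. Available canopy fuel is foliage plus
half of fine-branch biomass of **live** trees only (the portion consumable
in crown fire), per-species log-linear allometries
`ln B = b0 + b1 ln DBH`; the bundled species table is synthetic (the
interface, not the coefficients, is the contract — real projects supply
their own table).

## Strata and terrain metrics

Nonground returns are > 0 m above ground, canopy > 2 m, understory
strictly between. A return at exactly 2.00 m belongs to neither stratum
under the strict definitions; it is assigned to canopy so that no return is
silently dropped. Heights come from linear interpolation within a Delaunay
triangulation of ground returns (nearest-ground fallback outside the hull)
or bilinear interpolation of a supplied DTM. Statistics: STD with the n−1
denominator; skewness `m₃/m₂^1.5` and kurtosis `m₄/m₂²` from
bias-uncorrected sample moments (kurtosis is not excess); percentiles use
linear interpolation at rank `p(n−1)/100 + 1` (numpy's default). These
estimator variants differ across lidar toolchains; ours are fixed and
documented for reproducibility. Cells or plots with an empty stratum carry
zero-filled metrics plus an `empty.*` mask layer — forests cannot ingest
missing cells, and the mask preserves auditability. Grids snap to
multiples of the cell size; binning is half-open low-inclusive. Plot
footprints are circles (10 m radius for overstory plots; 7.62 m around a
transect midpoint, the minimal circle containing a 15.24-m segment — the
radius is configurable since protocols vary).

Terrain: Horn 3×3 gradients for slope/aspect (aspect is degrees clockwise
from north of the downslope direction; flat cells carry a NaN sentinel);
Zevenbergen–Thorne curvatures in 1/m with total curvature `−2(D+E)`;
heat-load index per McCune–Keon with aspect folded about the 225° axis;
TPI = center − neighborhood mean and TRI = RMS deviation of neighbors from
center over a 3×3 window (configurable); TRASP and SCOSA/SSINA from slope
in degrees. Flat cells get neutral fills (TRASP 0.5, SCOSA = SSINA = 0) so
undefined aspects do not propagate into model features. Edge cells are
computed on an edge-replicated pad and flagged in an `edge` layer; analytic
guarantees apply to interior cells.

## Fire history

Rasterization uses the cell-center coverage rule (a cell belongs to a fire
iff the polygon covers its center): deterministic and consistent with the
consumption summaries. Fires in the reference year count with YSF 0.
Never-burned cells are NPF 0 with missing YSF; as a model feature, missing
YSF is filled with record length + 1 ("at least this long unburned") plus
the burned mask — forests need finite values, and the choice is recorded
because observational products are ambiguous here.

## Random-forest fuel model

Regression forests with `ntree = 500` and `mtry = ⌊p/3⌋` (floored, minimum
1), evaluated exclusively on out-of-bag predictions:
`varexp = 100(1 − MSE_oob/var(y))`, `MBE = mean(pred) − mean(obs)`,
`RMSE = sqrt(mean((obs − pred)²))`, `%RMSE = 100·RMSE/mean(obs)`. Before
fitting, one representative is kept from every cluster of predictors with
|Pearson r| > 0.9 (representatives ranked by the impurity importance of a
single forest on all candidates, ties alphabetical — one forest rather
than per-variable univariate forests, same intent at a fraction of the
cost). Variable selection normalizes permutation importances to MIR scores
(max = 1), forms nested subsets at MIR thresholds 0, 0.1, …, 0.9, and
keeps the subset minimizing OOB MSE. This reconstructs the familiar
MIR-threshold selection behaviour of R-side forest utilities; the original
routine's internal criterion is not published in detail, so ours is a
documented reconstruction, with permutation importance computed on the
training data (scikit-learn) rather than per-tree OOB permutation.

## Consumption mapping

Fuel maps are per-cell forest predictions on the metric grids (negative
predictions clamped at zero — a no-op safeguard, as forests cannot predict
below the training minimum; fully empty cells stay missing). Consumption is
`pre − post` with negative values retained: apparent accumulation is
real signal (unburned or regrowing areas). Fire summaries include cells by
center-in-polygon, minus exclusion polygons; the total is
`Σ cell consumption × cell area` (0.04 ha at 20 m, derived from the grid
spec rather than hard-coded) reported in Gg, with confidence interval
`total × %RMSE/100` from the fuel model's out-of-bag error. Severity
classes come from a supplied dNBR-like raster via configurable thresholds
(defaults 100/270/440); per-class means/SDs and the Pearson correlation
between consumption and severity are reported.

## The synthetic landscape

The generator emulates a fire-prone dry-conifer plateau: elevation rises
along a configurable gradient with smoothed low-frequency relief; the
stable surface fuel load increases linearly with elevation
(A = 110 Mg ha⁻¹ at the 2300 m reference, 0.13 Mg ha⁻¹ per m — stable
loads of roughly 90–130 Mg ha⁻¹ across the landscape); burned cells follow
the accumulation curve with `L0 = 15 Mg ha⁻¹` and `k = 0.25 yr⁻¹` (95% of
the gap closed at ~12 years); mean-one lognormal noise (σ = 0.25)
represents unexplainable fine-scale heterogeneity. Woody fuels are 55% of
the surface total. Canopy fuel is proportional to a smooth canopy-cover
surface (up to 16 Mg ha⁻¹ at full cover, lognormal σ = 0.30) and —
deliberately — independent of years since fire, reflecting the reported
null relationship between canopy fuel and time since fire; this is an
assumption, not a derived result. Fire-history years are spread evenly
(shuffled) across the record window so YSF coverage spans it.

Point clouds: per-cell return counts are Poisson at the configured pulse
density (default 8 m⁻²); each return is canopy with probability equal to
canopy cover (placed uniformly in a crown envelope between 40% and 100% of
the cell tree height — a simple vertical envelope standing in for conical
crowns), understory with probability equal to understory density
(0.03–1.9 m), else ground exactly on the terrain surface. Occlusion,
waveform effects, and per-species crown shapes are not simulated.

Transect sampling inverts the planar-intercept equation at the class QMDs
for expected counts (Poisson-realized); 1000-h pieces are compound-Poisson
with diameters 7.62 cm + Exponential(2.5 cm); litter/duff depths are
mean-preserving gamma draws. All of these are unbiased for the generating
loads by construction, which the Monte-Carlo round-trip tests verify
(the 1000-h class has the largest sampling variance — few pieces per
transect — so its round trip is the loosest).

The consumption fire reduces surface fuel by `0.08 × dNBR + 2` Mg ha⁻¹
plus Gaussian noise (SD 16), clamped by available fuel; unburned cells
accrue a small litterfall gain (negative consumption). Understory returns
are removed with probability equal to the consumed fuel fraction; canopy
returns are thinned only above a high-severity threshold (dNBR 440). The
noise level was chosen so the generator's consumption–severity correlation
is moderate (~0.2–0.45), matching the regime where severity indices are
only partial predictors of surface fuel consumption.

Randomness: one global seed fans out to fixed named substreams
(terrain/fires/fuels/clouds/…), so components regenerate independently and
all outputs are bitwise reproducible for a given configuration.

## Problem sizes

The bundled demo configuration uses a 600 m × 600 m landscape (30 × 30
cells at 20 m), pulse density 2 m⁻², 120 plots, and 6 fires — sizes chosen
so the full pipeline, including a 500-tree forest with variable selection,
completes in well under ten minutes on a single CPU while leaving enough
burned pixels (several hundred) for stable accumulation fits. Planted-
signal checks use n = 1600 samples; accumulation-recovery checks use 4000
pixels. Scaling any of these up changes no interface.

## What the validation shows — and what it does not

Passing tests demonstrate internal correctness (estimators match closed
forms and brute-force oracles exactly; round trips are unbiased) and
end-to-end identifiability under the generator's assumptions: with
fuel-structure signal present in the returns, the pipeline recovers the
planted accumulation asymptote within a few percent. They do not
demonstrate accuracy on real acquisitions, where occlusion, classification
error, registration, and fuel types outside the generator's structure all
matter.

Known limitations:

* **Differencing attenuation.** Consumption maps made by differencing two
  independently predicted forest maps are biased toward zero (each map
  regresses toward its training mean), and with the Table-2-style metric
  vocabulary — which contains no absolute return-count feature — the
  mapped consumption total recovers roughly 60–80% of the true consumed
  mass on the synthetic landscape. The per-fire totals and CIs are exact
  *bookkeeping* of the mapped values; their calibration against true
  consumed mass is limited by this attenuation, a property of the method
  itself, not of the implementation.
* The understory stratum is the dominant fuel signal in the generator;
  real surface fuels under closed canopies are occluded and harder.
* The forest's OOB varexp on planted signals sits a few points below the
  population R² at finite n (estimation variance); recovery checks use the
  documented ±10-point band.
* Canopy-fuel dynamics with time since fire are not modelled (held
  constant by assumption, matching the reported null result).
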