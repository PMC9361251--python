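# fuelscape

Landscape-scale forest **fuel load mapping, fire consumption estimation, and
post-fire fuel accumulation analysis** from airborne lidar, terrain, and fire
history data — with a fully synthetic landscape generator so that every stage
of the workflow can be validated against known ground truth.

The package is aimed at fire ecologists and remote-sensing analysts who work
with the standard ingredients of modern fuel mapping: height-normalized lidar
point clouds, 20-m strata-metric grids, planar-intercept fuel transects,
allometric canopy fuel estimates, rasterized fire perimeters, and
random-forest regression.

## The workflow

1. **Strata metrics.** Classified lidar returns are normalized to heights
   above ground and summarized per 20-m cell (and per circular plot
   footprint) into canopy (>2 m) and understory (0–2 m) statistics — MAX,
   AVG, STD, skewness `m₃/m₂^1.5`, kurtosis `m₄/m₂²`, percentiles P05–P95 —
   plus height-band return densities D00–D07 and D00.lt2–D04.lt2.
2. **Terrain metrics.** From the DTM: slope/aspect (Horn), Zevenbergen–Thorne
   curvatures, heat-load index (McCune–Keon), TPI/TRI, TRASP
   `(1 − cos(aspect − 30°))/2`, and the slope–aspect interactions
   SCOSA/SSINA.
3. **Fire history.** Perimeter polygons with years → years-since-fire (YSF)
   and number-of-past-fires (NPF) grids by cell-center coverage.
4. **Field fuels.** Tree lists → available canopy fuel (foliage + ½ fine
   branch, Mg ha⁻¹); transect tallies → downed woody loads by timelag class
   via the planar-intercept estimator
   `W = (π²/8)·G·a·c·Σd²/L`, plus litter/duff from depth × bulk density.
5. **Fuel model.** A random-forest regression (`ntree = 500`,
   `mtry = ⌊p/3⌋`) of plot loads on the metric vocabulary, after an
   |r| > 0.9 collinearity filter and MIR-threshold variable selection;
   skill is reported from out-of-bag predictions (varexp, MBE, RMSE, %RMSE).
6. **Maps, consumption, trends.** The fitted forest predicts 20-m fuel maps;
   differencing pre-/post-fire maps gives consumption (negative values —
   apparent accumulation — are kept); totals per fire come with a
   `total × %RMSE` confidence interval, severity-class summaries, and the
   Pearson correlation against a dNBR-like severity raster. Burned pixels
   pooled by YSF are fitted with the three-parameter asymptotic accumulation
   model `L(t) = A + (L₀ − A)·e^(−kt)`.

The synthetic module generates all inputs with known truth: terrain with an
elevation-driven productivity gradient, overlapping historical fire
perimeters, fuel fields following the accumulation curve, truth-consistent
tree lists and Poisson transect tallies, classified point clouds, and a
severity-driven fire.

## Worked example

```python
from fuelscape import pipeline, consumption as cons, firehistory as fh, lidar, terrain
from fuelscape.fuelmodel import FuelLoadModel
from fuelscape.trends import AsymptoticAccumulationModel, pool_by_ysf

cfg = pipeline.default_config(seed=1)          # 600 m x 600 m demo landscape
sim = pipeline.simulate_landscape(cfg)
hist = fh.rasterize_history(sim.fires, sim.terrain.spec, sim.ref_year)
cloud = lidar.normalize_heights(*sim.pre_cloud,
                                dtm=(sim.terrain.spec, sim.terrain.elevation))
feats = pipeline.build_feature_table(sim, cloud, hist)
obs = pipeline.field_observations(sim)

res = FuelLoadModel(obs["total_surface"], feats, "total_surface").fit(seed=1)
print(res.summary())
```

```
Fuel load model: total_surface
==============================================
n plots:        120
ntree:          500
mtry:           3 (floor(p/3), p = 10)
OOB varexp:         59.4 %
MBE:                1.07 Mg/ha
RMSE:              19.64 Mg/ha
%RMSE:              20.4 %
----------------------------------------------
retained predictors (MIR):
  D01           1.00
  YSF           0.43
  ...
```

The forest explains 59% of out-of-bag variance in total surface fuel; the
top predictors are understory return density (D01), years since fire, and
elevation — the understory returns see the surface fuel directly, and fire
history and the productivity gradient explain the rest. Applying the model
across the landscape and pooling burned pixels by years since fire:

```python
grid = lidar.metrics_grid(cloud, sim.terrain.spec)
for name, layer in terrain.terrain_metrics(sim.terrain.spec, sim.terrain.elevation).items():
    if name != "edge":
        grid.layers.setdefault(name, layer)
fuel = cons.predict_grid(res, grid, hist, year=2019)
fit = AsymptoticAccumulationModel.from_pairs(pool_by_ysf(fuel, hist)).fit()
print(fit.summary())
```

```
Asymptotic fuel accumulation fit
==============================================
n pixels:            562
converged:           True
asymptote A:            103.2 Mg/ha
initial load L0:         31.9 Mg/ha
rate k:                 0.302 /yr
R^2 (asymptotic):       0.743
R^2 (linear):           0.321
t95 (to stability):       9.9 yr
```

Mapped surface fuel climbs from ~32 Mg ha⁻¹ just after fire toward a stable
~103 Mg ha⁻¹, reaching 95% of the gap in about 10 years — recovering the
asymptote the generator planted (within 3% here) and the classic
negative-exponential accumulation shape.

The same stages run from the shell:

```bash
fuelscape run --config configs/demo.yaml --out demo/   # full pipeline, file-based
fuelscape run --seed 1 --out demo/                     # or from the built-in demo config
fuelscape simulate --seed 1 --out demo/                # individual stages also exposed:
fuelscape terrain --dtm demo/terrain.asc --out demo/topo
fuelscape trends --fuel demo/fuel_pre.asc --ysf demo/ysf.asc --npf demo/npf.asc --out demo/trends.json
```

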