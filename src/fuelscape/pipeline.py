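"""End-to-end orchestration: simulate -> metrics -> field calc -> fire
history -> model fit -> maps -> consumption -> accumulation trends.

Stages communicate through files in the output directory (auditable,
partially re-runnable); a stage reruns when any of its outputs is missing
or any upstream stage was rerun.  A run manifest records the config hash,
seed, per-stage timings, and every output path.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import consumption as cons
from . import fieldfuels as ff
from . import firehistory as fh
from . import lidar, synthetic, terrain
from .fuelmodel import FuelLoadModel
from .grids import write_ascii_grid
from .synthetic import SimConfig
from .trends import AsymptoticAccumulationModel, pool_by_ysf

PLOT_RADIUS_M = 10.0
TRANSECT_RADIUS_M = 7.62  # minimal circle around a 15.24-m transect


def config_hash(cfg: SimConfig) -> str:
    """Stable hash of the configuration, invariant to key ordering."""
    canon = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    stages: dict = field(default_factory=dict)  # name -> {seconds, outputs, counts}

    def to_json(self, path) -> None:
        with open(path, "w") as fh_:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "stages": self.stages}, fh_, indent=2, default=str)


# ---------------------------------------------------------------------------
# in-memory simulation of the full study system


@dataclass
class SimulatedLandscape:
    """Everything the pipeline consumes, with ground truth attached."""

    cfg: SimConfig
    terrain: synthetic.Terrain
    fires: list  # historical FireEvents (record window)
    burn: fh.FireEvent  # the consumption fire at ref_year
    severity: np.ndarray
    truth_pre: synthetic.TrueFuelField
    truth_post: synthetic.TrueFuelField
    true_consumption: np.ndarray
    pre_cloud: tuple
    post_cloud: tuple
    plots: pd.DataFrame  # plot_id, x, y, slope_pct + true component loads
    tree_lists: dict
    transects: dict
    ref_year: int


def simulate_landscape(cfg: SimConfig, ref_year: int = 2019) -> SimulatedLandscape:
    """Generate the complete synthetic study system for one seed."""
    terr = synthetic.generate_terrain(
        cfg.extent_m, cfg.cell_m, cfg.relief_m, cfg.seed,
        base_elev_m=cfg.base_elev_m, gradient=cfg.elev_gradient,
    )
    fires = synthetic.generate_fire_history(
        terr, cfg.n_fires, (cfg.record_window[0], min(ref_year, cfg.record_window[1])),
        cfg.seed,
    )
    truth = synthetic.generate_true_fuels(terr, fires, ref_year, cfg)

    # the consumption fire: one large perimeter over the landscape core
    from shapely.geometry import Point

    spec = terr.spec
    cx = 0.5 * (spec.xmin + spec.xmax)
    cy = 0.5 * (spec.ymin + spec.ymax)
    burn_poly = Point(cx, cy).buffer(
        0.42 * min(spec.xmax - spec.xmin, spec.ymax - spec.ymin), quad_segs=24
    )
    severity = synthetic.generate_severity(terr, burn_poly, cfg.seed, cfg)
    burn = fh.FireEvent(polygon=burn_poly, year=ref_year, severity=severity,
                        fire_id="BURN")

    pre_cloud = synthetic.generate_point_cloud(
        terr, truth.canopy_cover, truth.tree_height, truth.understory_density,
        cfg.pulse_density, cfg.seed, stream="cloud",
    )
    post_cloud, truth_post, true_cons = synthetic.apply_fire(
        pre_cloud, truth, severity, cfg, terrain=terr
    )

    # field plots: random cells, truth-consistent tree lists and transects
    prng = synthetic.substream(cfg.seed, "plots")
    rows_i = prng.integers(1, spec.nrows - 1, size=cfg.n_plots)
    cols_i = prng.integers(1, spec.ncols - 1, size=cfg.n_plots)
    X, Y = spec.cell_centers()
    allom = ff.AllometryTable.default()
    plot_rows, tree_lists, transects = [], {}, {}
    for i, (r, c) in enumerate(zip(rows_i, cols_i)):
        pid = f"P{i:03d}"
        slope_pct = float(prng.uniform(0, 40))
        comp = synthetic.split_surface_components(
            cfg, truth.woody_1_1000h[r, c], truth.litter_duff[r, c]
        )
        tree_lists[pid] = synthetic.generate_tree_list(
            cfg.plot_area_ha, float(truth.canopy_fuel[r, c]), allom,
            seed=int(cfg.seed * 100003 + i) % (2**31),
        )
        transects[pid] = [
            synthetic.sample_transect(
                comp, slope_pct, seed=int(cfg.seed * 100003 + 1000 * (i + 1) + j) % (2**31)
            )
            for j in range(cfg.transects_per_plot)
        ]
        plot_rows.append(
            {"plot_id": pid, "x": float(X[r, c]), "y": float(Y[r, c]),
             "slope_pct": slope_pct,
             "true_total_surface": float(truth.total_surface[r, c]),
             "true_canopy_fuel": float(truth.canopy_fuel[r, c])}
        )
    plots = pd.DataFrame(plot_rows)
    return SimulatedLandscape(
        cfg=cfg, terrain=terr, fires=fires, burn=burn, severity=severity,
        truth_pre=truth, truth_post=truth_post, true_consumption=true_cons,
        pre_cloud=pre_cloud, post_cloud=post_cloud, plots=plots,
        tree_lists=tree_lists, transects=transects, ref_year=ref_year,
    )


def build_feature_table(sim: SimulatedLandscape, cloud: lidar.NormalizedCloud,
                        history: fh.FireHistoryGrids,
                        latitude_deg: float = 36.0) -> pd.DataFrame:
    """Plot-level predictor table: strata + topographic + fire-history metrics."""
    centers = list(zip(sim.plots["x"], sim.plots["y"]))
    feats = lidar.metrics_at_plots(cloud, centers, PLOT_RADIUS_M)
    topo = terrain.terrain_metrics(sim.terrain.spec, sim.terrain.elevation,
                                   latitude_deg=latitude_deg)
    topo_at = terrain.extract_layers_at_points(
        sim.terrain.spec, {k: v for k, v in topo.items() if k != "edge"},
        sim.plots["x"].to_numpy(), sim.plots["y"].to_numpy(),
    )
    for name, vals in topo_at.items():
        feats[name] = vals
    ysf, npf = fh.extract_at_points(history, sim.plots["x"].to_numpy(),
                                    sim.plots["y"].to_numpy())
    feats["YSF"] = ysf
    feats["NPF"] = npf.astype(float)
    feats = feats.drop(columns=[c for c in feats.columns if c.startswith("empty.")])
    return feats


def field_observations(sim: SimulatedLandscape) -> pd.DataFrame:
    """Plot fuel observations from the simulated tree lists and transects."""
    allom = ff.AllometryTable.default()
    obs = []
    for _, row in sim.plots.iterrows():
        pid = row["plot_id"]
        acf = ff.canopy_fuel_from_trees(sim.tree_lists[pid], sim.cfg.plot_area_ha,
                                        allom)
        obs.append(ff.aggregate_plot(sim.transects[pid], plot_id=pid,
                                     year=sim.ref_year, canopy_fuel=acf))
    return ff.observations_to_frame(obs)


# ---------------------------------------------------------------------------
# staged, file-based pipeline


def default_config(seed: int = 0) -> SimConfig:
    """Bundled demo configuration: ~0.36 km^2 landscape, thinned pulse
    density so the full pipeline runs in minutes on one CPU."""
    return SimConfig(seed=seed, extent_m=(600.0, 600.0), pulse_density=2.0,
                     n_plots=120, n_fires=6)


def run_pipeline(config, out_dir, ref_year: int = 2019) -> RunManifest:
    """Execute all stages from one config; see module docstring.

    *config* is a SimConfig, a mapping, or a path to a YAML file.
    """
    if isinstance(config, (str, Path)):
        cfg = SimConfig.from_yaml(config)
    elif isinstance(config, SimConfig):
        cfg = config
    elif isinstance(config, dict):
        cfg = SimConfig(**config)
    else:
        raise TypeError("config must be a SimConfig, dict, or YAML path")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(cfg), seed=cfg.seed)

    state: dict = {}
    reran: set[str] = set()

    stages = [
        ("simulate", _stage_simulate,
         ["terrain.asc", "fires.geojson", "burn.geojson", "severity.asc",
          "truth_total_surface.asc", "pre_cloud.csv", "post_cloud.csv",
          "plots.csv", "transects.csv", "trees.csv"]),
        ("firehistory", _stage_firehistory, ["ysf.asc", "npf.asc"]),
        ("metrics", _stage_metrics,
         ["metrics_pre.P50.gt2.asc", "features.csv"]),
        ("fieldcalc", _stage_fieldcalc, ["observations.csv"]),
        ("fit", _stage_fit, ["model_total_surface.json", "model_summary.txt"]),
        ("maps", _stage_maps, ["fuel_pre.asc", "fuel_post.asc"]),
        ("consume", _stage_consume, ["consumption.asc", "report.json"]),
        ("trends", _stage_trends, ["trends.json", "ysf_pairs.csv"]),
    ]
    for name, fn, outputs in stages:
        paths = [out / p for p in outputs]
        upstream_reran = bool(reran)
        if upstream_reran or any(not p.exists() for p in paths):
            t0 = time.perf_counter()
            counts = fn(cfg, out, state, ref_year)
            manifest.stages[name] = {
                "seconds": round(time.perf_counter() - t0, 3),
                "outputs": [str(p) for p in paths],
                "counts": counts or {},
            }
            reran.add(name)
        else:
            _stage_load(name, cfg, out, state, ref_year)
            manifest.stages[name] = {"seconds": 0.0, "cached": True,
                                     "outputs": [str(p) for p in paths]}
    manifest.to_json(out / "manifest.json")
    return manifest


def _stage_simulate(cfg, out: Path, state: dict, ref_year: int):
    sim = simulate_landscape(cfg, ref_year)
    state["sim"] = sim
    spec = sim.terrain.spec
    write_ascii_grid(out / "terrain.asc", spec, sim.terrain.elevation)
    fh.fires_to_geojson(out / "fires.geojson", sim.fires)
    fh.fires_to_geojson(out / "burn.geojson", [sim.burn])
    write_ascii_grid(out / "severity.asc", spec, sim.severity)
    write_ascii_grid(out / "truth_total_surface.asc", spec,
                     sim.truth_pre.total_surface)
    for tag, cloud in (("pre", sim.pre_cloud), ("post", sim.post_cloud)):
        x, y, z, c = cloud
        pd.DataFrame({"x": x, "y": y, "z": z, "classification": c}).to_csv(
            out / f"{tag}_cloud.csv", index=False
        )
    sim.plots.to_csv(out / "plots.csv", index=False)
    _write_transects(out / "transects.csv", sim.transects)
    _write_trees(out / "trees.csv", sim.tree_lists)
    return {"n_plots": len(sim.plots), "n_fires": len(sim.fires),
            "n_points_pre": len(sim.pre_cloud[0])}


def _stage_firehistory(cfg, out: Path, state: dict, ref_year: int):
    sim = state["sim"]
    hist = fh.rasterize_history(sim.fires, sim.terrain.spec, ref_year,
                                cfg.record_window)
    state["history"] = hist
    write_ascii_grid(out / "ysf.asc", hist.spec, hist.ysf)
    write_ascii_grid(out / "npf.asc", hist.spec, hist.npf.astype(float))
    return {"burned_cells": int(hist.burned_mask().sum())}


def _stage_metrics(cfg, out: Path, state: dict, ref_year: int):
    sim = state["sim"]
    dtm = (sim.terrain.spec, sim.terrain.elevation)
    clouds = {}
    for tag, cloud in (("pre", sim.pre_cloud), ("post", sim.post_cloud)):
        x, y, z, c = cloud
        clouds[tag] = lidar.normalize_heights(x, y, z, c, dtm=dtm)
    state["clouds"] = clouds
    grids = {tag: lidar.metrics_grid(clouds[tag], sim.terrain.spec)
             for tag in clouds}
    state["metric_grids"] = grids
    write_ascii_grid(out / "metrics_pre.P50.gt2.asc", sim.terrain.spec,
                     grids["pre"]["P50.gt2"])
    features = build_feature_table(sim, clouds["pre"], state["history"])
    features.insert(0, "plot_id", sim.plots["plot_id"].to_numpy())
    features.to_csv(out / "features.csv", index=False)
    state["features"] = features.drop(columns=["plot_id"])
    return {"n_features": state["features"].shape[1]}


def _stage_fieldcalc(cfg, out: Path, state: dict, ref_year: int):
    obs = field_observations(state["sim"])
    obs.to_csv(out / "observations.csv", index=False)
    state["observations"] = obs
    return {"n_observations": len(obs)}


def _stage_fit(cfg, out: Path, state: dict, ref_year: int):
    model = FuelLoadModel(state["observations"]["total_surface"],
                          state["features"], response_name="total_surface")
    res = model.fit(seed=cfg.seed)
    state["results"] = res
    res.save(out / "model_total_surface.json")
    (out / "model_summary.txt").write_text(res.summary() + "\n")
    return {"varexp": round(res.varexp, 2), "pct_rmse": round(res.pct_rmse, 2)}


def _stage_maps(cfg, out: Path, state: dict, ref_year: int):
    sim, res = state["sim"], state["results"]
    topo = terrain.terrain_metrics(sim.terrain.spec, sim.terrain.elevation)
    maps = {}
    for tag in ("pre", "post"):
        mg = state["metric_grids"][tag]
        for name, layer in topo.items():
            if name != "edge":
                mg.layers.setdefault(name, layer)
        maps[tag] = cons.predict_grid(res, mg, state["history"],
                                      year=ref_year if tag == "pre" else ref_year + 1)
        write_ascii_grid(out / f"fuel_{tag}.asc", sim.terrain.spec, maps[tag].load)
    state["fuel_maps"] = maps
    return {}


def _stage_consume(cfg, out: Path, state: dict, ref_year: int):
    sim, res = state["sim"], state["results"]
    consumption = cons.difference_maps(state["fuel_maps"]["pre"],
                                       state["fuel_maps"]["post"])
    write_ascii_grid(out / "consumption.asc", sim.terrain.spec, consumption)
    report = cons.summarize_fire(
        consumption, sim.terrain.spec, sim.burn.polygon,
        pct_rmse=res.pct_rmse, fire_id=sim.burn.fire_id, severity=sim.severity,
    )
    report.save(out / "report.json")
    state["report"] = report
    return {"mean_mg_ha": round(report.mean_mg_ha, 2),
            "total_gg": round(report.total_gg, 4)}


def _stage_trends(cfg, out: Path, state: dict, ref_year: int):
    pairs = pool_by_ysf(state["fuel_maps"]["pre"], state["history"])
    pairs.to_csv(out / "ysf_pairs.csv", index=False)
    fit = AsymptoticAccumulationModel.from_pairs(pairs).fit()
    fit.save(out / "trends.json")
    state["trend_fit"] = fit
    return {"asymptote": round(fit.asymptote, 2), "rate": round(fit.rate, 4),
            "converged": fit.converged}


def _stage_load(name, cfg, out: Path, state: dict, ref_year: int):
    """Rebuild in-memory state for a cached stage (stages after it may run)."""
    # Recomputing is the simplest faithful reload: stage outputs are
    # deterministic functions of the config, so regeneration == re-reading.
    {
        "simulate": _stage_simulate_mem,
        "firehistory": _stage_firehistory_mem,
        "metrics": _stage_metrics_mem,
        "fieldcalc": _stage_fieldcalc_mem,
        "fit": _stage_fit_mem,
        "maps": _stage_maps_mem,
        "consume": _stage_consume_mem,
        "trends": _stage_trends_mem,
    }[name](cfg, out, state, ref_year)


def _stage_simulate_mem(cfg, out, state, ref_year):
    state["sim"] = simulate_landscape(cfg, ref_year)


def _stage_firehistory_mem(cfg, out, state, ref_year):
    sim = state["sim"]
    state["history"] = fh.rasterize_history(sim.fires, sim.terrain.spec,
                                            ref_year, cfg.record_window)


def _stage_metrics_mem(cfg, out, state, ref_year):
    sim = state["sim"]
    dtm = (sim.terrain.spec, sim.terrain.elevation)
    clouds = {
        tag: lidar.normalize_heights(*cloud, dtm=dtm)
        for tag, cloud in (("pre", sim.pre_cloud), ("post", sim.post_cloud))
    }
    state["clouds"] = clouds
    state["metric_grids"] = {t: lidar.metrics_grid(clouds[t], sim.terrain.spec)
                             for t in clouds}
    state["features"] = build_feature_table(sim, clouds["pre"], state["history"])


def _stage_fieldcalc_mem(cfg, out, state, ref_year):
    state["observations"] = field_observations(state["sim"])


def _stage_fit_mem(cfg, out, state, ref_year):
    model = FuelLoadModel(state["observations"]["total_surface"],
                          state["features"], response_name="total_surface")
    state["results"] = model.fit(seed=cfg.seed)


def _stage_maps_mem(cfg, out, state, ref_year):
    _stage_maps(cfg, out, state, ref_year)


def _stage_consume_mem(cfg, out, state, ref_year):
    _stage_consume(cfg, out, state, ref_year)


def _stage_trends_mem(cfg, out, state, ref_year):
    _stage_trends(cfg, out, state, ref_year)


def _write_transects(path, transects: dict) -> None:
    rows = []
    for pid, tallies in transects.items():
        for j, t in enumerate(tallies):
            rows.append({
                "plot_id": pid, "transect": j, "count_1h": t.count_1h,
                "count_10h": t.count_10h, "count_100h": t.count_100h,
                "diameters_1000h_cm": ";".join(f"{d:.3f}" for d in t.diameters_1000h_cm),
                "litter_depths_cm": ";".join(f"{d:.3f}" for d in t.litter_depths_cm),
                "duff_depths_cm": ";".join(f"{d:.3f}" for d in t.duff_depths_cm),
                "slope_pct": t.slope_pct, "azimuth_deg": t.azimuth_deg,
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def _write_trees(path, tree_lists: dict) -> None:
    rows = []
    for pid, trees in tree_lists.items():
        for t in trees:
            rows.append({
                "plot_id": pid, "status": t.status, "dbh_cm": t.dbh_cm,
                "height_m": t.height_m, "crown_base_m": t.crown_base_m,
                "species": t.species, "crown_class": t.crown_class,
            })
    pd.DataFrame(rows).to_csv(path, index=False)
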