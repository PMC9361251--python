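"""Fuel mapping, differencing, and consumption summaries."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import box

from fuelscape.consumption import (
    FuelGrid,
    classify_severity,
    correlate_dnbr,
    difference_maps,
    predict_grid,
    severity_summary,
    summarize_fire,
)
from fuelscape.fuelmodel import FuelLoadModel
from fuelscape.grids import GridSpec
from fuelscape.lidar import MetricGrid
from fuelscape.synthetic import planted_signal_dataset


@pytest.fixture
def spec():
    return GridSpec(xmin=0, ymax=200, cell=20, nrows=10, ncols=10)


def fitted_model(seed=0):
    X, y, _ = planted_signal_dataset(120, 0.9, seed=seed, n_noise=1)
    return FuelLoadModel(np.abs(y) * 10, X, "fuel").fit(ntree=100, seed=seed), X


class TestPredictGrid:
    def test_constant_layers_constant_map(self, spec):
        res, X = fitted_model()
        row = X.iloc[7]
        layers = {c: np.full(spec.shape, row[c]) for c in X.columns}
        mg = MetricGrid(spec=spec, layers=layers)
        fuel = predict_grid(res, mg)
        point = res.predict(pd.DataFrame([row]))[0]
        np.testing.assert_allclose(fuel.load, max(point, 0.0))

    def test_rowwise_oracle_equivalence(self, spec):
        """Per-cell predictions equal row-wise prediction on extracted
        feature vectors."""
        res, X = fitted_model(1)
        rng = np.random.default_rng(2)
        layers = {c: rng.standard_normal(spec.shape) for c in X.columns}
        mg = MetricGrid(spec=spec, layers=layers)
        fuel = predict_grid(res, mg)
        table = pd.DataFrame({c: layers[c].ravel() for c in res.features})
        expect = np.maximum(res.predict(table), 0.0).reshape(spec.shape)
        np.testing.assert_array_equal(fuel.load, expect)

    def test_masked_cell_missing(self, spec):
        res, X = fitted_model(2)
        rng = np.random.default_rng(3)
        layers = {c: rng.standard_normal(spec.shape) for c in X.columns}
        empty = np.zeros(spec.shape)
        empty[4, 4] = 1.0
        layers["empty.ng"] = empty
        fuel = predict_grid(res, MetricGrid(spec=spec, layers=layers))
        assert np.isnan(fuel.load[4, 4])
        assert np.isfinite(fuel.load[0, 0])

    def test_missing_layer_named(self, spec):
        res, X = fitted_model(3)
        mg = MetricGrid(spec=spec, layers={})
        with pytest.raises(KeyError, match=res.features[0]):
            predict_grid(res, mg)


class TestDifferenceMaps:
    def test_basic_and_negative_retained(self, spec):
        pre = FuelGrid(spec=spec, load=np.full(spec.shape, 100.0),
                       response_name="f")
        post = FuelGrid(spec=spec, load=np.full(spec.shape, 80.0),
                        response_name="f")
        np.testing.assert_allclose(difference_maps(pre, post), 20.0)
        np.testing.assert_allclose(difference_maps(post, pre), -20.0)
        np.testing.assert_allclose(difference_maps(pre, pre), 0.0)

    def test_mismatch_rejected(self, spec):
        other = GridSpec(xmin=0, ymax=100, cell=20, nrows=5, ncols=5)
        pre = FuelGrid(spec=spec, load=np.zeros(spec.shape), response_name="f")
        post = FuelGrid(spec=other, load=np.zeros(other.shape), response_name="f")
        with pytest.raises(ValueError):
            difference_maps(pre, post)


class TestSummarizeFire:
    def test_uniform_consumption_total(self, spec):
        """Uniform 16.1 Mg/ha over all 100 cells (4 ha): 0.0644 Gg, and the
        CI follows the %RMSE definition."""
        cons = np.full(spec.shape, 16.1)
        rep = summarize_fire(cons, spec, box(-1, -1, 201, 201), pct_rmse=43.0)
        assert rep.mean_mg_ha == pytest.approx(16.1)
        assert rep.total_gg == pytest.approx(16.1 * 4.0 / 1000.0, rel=1e-12)
        assert rep.ci_gg == pytest.approx(rep.total_gg * 0.43, rel=1e-12)

    def test_total_equals_brute_force_sum(self, spec):
        rng = np.random.default_rng(5)
        cons = rng.normal(10, 20, spec.shape)
        poly = box(30, 30, 150, 170)
        rep = summarize_fire(cons, spec, poly, pct_rmse=25.0)
        X, Y = spec.cell_centers()
        import shapely

        inside = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(spec.shape)
        brute = cons[inside].sum() * 0.04 / 1000.0
        assert rep.total_gg == brute
        assert rep.n_cells == int(inside.sum())

    def test_exclusion_half(self, spec):
        cons = np.where(spec.cell_centers()[0] < 100, 10.0, 30.0)
        rep_all = summarize_fire(cons, spec, box(-1, -1, 201, 201), 0.0)
        rep_ex = summarize_fire(cons, spec, box(-1, -1, 201, 201), 0.0,
                                exclusions=[box(-1, -1, 100, 201)])
        assert rep_all.mean_mg_ha == pytest.approx(20.0)
        assert rep_ex.mean_mg_ha == pytest.approx(30.0)
        assert rep_ex.n_excluded == 50

    def test_exclusion_does_not_change_included_values(self, spec):
        rng = np.random.default_rng(6)
        cons = rng.normal(10, 5, spec.shape)
        poly = box(-1, -1, 201, 201)
        ex = box(-1, -1, 60, 60)
        rep = summarize_fire(cons, spec, poly, 10.0, exclusions=[ex])
        import shapely

        X, Y = spec.cell_centers()
        keep = (~shapely.contains_xy(ex, X.ravel(), Y.ravel())).reshape(spec.shape)
        assert rep.mean_mg_ha == pytest.approx(cons[keep].mean())

    def test_no_cells_inside_errors(self, spec):
        with pytest.raises(ValueError):
            summarize_fire(np.zeros(spec.shape), spec, box(500, 500, 600, 600), 10.0)


class TestSeveritySummary:
    def test_single_class_equals_global(self):
        cons = np.array([1.0, 2.0, 3.0, 4.0])
        tab = severity_summary(cons, np.zeros(4))
        assert tab.loc["unburned_to_low", "mean"] == pytest.approx(cons.mean())
        assert tab.loc["unburned_to_low", "sd"] == pytest.approx(cons.std(ddof=1))
        assert tab.loc["low", "n"] == 0 and np.isnan(tab.loc["low", "mean"])

    def test_two_constant_classes(self):
        cons = np.array([10.0, 10.0, 40.0, 40.0])
        cls_ = np.array([1, 1, 3, 3])
        tab = severity_summary(cons, cls_)
        assert tab.loc["low", "mean"] == 10.0 and tab.loc["low", "sd"] == 0.0
        assert tab.loc["high", "mean"] == 40.0 and tab.loc["high", "sd"] == 0.0

    def test_classify_thresholds(self):
        cls_ = classify_severity([50, 150, 300, 500, np.nan])
        np.testing.assert_array_equal(cls_[:4], [0, 1, 2, 3])
        assert np.isnan(cls_[4])


class TestCorrelateDnbr:
    def test_perfect_linear(self):
        d = np.linspace(0, 100, 50)
        assert correlate_dnbr(2 * d, d) == pytest.approx(1.0)

    def test_null_correlation_small(self):
        rng = np.random.default_rng(7)
        a, b = rng.standard_normal(10_000), rng.standard_normal(10_000)
        assert abs(correlate_dnbr(a, b)) < 0.05

    def test_zero_variance_flagged(self):
        assert np.isnan(correlate_dnbr(np.ones(10), np.arange(10.0)))
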