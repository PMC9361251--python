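"""Strata-metric engine: normalization, stratification, statistics, grids."""

import numpy as np
import pytest

from fuelscape.lidar import (
    METRIC_NAMES,
    NormalizedCloud,
    compute_strata_metrics,
    density_bins,
    height_percentiles,
    height_statistics,
    metrics_for_footprint,
    metrics_grid,
    normalize_heights,
    stratify,
)

from conftest import make_cloud


class TestNormalizeHeights:
    def test_flat_plane(self):
        """Point 3 m above a flat z=100 ground plane has height 3."""
        gx, gy = np.meshgrid(np.linspace(0, 100, 5), np.linspace(0, 100, 5))
        x = np.append(gx.ravel(), 50.0)
        y = np.append(gy.ravel(), 50.0)
        z = np.append(np.full(25, 100.0), 103.0)
        cls = np.append(np.full(25, 2), 1)
        cloud = normalize_heights(x, y, z, cls)
        assert cloud.height[-1] == pytest.approx(3.0, abs=1e-9)
        np.testing.assert_allclose(cloud.height[:25], 0.0, atol=1e-9)

    def test_tilted_plane_analytic(self):
        """Heights above a tilted ground plane match the analytic value."""
        rng = np.random.default_rng(7)
        gx = rng.uniform(0, 100, 200)
        gy = rng.uniform(0, 100, 200)
        plane = lambda x, y: 50.0 + 0.2 * x - 0.1 * y
        px, py = rng.uniform(10, 90, 50), rng.uniform(10, 90, 50)
        x = np.concatenate([gx, px])
        y = np.concatenate([gy, py])
        z = np.concatenate([plane(gx, gy), plane(px, py) + 2.0])
        cls = np.concatenate([np.full(200, 2), np.full(50, 1)])
        cloud = normalize_heights(x, y, z, cls)
        np.testing.assert_allclose(cloud.height[200:], 2.0, atol=1e-6)

    def test_dtm_supplied(self, spec20):
        elev = np.full(spec20.shape, 1500.0)
        cloud = normalize_heights([10.0], [10.0], [1507.5], [1], dtm=(spec20, elev))
        assert cloud.height[0] == pytest.approx(7.5)

    def test_too_few_ground_points_rejected(self):
        with pytest.raises(ValueError, match="ground"):
            normalize_heights([0, 1], [0, 1], [0, 1], [2, 2])


class TestStratify:
    def test_boundaries(self):
        """Nonground is h>0; understory 0<h<2; exactly 2 m goes to canopy."""
        h = np.array([-0.01, 0.0, 1.0, 2.0, 3.0])
        canopy, under, nonground = stratify(h)
        assert list(h[nonground]) == [1.0, 2.0, 3.0]
        assert list(h[under]) == [1.0]
        assert list(h[canopy]) == [2.0, 3.0]

    def test_empty_and_all_ground(self):
        for h in ([], [0.0, 0.0]):
            canopy, under, nonground = stratify(h)
            assert not canopy.any() and not under.any() and not nonground.any()


class TestHeightStatistics:
    def test_constant_sample(self):
        s = height_statistics([5.0, 5.0, 5.0])
        assert s["MAX"] == 5 and s["AVG"] == 5 and s["STD"] == 0
        assert np.isnan(s["SKE"]) and np.isnan(s["KUR"])

    def test_hand_computed_std(self):
        s = height_statistics([3, 4, 5, 6, 7])
        assert s["AVG"] == pytest.approx(5.0)
        assert s["STD"] == pytest.approx(1.5811, abs=1e-4)

    def test_symmetric_skewness_zero(self):
        s = height_statistics([2.5, 3.0, 3.5])
        assert s["SKE"] == pytest.approx(0.0, abs=1e-12)

    def test_kurtosis_not_excess(self):
        """Pearson kurtosis of a large normal sample is near 3, not 0."""
        v = np.random.default_rng(0).standard_normal(20000)
        assert height_statistics(v)["KUR"] == pytest.approx(3.0, abs=0.15)


class TestHeightPercentiles:
    def test_constant(self):
        p = height_percentiles([4.2] * 7)
        assert all(v == 4.2 for v in p.values())

    def test_odd_median(self):
        assert height_percentiles([3, 4, 5, 6, 7])["P50"] == 5.0

    def test_interpolation_rule(self):
        """{2,4} at P25: rank 1.25 -> 2 + 0.25*(4-2) = 2.5."""
        assert height_percentiles([2.0, 4.0], probs=(25,))["P25"] == pytest.approx(2.5)

    def test_monotone_property(self, rng):
        for _ in range(20):
            v = rng.uniform(0, 30, rng.integers(1, 50))
            p = list(height_percentiles(v).values())
            assert all(a <= b + 1e-12 for a, b in zip(p, p[1:]))


class TestDensityBins:
    def test_nonground_direct_count(self):
        h = [0.3, 0.3, 0.7, 1.5, 3, 3, 5, 9, 20, 40]
        d = density_bins(h, "nonground")
        expect = {"D00": 20, "D01": 10, "D02": 10, "D03": 20, "D04": 10,
                  "D05": 10, "D06": 10, "D07": 10}
        for k, v in expect.items():
            assert d[k] == pytest.approx(v)

    def test_understory_even_bins(self):
        d = density_bins([0.04, 0.1, 0.3, 0.7, 1.5], "understory")
        assert all(v == pytest.approx(20.0) for v in d.values())
        assert sum(d.values()) == pytest.approx(100.0)

    def test_above_top_band(self):
        d = density_bins([50.0], "nonground")
        assert all(v == 0.0 for v in d.values())
        assert sum(d.values()) < 100

    def test_empty_stratum_zero_filled(self):
        assert all(v == 0.0 for v in density_bins([], "understory").values())


class TestFootprintAndGrid:
    def test_single_return_inside(self, rng):
        cloud = make_cloud(rng, n=11, extent=1000.0)
        cloud.x[:10] += 5000.0  # move 10 points far away
        m = metrics_for_footprint(cloud, (cloud.x[10], cloud.y[10]), 10.0)
        ref = compute_strata_metrics(cloud.height[10:])
        for k in METRIC_NAMES:
            np.testing.assert_equal(m[k], ref[k])

    def test_radius_spanning_cloud(self, random_cloud):
        m = metrics_for_footprint(random_cloud, (100, 100), 1e6)
        ref = compute_strata_metrics(random_cloud.height)
        for k in METRIC_NAMES:
            np.testing.assert_equal(m[k], ref[k])

    def test_footprint_brute_force_oracle(self, rng):
        """Footprint metrics equal brute-force distance filtering, many clouds."""
        for _ in range(25):
            cloud = make_cloud(rng, n=200)
            cx, cy, r = rng.uniform(0, 200, 2).tolist() + [rng.uniform(5, 60)]
            m = metrics_for_footprint(cloud, (cx, cy), r)
            mask = np.hypot(cloud.x - cx, cloud.y - cy) <= r
            ref = compute_strata_metrics(cloud.height[mask])
            for k in METRIC_NAMES:
                np.testing.assert_equal(m[k], ref[k])

    def test_grid_equals_brute_force(self, rng, spec20):
        """Per-cell grid metrics equal per-subset recomputation exactly."""
        cloud = make_cloud(rng, n=1500)
        grid = metrics_grid(cloud, spec20)
        row, col = spec20.index_of(cloud.x, cloud.y)
        for r, c in [(0, 0), (3, 7), (9, 9), (5, 5)]:
            sub = cloud.height[(row == r) & (col == c)]
            ref = compute_strata_metrics(sub)
            for k in METRIC_NAMES:
                v = ref[k]
                if np.isnan(v):
                    v = 0.0  # grid fill policy
                assert grid[k][r, c] == v, k

    def test_cloud_confined_to_one_cell(self, rng, spec20):
        cloud = make_cloud(rng, n=50, extent=19.0)  # all in cell (9, 0)
        grid = metrics_grid(cloud, spec20)
        empty = grid["empty.ng"] >= 1.0
        assert empty.sum() >= 99  # all cells but one flagged empty

    def test_empty_footprint_flagged(self, random_cloud):
        m = metrics_for_footprint(random_cloud, (1e7, 1e7), 1.0)
        assert m["empty.ng"] == 1.0 and m["D00"] == 0.0


class TestInvariants:
    def test_percentile_monotone_and_bins_bounded_per_cell(self, rng, spec20):
        cloud = make_cloud(rng, n=2000)
        grid = metrics_grid(cloud, spec20)
        p_cols = [f"P{p:02d}.gt2" for p in (5, 10, 25, 50, 75, 90, 95)]
        stacked = np.stack([grid[c] for c in p_cols])
        assert (np.diff(stacked, axis=0) >= -1e-12).all()
        for i in range(8):
            d = grid[f"D{i:02d}"]
            assert ((d >= 0) & (d <= 100)).all()
        occupied = grid["empty.lt2"] == 0.0
        under_sum = sum(grid[f"D{i:02d}.lt2"] for i in range(5))
        np.testing.assert_allclose(under_sum[occupied], 100.0, atol=1e-9)

    def test_csv_roundtrip(self, random_cloud, tmp_path):
        p = tmp_path / "cloud.csv"
        random_cloud.to_csv(p)
        back = NormalizedCloud.from_csv(p)
        np.testing.assert_allclose(back.height, random_cloud.height)
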