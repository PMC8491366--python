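"""Kernel and MCP home ranges, overlap indices, filters, and summary arithmetic."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from jackalkit import homerange as hr


@pytest.fixture(scope="module")
def normal_cloud():
    return np.random.default_rng(42).normal(0.0, 1.0, (1000, 2))


class TestHref:
    def test_unit_variance_formula(self, rng):
        pts = rng.normal(0, 1, (64, 2))
        pts = (pts - pts.mean(0)) / pts.std(0, ddof=1)  # exact unit sample variance
        assert hr.href(pts) == pytest.approx(64 ** (-1 / 6))

    def test_scale_equivariance(self, rng):
        pts = rng.normal(0, 1, (50, 2))
        assert hr.href(pts * 250.0) == pytest.approx(250.0 * hr.href(pts))

    def test_monte_carlo_mean_matches_plugin_rule(self, rng):
        vals = [hr.href(rng.normal(0, 1000.0, (100, 2))) for _ in range(100)]
        assert np.mean(vals) == pytest.approx(1000.0 * 100 ** (-1 / 6), rel=0.05)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            hr.href(np.zeros((10, 2)))
        with pytest.raises(ValueError):
            hr.href(np.random.default_rng(0).normal(size=(4, 2)))


class TestAdhocBandwidth:
    def test_single_cluster_scan(self, rng):
        pts = rng.normal(0, 1000.0, (1000, 2))
        h0 = hr.href(pts)
        h = hr.adhoc_bandwidth(pts)
        mult = h / h0
        assert mult <= 1.0 + 1e-9
        assert any(abs(mult - m) < 1e-9 for m in np.arange(1.0, 0.049, -0.05))
        # contiguity holds at the returned bandwidth, fails one step below
        grid = hr.grid_from_points(pts, h, n_cells=128)
        iso = hr.isopleth(hr.kde_ud(pts, h, grid), 0.95)
        assert hr._is_single_contiguous_no_holes(iso.cell_mask)
        h_below = (mult - 0.05) * h0
        grid = hr.grid_from_points(pts, h_below, n_cells=128)
        iso = hr.isopleth(hr.kde_ud(pts, h_below, grid), 0.95)
        assert not hr._is_single_contiguous_no_holes(iso.cell_mask)

    def test_two_clusters_bridge_closes_then_splits(self):
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(0, 100.0, (300, 2)), rng.normal([600.0, 0.0], 100.0, (300, 2))]
        )
        h0 = hr.href(pts)
        h = hr.adhoc_bandwidth(pts)
        assert h < h0  # scan moved below the reference bandwidth
        grid = hr.grid_from_points(pts, h, n_cells=128)
        assert hr._is_single_contiguous_no_holes(
            hr.isopleth(hr.kde_ud(pts, h, grid), 0.95).cell_mask
        )
        h_below = h - 0.05 * h0
        grid = hr.grid_from_points(pts, h_below, n_cells=128)
        assert not hr._is_single_contiguous_no_holes(
            hr.isopleth(hr.kde_ud(pts, h_below, grid), 0.95).cell_mask
        )

    def test_fragmentation_at_href_warns_and_returns_href(self):
        rng = np.random.default_rng(5)
        pts = np.vstack(
            [rng.normal(0, 100.0, (200, 2)),
             rng.normal([20_000.0, 0.0], 100.0, (200, 2))]
        )
        with pytest.warns(UserWarning, match="fragmented"):
            h = hr.adhoc_bandwidth(pts)
        assert h == pytest.approx(hr.href(pts))


class TestKDE:
    def test_single_point_mode_and_normalization(self):
        grid = hr.GridSpec(-5, -5, 0.1, 100, 100)
        ud = hr.kde_ud(np.array([[0.33, -0.18]]), 1.0, grid)
        assert ud.masses.sum() == pytest.approx(1.0)
        iy, ix = np.unravel_index(np.argmax(ud.masses), ud.masses.shape)
        assert grid.x_centers[ix] == pytest.approx(0.35, abs=0.051)
        assert grid.y_centers[iy] == pytest.approx(-0.15, abs=0.051)

    def test_gaussian_cloud_area_matches_analytic_ellipse(self, normal_cloud):
        h = hr.href(normal_cloud)
        grid = hr.grid_from_points(normal_cloud, h, n_cells=256)
        ud = hr.kde_ud(normal_cloud, h, grid)
        area_m2 = hr.isopleth(ud, 0.95).area_km2 * 1e6
        analytic = np.pi * stats.chi2.ppf(0.95, 2) * (1 + h * h)
        assert area_m2 == pytest.approx(analytic, rel=0.15)

    def test_grid_resolution_stability(self, normal_cloud):
        h = hr.href(normal_cloud)
        areas = []
        for n_cells in (128, 256):
            grid = hr.grid_from_points(normal_cloud, h, n_cells=n_cells)
            areas.append(hr.isopleth(hr.kde_ud(normal_cloud, h, grid), 0.95).area_km2)
        assert abs(areas[1] - areas[0]) / areas[0] < 0.05

    def test_area_shrinks_with_bandwidth(self, normal_cloud):
        h0 = hr.href(normal_cloud)
        prev = np.inf
        for m in (1.0, 0.7, 0.4):
            grid = hr.grid_from_points(normal_cloud, h0, n_cells=128)
            area = hr.isopleth(hr.kde_ud(normal_cloud, m * h0, grid), 0.95).area_km2
            assert area < prev
            prev = area

    def test_insufficient_margin_rejected(self, normal_cloud):
        grid = hr.GridSpec(-2, -2, 0.05, 80, 80)  # does not cover +-3h around data
        with pytest.raises(ValueError, match="margin"):
            hr.kde_ud(normal_cloud, 1.0, grid)


class TestIsopleth:
    def test_level_one_takes_all_positive_cells(self):
        grid = hr.GridSpec(0, 0, 1, 4, 4)
        masses = np.zeros((4, 4))
        masses[:2, :2] = 0.25
        ud = hr.UtilizationDistribution(grid, masses)
        assert hr.isopleth(ud, 1.0).n_cells == 4

    def test_nesting(self, normal_cloud):
        h = hr.href(normal_cloud)
        grid = hr.grid_from_points(normal_cloud, h, n_cells=128)
        ud = hr.kde_ud(normal_cloud, h, grid)
        inner = hr.isopleth(ud, 0.5).cell_mask
        outer = hr.isopleth(ud, 0.95).cell_mask
        assert np.all(outer[inner])

    def test_uniform_tie_break_gives_exact_count(self):
        grid = hr.GridSpec(0, 0, 1, 10, 10)
        ud = hr.UtilizationDistribution(grid, np.full((10, 10), 0.01))
        assert hr.isopleth(ud, 0.95).n_cells == 95


class TestMCP:
    def test_full_hull_of_unit_square(self):
        pts = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [0.5, 0.5]], float)
        poly, area_km2 = hr.mcp(pts, 1.0)
        assert area_km2 == pytest.approx(1.0 / 1e6)

    def test_outlier_removed_at_95_percent(self, rng):
        theta = rng.uniform(0, 2 * np.pi, 100)
        boundary = 5000.0 * np.column_stack([np.cos(theta), np.sin(theta)])
        pts = np.vstack([boundary, [[50_000.0, 0.0]]])
        poly, area = hr.mcp(pts, 0.95)
        assert poly.bounds[2] < 6000.0  # the far point is gone
        full_area = hr.mcp(pts, 1.0)[1]
        assert area < full_area

    def test_area_monotone_in_percent(self, normal_cloud):
        pts = normal_cloud * 1000.0
        areas = [hr.mcp(pts, p)[1] for p in (0.5, 0.75, 0.95, 1.0)]
        assert all(a <= b + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_hull_area_matches_independent_implementation(self, rng):
        from scipy.spatial import ConvexHull

        for _ in range(20):
            pts = rng.normal(0, 500.0, (60, 2))
            poly, area_km2 = hr.mcp(pts, 1.0)
            assert area_km2 * 1e6 == pytest.approx(ConvexHull(pts).volume)


class TestOverlap:
    def test_udoi_identical_uniform_is_one(self):
        grid = hr.GridSpec(0, 0, 1, 10, 10)
        ud = hr.UtilizationDistribution(grid, np.full((10, 10), 0.01))
        assert hr.udoi(ud, ud) == pytest.approx(1.0)

    def test_udoi_disjoint_is_zero(self):
        grid = hr.GridSpec(0, 0, 1, 10, 10)
        a = np.zeros((10, 10)); a[:5] = 0.02
        b = np.zeros((10, 10)); b[5:] = 0.02
        ua = hr.UtilizationDistribution(grid, a)
        ub = hr.UtilizationDistribution(grid, b)
        assert hr.udoi(ua, ub) == 0.0

    def test_udoi_matches_quadrature_oracle_for_offset_gaussians(self):
        # two unit-variance Gaussians one sigma apart; the continuous UDOI is
        # (lens area of the two 95% disks) x integral of the density product
        grid = hr.GridSpec(-6, -6, 12 / 400, 400, 400)
        ua = hr.kde_ud(np.array([[0.0, 0.0]]), 1.0, grid)
        ub = hr.kde_ud(np.array([[1.0, 0.0]]), 1.0, grid)
        val = hr.udoi(ua, ub)
        r = np.sqrt(stats.chi2.ppf(0.95, 2))
        d = 1.0
        lens = 2 * r * r * np.arccos(d / (2 * r)) - d / 2 * np.sqrt(4 * r * r - d * d)
        product_integral = np.exp(-(d * d) / 4) / (4 * np.pi)
        assert val == pytest.approx(lens * product_integral, rel=0.02)
        assert hr.udoi(ub, ua) == pytest.approx(val)  # symmetric

    def test_udoi_grid_mismatch_rejected(self):
        g1 = hr.GridSpec(0, 0, 1, 10, 10)
        g2 = hr.GridSpec(0, 0, 2, 10, 10)
        u1 = hr.UtilizationDistribution(g1, np.full((10, 10), 0.01))
        u2 = hr.UtilizationDistribution(g2, np.full((10, 10), 0.01))
        with pytest.raises(ValueError, match="grid"):
            hr.udoi(u1, u2)

    def test_percent_area_overlap(self):
        import shapely

        a = shapely.box(0, 0, 1, 1)
        assert hr.percent_area_overlap(a, a) == pytest.approx((100, 100, 100))
        far = shapely.box(5, 5, 6, 6)
        assert hr.percent_area_overlap(a, far) == pytest.approx((0, 0, 0))
        half = shapely.box(0, 0, 1, 2)
        assert hr.percent_area_overlap(a, half) == pytest.approx((100, 50, 75))


class TestRelocationFilters:
    @staticmethod
    def tracks(n, start, freq_h=6):
        ts = pd.date_range(start, periods=n, freq=f"{freq_h}h")
        rng = np.random.default_rng(1)
        return pd.DataFrame(
            {"animal_id": "A1", "timestamp": ts,
             "x": rng.normal(0, 800, n), "y": rng.normal(0, 800, n)}
        )

    def test_month_with_too_few_locations_excluded(self):
        relocs = self.tracks(27, "2015-04-01")  # 27 fixes spanning ~7 days
        with pytest.warns(UserWarning, match="filters"):
            assert hr.monthly_ranges(relocs).empty

    def test_short_span_excluded_despite_count(self):
        relocs = self.tracks(40, "2015-04-01")  # 40 fixes in 10 days
        with pytest.warns(UserWarning):
            out = hr.monthly_ranges(relocs)
        assert out.empty

    def test_boundary_month_included(self):
        relocs = self.tracks(60, "2015-04-01")  # 60 fixes spanning ~15 days
        out = hr.monthly_ranges(relocs)
        assert list(out["month"]) == ["2015-04"]
        assert out["kde95_km2"].iloc[0] > 0

    def test_exclude_forays_identity_without_list(self):
        relocs = self.tracks(30, "2015-04-01")
        out, flagged = hr.exclude_forays(relocs)
        pd.testing.assert_frame_equal(out, relocs)
        assert flagged.empty

    def test_manual_window_removed_and_flagging_monotone(self):
        relocs = self.tracks(30, "2015-04-01")
        relocs.loc[10, ["x", "y"]] = (13_000.0, 0.0)  # 13-km excursion
        out, _ = hr.exclude_forays(
            relocs, exclusion_list=[("A1", "2015-04-03 11:00", "2015-04-03 13:00")]
        )
        assert len(out) == 29
        _, f12 = hr.exclude_forays(relocs, auto_threshold_km=12.0)
        _, f5 = hr.exclude_forays(relocs, auto_threshold_km=5.0)
        assert len(f12) == 1  # only the foray is flagged, never removed
        assert len(f5) >= len(f12)


class TestSummaries:
    def test_study_mean_and_se(self):
        mean, se = hr.summarize_ranges([50.7, 46.7, 40.1, 50.8])
        assert round(mean, 1) == 47.1
        assert round(se, 1) == 2.5

    def test_identical_values_zero_se(self):
        assert hr.summarize_ranges([5.0, 5.0, 5.0])[1] == 0.0

    def test_two_values(self):
        assert hr.summarize_ranges([1.0, 3.0]) == pytest.approx((2.0, 1.0))

    @pytest.mark.parametrize(
        "args, expected", [((4, 2, 800), 0.01), ((1, 1, 1), 1.0), ((5, 3.2, 400), 0.04)]
    )
    def test_density(self, args, expected):
        assert hr.density_estimate(*args) == pytest.approx(expected)

    def test_density_rejects_bad_area(self):
        with pytest.raises(ValueError):
            hr.density_estimate(4, 2, 0)


class TestKernelHomeRangeEstimator:
    def test_fit_exposes_bandwidths_areas_and_polygons(self, normal_cloud):
        pts = normal_cloud * 1000.0
        est = hr.KernelHomeRange(n_cells=128).fit(pts)
        bw = est.bandwidth_
        assert bw.h_used == pytest.approx(max(0.8 * bw.h_ref, bw.h_adhoc))
        assert est.kde_areas_km2_[0.5] <= est.kde_areas_km2_[0.95]
        assert est.mcp_areas_km2_[0.5] <= est.mcp_areas_km2_[0.95]
        assert est.ud_.masses.sum() == pytest.approx(1.0)
        assert est.isopleths_[0.95].polygon.area > 0

    def test_sklearn_param_interface(self):
        est = hr.KernelHomeRange(n_cells=64, factor=0.9)
        cloned = clone(est)
        assert cloned.get_params()["factor"] == 0.9
        assert cloned.get_params()["n_cells"] == 64
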