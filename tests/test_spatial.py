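import math

import numpy as np
import pytest

from phylodemo.spatial import (
    GeoPoint,
    SuitabilityRaster,
    UndefinedCorrelationError,
    centroid_distances,
    distance_matrix,
    geodesic_distance,
    isolation_by_distance,
    linearize_phist,
    mantel_exact,
    mantel_test,
    pinball_loss,
    quantile_regression,
    range_centroid,
    suitability_stability,
)


class TestGeodesicDistance:
    def test_zero_for_identical_points(self):
        p = GeoPoint(-15.25, -47.75)
        assert geodesic_distance(p, p) == 0.0

    def test_half_circumference(self):
        d = geodesic_distance(GeoPoint(0, 0), GeoPoint(0, 180))
        assert d == pytest.approx(math.pi * 6371, rel=1e-6)

    def test_one_degree_at_equator(self):
        d = geodesic_distance(GeoPoint(0, 0), GeoPoint(0, 1))
        assert d == pytest.approx(2 * math.pi * 6371 / 360, rel=1e-6)

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(50):
            pts = [
                GeoPoint(float(rng.uniform(-80, 80)),
                         float(rng.uniform(-179, 179)))
                for _ in range(3)
            ]
            ab = geodesic_distance(pts[0], pts[1])
            ba = geodesic_distance(pts[1], pts[0])
            ac = geodesic_distance(pts[0], pts[2])
            cb = geodesic_distance(pts[2], pts[1])
            assert ab == pytest.approx(ba, rel=1e-12)
            assert ab <= ac + cb + 1e-9

    def test_invalid_coordinates_rejected(self):
        with pytest.raises(Exception):
            GeoPoint(91, 0)


def _toy_matrices():
    rng = np.random.default_rng(7)
    pts = rng.uniform(0, 10, size=(4, 2))
    A = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    B = A + rng.normal(0, 0.5, size=A.shape)
    B = (B + B.T) / 2
    np.fill_diagonal(B, 0)
    return A, B


class TestMantel:
    def test_self_correlation_is_one(self):
        A, _ = _toy_matrices()
        res = mantel_test(A, A.copy(), n_perm=99,
                          rng=np.random.default_rng(0))
        assert res.r == pytest.approx(1.0)

    def test_affine_reversal_is_minus_one(self):
        A, _ = _toy_matrices()
        B = A.max() + 1 - A
        np.fill_diagonal(B, 0)
        res = mantel_test(A, B, n_perm=99, rng=np.random.default_rng(0))
        assert res.r == pytest.approx(-1.0)

    def test_sampled_p_matches_exact_enumeration(self):
        A, B = _toy_matrices()
        p_exact = mantel_exact(A, B)
        res = mantel_test(A, B, n_perm=20_000,
                          rng=np.random.default_rng(42))
        # binomial 99% bound around the exact enumeration value
        se = math.sqrt(p_exact * (1 - p_exact) / 20_000)
        assert abs(res.p_value - p_exact) < max(2.6 * se, 0.01)

    def test_constant_matrix_rejected(self):
        A, _ = _toy_matrices()
        C = np.ones((4, 4)) - np.eye(4)
        with pytest.raises(UndefinedCorrelationError):
            mantel_test(A, C, n_perm=10)

    def test_r_agrees_with_independent_implementation(self):
        skbio = pytest.importorskip("skbio")
        from skbio.stats.distance import mantel as skbio_mantel

        A, B = _toy_matrices()
        r_theirs, _, _ = skbio_mantel(A, B, permutations=0)
        res = mantel_test(A, B, n_perm=10, rng=np.random.default_rng(0))
        assert res.r == pytest.approx(r_theirs, abs=1e-10)


def _raster(values, xll=-50.0, yll=-20.0, cs=0.5, tag=""):
    return SuitabilityRaster(values=np.asarray(values, dtype=float),
                             xll=xll, yll=yll, cellsize=cs, time_slice=tag)


class TestStability:
    def test_identical_rasters_are_maximally_stable(self, rng):
        v = rng.random((5, 6))
        stability, refugium = suitability_stability(
            [_raster(v), _raster(v.copy()), _raster(v.copy())], threshold=0.5
        )
        assert np.allclose(stability, 0.0)
        assert np.array_equal(refugium, v >= 0.5)

    def test_oscillating_cell_mean_abs_difference(self):
        slices = [
            _raster([[1.0]]), _raster([[0.0]]), _raster([[1.0]]),
        ]
        stability, _ = suitability_stability(slices)
        # pairwise |differences| {1, 0, 1} -> mean 2/3, sign flipped
        assert stability[0, 0] == pytest.approx(-2 / 3)

    def test_refugium_subset_of_each_slice(self, rng):
        slices = [_raster(rng.random((8, 8))) for _ in range(3)]
        _, refugium = suitability_stability(slices, threshold=0.4)
        for r in slices:
            assert np.all(refugium <= (r.values >= 0.4))

    def test_grid_mismatch_rejected(self, rng):
        with pytest.raises(Exception):
            suitability_stability(
                [_raster(rng.random((4, 4))), _raster(rng.random((5, 4)))]
            )


class TestRangeCentroid:
    def test_single_cell_centroid_is_its_center(self):
        v = np.zeros((4, 4))
        v[1, 2] = 0.9
        r = _raster(v)
        c = range_centroid(r, threshold=0.5)
        # row 1 from the top of a 4-row grid, yll=-20, cellsize 0.5
        assert c.lon == pytest.approx(-50.0 + 2.5 * 0.5)
        assert c.lat == pytest.approx(-20.0 + 2.5 * 0.5)

    def test_symmetric_cells_centroid_on_axis(self):
        v = np.zeros((3, 5))
        v[1, 0] = v[1, 4] = 1.0
        c = range_centroid(_raster(v), threshold=0.5)
        assert c.lon == pytest.approx(-50.0 + 2.5 * 0.5)

    def test_three_cells_mean_of_centers(self):
        v = np.zeros((3, 3))
        v[0, 0] = v[1, 1] = v[2, 2] = 1.0
        c = range_centroid(_raster(v), threshold=0.5)
        lats = [-20 + (3 - 1 - i + 0.5) * 0.5 for i in range(3)]
        lons = [-50 + (j + 0.5) * 0.5 for j in range(3)]
        assert c.lat == pytest.approx(np.mean(lats))
        assert c.lon == pytest.approx(np.mean(lons))

    def test_invariant_to_subthreshold_changes(self, rng):
        v = rng.random((6, 6))
        r1 = _raster(v)
        v2 = v.copy()
        v2[v2 < 0.5] *= 0.5  # perturb only sub-threshold cells
        r2 = _raster(v2)
        c1 = range_centroid(r1, 0.5)
        c2 = range_centroid(r2, 0.5)
        assert (c1.lat, c1.lon) == (c2.lat, c2.lon)

    def test_empty_range_rejected(self):
        with pytest.raises(Exception):
            range_centroid(_raster(np.zeros((3, 3))), threshold=0.5)


def brute_force_quantile(x, y, tau, a_grid, b_grid):
    best = (None, None, np.inf)
    for a in a_grid:
        for b in b_grid:
            loss = pinball_loss(y, a + b * x, tau)
            if loss < best[2]:
                best = (a, b, loss)
    return best


class TestQuantileRegression:
    @pytest.mark.parametrize("tau", [0.1, 0.5, 0.9])
    def test_exact_line_recovered(self, tau):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        y = 2 * x + 1
        fit = quantile_regression(x, y, tau)
        assert fit.slope == pytest.approx(2.0, abs=1e-8)
        assert fit.intercept == pytest.approx(1.0, abs=1e-8)
        assert fit.pinball_loss == pytest.approx(0.0, abs=1e-10)

    def test_median_fit_matches_grid_search(self):
        x = np.array([0.0, 1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([0.2, 1.4, 1.9, 3.4, 3.8, 5.4])
        fit = quantile_regression(x, y, 0.5)
        a_grid = np.arange(-1, 1, 0.001)
        b_grid = np.arange(0.5, 1.5, 0.001)
        a, b, loss = brute_force_quantile(x, y, 0.5, a_grid, b_grid)
        assert fit.pinball_loss <= loss + 1e-3
        assert fit.slope == pytest.approx(b, abs=2e-3)

    def test_upper_quantile_lies_above_median(self, rng):
        x = rng.uniform(0, 10, 200)
        y = x + rng.exponential(2.0, 200)
        lo = quantile_regression(x, y, 0.25)
        hi = quantile_regression(x, y, 0.75)
        mid_x = 5.0
        assert hi.intercept + hi.slope * mid_x > lo.intercept + lo.slope * mid_x

    def test_constant_predictor_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            quantile_regression(np.ones(5), np.arange(5.0), 0.5)

    def test_matches_statsmodels_on_noisy_data(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        x = rng.uniform(0, 10, 80)
        y = 1.5 * x + rng.normal(0, 1, 80)
        fit = quantile_regression(x, y, 0.5)
        X = sm.add_constant(x)
        theirs = sm.QuantReg(y, X).fit(q=0.5)
        assert fit.pinball_loss <= pinball_loss(
            y, theirs.params[0] + theirs.params[1] * x, 0.5
        ) + 1e-8


class TestIsolationByDistance:
    def test_constructed_cline_gives_high_r(self):
        pts = [GeoPoint(0.0, lon) for lon in (0.0, 1.0, 3.0, 7.0, 15.0)]
        geo = distance_matrix(pts)
        with np.errstate(divide="ignore"):
            log_geo = np.where(geo > 0, np.log10(geo), 0.0)
        lin = log_geo / (1 + log_geo.max())  # phi/(1-phi) proportional target
        phi = lin / (1 + lin)
        np.fill_diagonal(phi, 0)
        res = isolation_by_distance(
            phi, pts, n_perm=200, rng=np.random.default_rng(0)
        )
        assert res.r > 0.99

    def test_null_labels_give_uniformish_p(self):
        rng = np.random.default_rng(5)
        pts = [
            GeoPoint(float(rng.uniform(-20, 0)), float(rng.uniform(-60, -40)))
            for _ in range(8)
        ]
        ps = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            phi = r.uniform(0, 0.5, size=(8, 8))
            phi = (phi + phi.T) / 2
            np.fill_diagonal(phi, 0)
            res = isolation_by_distance(phi, pts, n_perm=200, rng=r)
            ps.append(res.p_value)
        # under the null, p-values spread over (0, 1)
        assert 0.15 < np.mean(ps) < 0.85
        assert np.std(ps) > 0.1

    def test_composition_equals_direct_mantel(self):
        pts = [GeoPoint(0.0, lon) for lon in (0.0, 2.0, 5.0, 9.0)]
        rng = np.random.default_rng(3)
        phi = rng.uniform(0, 0.8, size=(4, 4))
        phi = (phi + phi.T) / 2
        np.fill_diagonal(phi, 0)
        res = isolation_by_distance(phi, pts, n_perm=500,
                                    rng=np.random.default_rng(9))
        geo = distance_matrix(pts)
        log_geo = np.log10(np.maximum(geo, geo[geo > 0].min() / 2))
        np.fill_diagonal(log_geo, 0)
        direct = mantel_test(linearize_phist(phi), log_geo, n_perm=500,
                             rng=np.random.default_rng(9))
        assert res.r == pytest.approx(direct.r, abs=1e-12)
        assert res.p_value == pytest.approx(direct.p_value, abs=1e-12)

    def test_centroid_distances_shape(self):
        pts = [GeoPoint(0, 0), GeoPoint(0, 1)]
        d = centroid_distances(pts, GeoPoint(0, 2))
        assert len(d) == 2
        assert d[1] < d[0]
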