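import numpy as np
import pytest

from curvislice.foreground import ForegroundPoints
from curvislice.surface import (
    AffineXY,
    PolySurface,
    build_design,
    evaluate_surface,
    fit_points,
    fit_surface,
    poly_exponents,
    surface_gradient,
)


def points_from_arrays(x, y, z):
    return ForegroundPoints(np.column_stack([x, y, z]).astype(int))


class TestDesign:
    def test_degree3_has_ten_columns(self):
        pts = points_from_arrays(np.arange(12), np.arange(12), np.arange(12))
        assert build_design(pts, k=3).X.shape[1] == 10

    def test_degree0_is_all_ones(self):
        pts = points_from_arrays([1, 2], [3, 4], [5, 6])
        X = build_design(pts, k=0).X
        np.testing.assert_array_equal(X, np.ones((2, 1)))

    def test_monomial_order_is_lexicographic(self):
        # (a, b) = (0,0), (0,1), (1,0) for k=1: row is [1, y, x]
        pts = points_from_arrays([2, 0, 1], [3, 0, 1], [7, 0, 1])
        X = build_design(pts, k=1, normalize=False).X
        np.testing.assert_array_equal(X[0], [1.0, 3.0, 2.0])
        assert poly_exponents(1) == [(0, 0), (0, 1), (1, 0)]

    def test_negative_degree_rejected(self):
        pts = points_from_arrays([0], [0], [0])
        with pytest.raises(ValueError):
            build_design(pts, k=-1)

    def test_underdetermined_design_warns(self):
        pts = points_from_arrays([0, 1], [0, 1], [0, 1])
        with pytest.warns(UserWarning, match="underdetermined"):
            build_design(pts, k=3)


class TestFit:
    def test_constant_surface_recovered_exactly_despite_ridge(self):
        rng = np.random.default_rng(0)
        pts = points_from_arrays(rng.integers(0, 50, 30), rng.integers(0, 50, 30), np.full(30, 5))
        s = fit_points(pts, k=3, alpha=0.1)
        assert s.coeffs[0] == pytest.approx(5.0, abs=1e-9)
        np.testing.assert_allclose(s.coeffs[1:], 0.0, atol=1e-9)

    def test_exact_plane_interpolation_with_alpha_zero(self):
        x = np.array([0, 1, 0, 2])
        y = np.array([0, 0, 1, 1])
        z = 2 * x + 3 * y + 1
        s = fit_points(points_from_arrays(x, y, z), k=1, alpha=0.0, normalize=False)
        np.testing.assert_allclose(s.coeffs, [1.0, 3.0, 2.0], atol=1e-9)

    def test_matches_closed_form_ridge_solution(self):
        rng = np.random.default_rng(3)
        pts = points_from_arrays(
            rng.integers(0, 100, 20), rng.integers(0, 100, 20), rng.integers(0, 60, 20)
        )
        alpha = 0.1
        design = build_design(pts, k=2)
        s = fit_surface(design, alpha)
        penalty = np.eye(design.X.shape[1])
        penalty[0, 0] = 0.0
        w_oracle = np.linalg.pinv(design.X.T @ design.X + alpha * penalty) @ design.X.T @ design.z
        np.testing.assert_allclose(s.coeffs, w_oracle, atol=1e-8)

    def test_rank_deficient_unregularized_fit_errors_with_guidance(self):
        pts = points_from_arrays([5] * 12, [5] * 12, np.arange(12))
        with pytest.raises(np.linalg.LinAlgError, match="alpha"):
            fit_points(pts, k=2, alpha=0.0)

    def test_ridge_shrinkage_is_monotone_in_alpha(self):
        rng = np.random.default_rng(8)
        pts = points_from_arrays(
            rng.integers(0, 40, 50), rng.integers(0, 40, 50), rng.integers(0, 80, 50)
        )
        design = build_design(pts, k=3)
        norms = [
            np.linalg.norm(fit_surface(design, a).coeffs[1:])
            for a in [0.0, 0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(norms, norms[1:]))

    def test_noiseless_polynomial_recovered_through_normalization(self):
        rng = np.random.default_rng(5)
        x = rng.integers(0, 200, 300)
        y = rng.integers(0, 120, 300)
        z = 40 + 0.05 * x - 0.03 * y + 1e-4 * x * y + 2e-6 * x**2 * y
        s = fit_points(points_from_arrays(x, y, np.round(z)), k=3, alpha=0.0)
        # recovery is judged in value space: normalized-basis coefficients differ
        grid_x, grid_y = np.meshgrid(np.arange(0, 200, 7), np.arange(0, 120, 7), indexing="ij")
        z_true = 40 + 0.05 * grid_x - 0.03 * grid_y + 1e-4 * grid_x * grid_y + 2e-6 * grid_x**2 * grid_y
        err = evaluate_surface(s, grid_x, grid_y) - z_true
        assert np.abs(err).max() < 1.0  # z was rounded to integer voxels


class TestEvaluate:
    def test_constant_plus_offset(self):
        s = PolySurface(0, [5.0], dz=11.0)
        assert evaluate_surface(s, 123.0, 45.0) == pytest.approx(16.0)

    def test_full_lateral_grid_shape(self):
        s = PolySurface(1, [10.0, 0.01, 0.02])
        xs = np.arange(1024.0)[:, None]
        ys = np.arange(256.0)[None, :]
        grid = evaluate_surface(s, xs, ys)
        assert grid.shape == (1024, 256)
        assert np.all(np.isfinite(grid))

    def test_interpolated_plane_reproduces_fit_points(self):
        x = np.array([0, 3, 0, 5])
        y = np.array([0, 0, 2, 4])
        z = 4 * x + 2 * y + 3
        s = fit_points(points_from_arrays(x, y, z), k=1, alpha=0.0, normalize=False)
        np.testing.assert_allclose(evaluate_surface(s, x, y), z, atol=1e-9)

    def test_dz_shift_identity(self):
        rng = np.random.default_rng(1)
        s = PolySurface(3, rng.normal(size=10), dz=0.0, transform=AffineXY(50, 50, 30, 30))
        shifted = s.shifted(7.25)
        xs, ys = rng.random(20) * 100, rng.random(20) * 60
        np.testing.assert_array_equal(
            evaluate_surface(shifted, xs, ys), evaluate_surface(s, xs, ys) + 7.25
        )


class TestGradient:
    def test_constant_surface_zero_gradient(self):
        s = PolySurface(2, [5, 0, 0, 0, 0, 0])
        assert surface_gradient(s, 3.0, 4.0) == (0.0, 0.0)

    def test_plane_gradient(self):
        # z = 2x + 3y: order (0,0),(0,1),(0,2)... for k=2 is
        # (0,0),(0,1),(0,2),(1,0),(1,1),(2,0)
        s = PolySurface(2, [0, 3, 0, 2, 0, 0])
        gx, gy = surface_gradient(s, 11.0, -2.0)
        assert (gx, gy) == (2.0, 3.0)

    def test_matches_central_finite_differences(self):
        rng = np.random.default_rng(2)
        s = PolySurface(3, rng.normal(size=10), transform=AffineXY(80, 80, 40, 40))
        h = 1e-3
        for x0, y0 in [(10.0, 5.0), (100.0, 60.0), (42.5, 33.3)]:
            gx, gy = surface_gradient(s, x0, y0)
            fd_x = (evaluate_surface(s, x0 + h, y0) - evaluate_surface(s, x0 - h, y0)) / (2 * h)
            fd_y = (evaluate_surface(s, x0, y0 + h) - evaluate_surface(s, x0, y0 - h)) / (2 * h)
            assert gx == pytest.approx(fd_x, abs=1e-4)
            assert gy == pytest.approx(fd_y, abs=1e-4)


def test_surface_json_roundtrip(tmp_path):
    rng = np.random.default_rng(4)
    s = PolySurface(3, rng.normal(size=10), dz=-2.5, label=2, transform=AffineXY(10, 20, 30, 40))
    path = tmp_path / "surface.json"
    s.save_json(path)
    back = PolySurface.load_json(path)
    assert back.degree == s.degree and back.label == s.label and back.dz == s.dz
    np.testing.assert_array_equal(back.coeffs, s.coeffs)
    assert back.transform == s.transform
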