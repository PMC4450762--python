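import numpy as np
import pytest

from phasesnake import (
    Contour,
    ContourCollapseError,
    ContourError,
    SnakeParams,
    VectorField,
    evolve,
    internal_force,
    resample,
    sample_field,
)

from helpers import random_star_contour, snake_step_reference


def zero_field(shape=(40, 40)):
    return VectorField(np.zeros(shape), np.zeros(shape))


def square(side=10.0, origin=(5.0, 5.0)):
    x0, y0 = origin
    return np.array([[x0, y0], [x0 + side, y0], [x0 + side, y0 + side], [x0, y0 + side]])


class TestContour:
    def test_too_few_points_rejected(self):
        with pytest.raises(ContourError):
            Contour([[0, 0], [1, 0], [1, 1]])

    def test_duplicate_consecutive_points_merged(self):
        c = Contour([[0, 0], [0, 0], [2, 0], [2, 2], [0, 2], [0, 0]])
        assert c.n == 4

    def test_orientation_normalized_to_positive_area(self):
        cw = square()[::-1]
        c = Contour(cw)
        assert c.signed_area > 0

    def test_geometry_of_square(self):
        c = Contour(square(10.0))
        assert c.area == pytest.approx(100.0)
        assert c.perimeter == pytest.approx(40.0)
        assert np.allclose(c.centroid, [10.0, 10.0])


class TestInternalForce:
    def test_collinear_equispaced_point_has_zero_second_difference(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [2, 2], [0, 2]], float)
        f = internal_force(pts, alpha=1.0, beta=0.0, ds=1.0)
        assert np.allclose(f[1], 0.0)

    def test_regular_polygon_forces_point_inward_with_equal_magnitude(self):
        n = 12
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        pts = np.column_stack([10 * np.cos(theta), 10 * np.sin(theta)])
        f = internal_force(pts, alpha=1.0, beta=0.0, ds=1.0)
        mags = np.linalg.norm(f, axis=1)
        assert np.allclose(mags, mags[0])
        inward = -pts / np.linalg.norm(pts, axis=1, keepdims=True)
        assert np.allclose(f / mags[:, None], inward)

    def test_zero_weights_give_zero_force(self, rng):
        pts = random_star_contour(rng)
        assert np.allclose(internal_force(pts, 0.0, 0.0), 0.0)


class TestSampleField:
    def test_integer_grid_point_returns_stored_vector(self, rng):
        u, v = rng.normal(size=(2, 10, 10))
        f = VectorField(u, v)
        assert np.allclose(sample_field(f, (3.0, 7.0)), [u[7, 3], v[7, 3]])

    def test_midpoint_bilinear_average(self):
        u = np.zeros((2, 2))
        v = np.zeros((2, 2))
        u[0, 0], v[0, 0] = 1.0, 0.0
        u[0, 1], v[0, 1] = 0.0, 1.0
        out = sample_field(VectorField(u, v), (0.5, 0.0))
        assert np.allclose(out, [0.5, 0.5])

    def test_far_outside_point_clamps_to_border(self, rng):
        u, v = rng.normal(size=(2, 8, 8))
        f = VectorField(u, v)
        assert np.allclose(sample_field(f, (1000.0, -50.0)), [u[0, 7], v[0, 7]])


class TestEq13Step:
    def test_four_point_square_matches_hand_evaluation(self):
        pts = square(4.0, origin=(10.0, 10.0))
        params = SnakeParams(
            alpha=1.0, beta=0.0, gamma=0.01, n_iter=1, resample_every=0, ds=None
        )  # ds=None -> h = 1/(N-1) = 1/3
        res = evolve(Contour(pts), zero_field(), params)
        h = 1.0 / 3.0
        expected = np.empty_like(pts)
        for i in range(4):
            d2 = (pts[(i + 1) % 4] - 2 * pts[i] + pts[(i - 1) % 4]) / h**2
            expected[i] = pts[i] + 0.01 * 1.0 * d2
        assert np.allclose(res.contour.points, expected, atol=1e-12)

    def test_random_contours_match_scalar_loop_to_1e10(self, rng):
        for _ in range(10):
            pts = random_star_contour(rng, n=32, radius=10, center=(16, 16))
            u = 0.4 * rng.standard_normal((33, 33))
            v = 0.4 * rng.standard_normal((33, 33))
            field = VectorField(u, v)
            # gamma tiny: the 4th difference divided by h^4 is ~1e6
            alpha, beta, gamma = 0.7, 0.12, 1e-8
            h = 1.0 / 31.0
            params = SnakeParams(
                alpha=alpha, beta=beta, gamma=gamma, n_iter=1, resample_every=0, ds=h
            )
            got = evolve(Contour(pts), field, params).contour.points
            want = snake_step_reference(pts, u, v, alpha, beta, gamma, h)
            assert np.abs(got - want).max() < 1e-10


class TestEvolve:
    def test_perimeter_strictly_decreases_under_curvature_flow(self):
        theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
        pts = np.column_stack([20 + 10 * np.cos(theta), 20 + 10 * np.sin(theta)])
        perims = [Contour(pts).perimeter]
        c = Contour(pts)
        for _ in range(5):
            c = evolve(c, zero_field(), SnakeParams(alpha=1.0, beta=0.0, gamma=0.05,
                                                    n_iter=1, resample_every=0)).contour
            perims.append(c.perimeter)
        assert all(a > b for a, b in zip(perims, perims[1:]))

    def test_bending_energy_non_increasing_with_beta_only(self, rng):
        pts = random_star_contour(rng, n=40, radius=12, center=(20, 20))

        def bend(p):
            d2 = np.roll(p, -1, axis=0) - 2 * p + np.roll(p, 1, axis=0)
            return float(np.sum(d2**2))

        c = Contour(pts)
        vals = [bend(c.points)]
        for _ in range(5):
            c = evolve(c, zero_field(), SnakeParams(alpha=0.0, beta=0.05, gamma=0.1,
                                                    n_iter=1, resample_every=0)).contour
            vals.append(bend(c.points))
        assert all(a >= b - 1e-12 for a, b in zip(vals, vals[1:]))

    def test_deterministic(self, rng):
        pts = random_star_contour(rng, n=30, radius=9, center=(16, 16))
        u = rng.normal(size=(33, 33)) * 0.3
        field = VectorField(u, u.T.copy())
        params = SnakeParams(n_iter=40)
        a = evolve(Contour(pts), field, params)
        b = evolve(Contour(pts), field, params)
        assert np.array_equal(a.contour.points, b.contour.points)
        assert a.iterations == b.iterations

    def test_collapse_raises(self):
        pts = square(3.0, origin=(10.0, 10.0))
        params = SnakeParams(alpha=2.0, beta=0.0, gamma=0.2, n_iter=200, resample_every=0)
        with pytest.raises(ContourCollapseError, match="collapse"):
            evolve(Contour(pts), zero_field(), params)

    def test_iteration_budget_respected(self, rng):
        pts = random_star_contour(rng, n=24, radius=8, center=(16, 16))
        res = evolve(Contour(pts), zero_field(), SnakeParams(n_iter=7, alpha=0.1, beta=0.0))
        assert res.iterations <= 7


class TestResample:
    def test_uniform_contour_is_fixpoint(self):
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        pts = np.column_stack([50 + 30 * np.cos(theta), 50 + 30 * np.sin(theta)])
        c = Contour(pts)
        spacing = c.perimeter / 64
        out = resample(c, spacing)
        assert out.n == 64
        assert np.abs(out.points - pts).max() < 1e-6

    def test_circle_resampled_to_uniform_angles(self):
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.column_stack([60 + 50 * np.cos(theta), 60 + 50 * np.sin(theta)])
        target = 2 * np.pi * 50 / 64
        out = resample(Contour(pts), target)
        assert out.n == 64
        ang = np.unwrap(np.arctan2(out.points[:, 1] - 60, out.points[:, 0] - 60))
        gaps = np.degrees(np.diff(ang))
        assert np.all(np.abs(gaps - gaps.mean()) < 0.5)

    def test_perimeter_preserved_within_one_percent(self):
        # smooth star-shaped contour, well resolved at the target spacing
        theta = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        r = 20 + 2 * np.cos(3 * theta) + 1.2 * np.sin(5 * theta)
        pts = np.column_stack([30 + r * np.cos(theta), 30 + r * np.sin(theta)])
        c = Contour(pts)
        out = resample(c, 2.0)
        assert abs(out.perimeter - c.perimeter) / c.perimeter < 0.01

    def test_minimum_point_count(self):
        out = resample(Contour(square(4.0)), target_spacing=10.0)
        assert out.n >= 16
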