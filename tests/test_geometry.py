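"""Geometric primitives: projections, in-plane distances, rotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from jointline.geometry import (
    DegenerateLineError,
    GeometryError,
    Line3,
    ParallelDirectionsError,
    Plane3,
    RigidTransform,
    angle_between_deg,
    in_plane_point_line_distance,
    plane_from_two_directions,
    project_point_onto_line,
    project_point_onto_plane,
    rotate_direction,
)

X = np.array([1.0, 0.0, 0.0])
Y = np.array([0.0, 1.0, 0.0])
Z = np.array([0.0, 0.0, 1.0])


class TestProjections:
    def test_point_in_plane_is_fixed(self):
        pl = Plane3(np.zeros(3), Z)
        p = np.array([3.0, -2.0, 0.0])
        assert np.allclose(project_point_onto_plane(p, pl), p)

    def test_plane_projection_drops_normal_component(self):
        pl = Plane3(np.zeros(3), Z)
        assert np.allclose(project_point_onto_plane([0, 0, 5], pl), [0, 0, 0])

    def test_plane_projection_matches_plane_equation(self, rng):
        for _ in range(20):
            pl = Plane3(rng.normal(size=3), rng.normal(size=3))
            p = rng.normal(size=3) * 10
            q = project_point_onto_plane(p, pl)
            # residual is parallel to the normal, length = analytic distance
            d = abs(np.dot(p - pl.point, pl.normal))
            assert abs(np.linalg.norm(p - q) - d) < 1e-9
            assert abs(np.dot(q - pl.point, pl.normal)) < 1e-9

    def test_point_on_line_is_fixed(self):
        l = Line3(np.zeros(3), X)
        assert np.allclose(project_point_onto_line([2, 0, 0], l), [2, 0, 0])

    def test_line_projection_example(self):
        l = Line3(np.zeros(3), X)
        assert np.allclose(project_point_onto_line([1, 1, 0], l), [1, 0, 0])

    def test_line_projection_residual_is_orthogonal(self, rng):
        for _ in range(20):
            l = Line3(rng.normal(size=3), rng.normal(size=3))
            p = rng.normal(size=3) * 10
            q = project_point_onto_line(p, l)
            assert abs(np.dot(p - q, l.direction)) < 1e-9


class TestInPlaneDistance:
    def test_zero_for_point_on_line(self):
        pl = Plane3(np.zeros(3), Z)
        l = Line3(np.zeros(3), X)
        assert in_plane_point_line_distance([4, 0, 0], l, pl) == pytest.approx(0.0)

    def test_simple_offset(self):
        pl = Plane3(np.zeros(3), Z)
        l = Line3(np.zeros(3), X)
        assert in_plane_point_line_distance([0, 10, 0], l, pl) == pytest.approx(10.0)

    def test_matches_brute_force_minimum(self, rng):
        pl = Plane3(rng.normal(size=3), rng.normal(size=3))
        l = Line3(rng.normal(size=3) * 5, rng.normal(size=3))
        p = rng.normal(size=3) * 20
        d = in_plane_point_line_distance(p, l, pl)
        # brute force: project dense line samples and the point into the
        # plane, take the minimum in-plane separation
        ts = np.linspace(-300, 300, 400001)
        pts = l.origin + np.outer(ts, l.direction)
        proj = pts - np.outer((pts - pl.point) @ pl.normal, pl.normal)
        p2 = project_point_onto_plane(p, pl)
        brute = np.linalg.norm(proj - p2, axis=1).min()
        assert d == pytest.approx(brute, abs=1e-4)

    def test_degenerate_projected_line_raises(self):
        pl = Plane3(np.zeros(3), Z)
        l = Line3(np.zeros(3), Z)  # perpendicular to the plane
        with pytest.raises(DegenerateLineError):
            in_plane_point_line_distance([1, 1, 1], l, pl)

    def test_homogeneous_under_in_plane_scaling(self, rng):
        pl = Plane3(np.zeros(3), Z)
        l = Line3([1.0, 2.0, 0.0], [1.0, 1.0, 0.0])
        p = np.array([-3.0, 5.0, 0.0])
        d1 = in_plane_point_line_distance(p, l, pl)
        s = 2.7
        l2 = Line3(np.asarray(l.origin) * s, l.direction)
        d2 = in_plane_point_line_distance(p * s, l2, pl)
        assert d2 == pytest.approx(s * d1, abs=1e-9)


class TestRotations:
    def test_zero_angle_is_identity(self):
        v = np.array([0.3, 0.5, np.sqrt(1 - 0.34)])
        assert np.allclose(rotate_direction(v, Z, 0.0), v)

    def test_quarter_turn(self):
        assert np.allclose(rotate_direction(X, Z, 90.0), Y, atol=1e-12)

    def test_rotation_composes(self):
        one = rotate_direction(rotate_direction(X, Z, 3.0), Z, 3.0)
        two = rotate_direction(X, Z, 6.0)
        assert np.allclose(one, two, atol=1e-9)

    def test_angle_matches_request_for_orthogonal_axis(self):
        out = rotate_direction(X, Z, 37.0)
        assert angle_between_deg(X, out) == pytest.approx(37.0, abs=1e-9)


class TestPlaneFromDirections:
    def test_xy_gives_z_normal(self):
        pl = plane_from_two_directions(np.zeros(3), X, Y)
        assert abs(abs(np.dot(pl.normal, Z)) - 1) < 1e-12

    def test_normal_orthogonal_to_inputs(self, rng):
        for _ in range(10):
            d1, d2 = rng.normal(size=3), rng.normal(size=3)
            pl = plane_from_two_directions(rng.normal(size=3), d1, d2)
            assert abs(np.dot(pl.normal, d1 / np.linalg.norm(d1))) < 1e-9
            assert abs(np.dot(pl.normal, d2 / np.linalg.norm(d2))) < 1e-9

    def test_swapping_directions_defines_same_plane(self):
        p = np.array([1.0, 2.0, 3.0])
        a = plane_from_two_directions(p, X, Y)
        b = plane_from_two_directions(p, Y, X)
        assert abs(abs(np.dot(a.normal, b.normal)) - 1) < 1e-12

    def test_parallel_directions_raise(self):
        with pytest.raises(ParallelDirectionsError):
            plane_from_two_directions(np.zeros(3), X, -X)


coords = st.floats(min_value=-100.0, max_value=100.0, allow_nan=False, width=64)


class TestPropertyBased:
    @given(st.tuples(coords, coords, coords), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_projection_residual_orthogonality(self, p, seed):
        rng = np.random.default_rng(seed)
        l = Line3(rng.normal(size=3), rng.normal(size=3))
        q = project_point_onto_line(np.array(p), l)
        assert abs(np.dot(np.array(p) - q, l.direction)) < 1e-7

    @given(st.floats(0.1, 10.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_in_plane_distance_scales_linearly(self, scale, seed):
        rng = np.random.default_rng(seed)
        n = rng.normal(size=3)
        pl = Plane3(np.zeros(3), n)
        o, d = rng.normal(size=3), rng.normal(size=3)
        if abs(np.dot(d / np.linalg.norm(d), n / np.linalg.norm(n))) > 0.99:
            return  # nearly perpendicular line: projection degenerates
        p = rng.normal(size=3) * 10
        l = Line3(o, d)
        d1 = in_plane_point_line_distance(p, l, pl)
        d2 = in_plane_point_line_distance(p * scale, Line3(o * scale, d), pl)
        assert d2 == pytest.approx(scale * d1, rel=1e-7, abs=1e-9)


class TestRigidTransform:
    def test_reflection_rejected(self):
        r = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(GeometryError):
            RigidTransform(r, np.zeros(3))

    def test_inverse_roundtrip(self, rng):
        t = RigidTransform.random(rng)
        p = rng.normal(size=(5, 3)) * 50
        assert np.allclose(t.inverse().apply(t.apply(p)), p, atol=1e-9)

    def test_in_plane_distance_is_rigid_invariant(self, rng):
        pl = Plane3(rng.normal(size=3), rng.normal(size=3))
        l = Line3(rng.normal(size=3) * 10, rng.normal(size=3))
        p = rng.normal(size=3) * 30
        d0 = in_plane_point_line_distance(p, l, pl)
        for _ in range(5):
            t = RigidTransform.random(rng)
            d1 = in_plane_point_line_distance(
                t.apply(p), t.apply_line(l), t.apply_plane(pl)
            )
            assert d1 == pytest.approx(d0, abs=1e-6)
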