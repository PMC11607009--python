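"""Axis fitting, rotation about an arbitrary 3D line, candidate orbits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from fidkit import (
    DegenerateAxisError,
    DegenerateOrbitError,
    DeviceGeometry,
    LineAxis,
    fit_axis,
    generate_candidates,
    rotate_about_axis,
    rotate_about_axis_expanded,
)

finite = st.floats(-100.0, 100.0, allow_nan=False)


def _random_axis(rng) -> LineAxis:
    d = rng.normal(size=3)
    return LineAxis(direction=d, pivot=rng.uniform(-50, 50, 3))


class TestFitAxis:
    def test_exactly_collinear_points(self):
        ax = fit_axis(np.array([[0.0, 0, 0], [0, 0, 5], [0, 0, 10]]))
        assert np.allclose(ax.direction, [0, 0, 1])
        assert np.allclose(ax.pivot, [0, 0, 5])
        assert ax.fit_residual == pytest.approx(0.0, abs=1e-12)

    def test_matches_eigendecomposition_oracle_under_jitter(self, rng):
        true_dir = np.array([1.0, 2.0, 2.0]) / 3.0
        t = np.array([-8.0, 0.0, 8.0])
        pts = np.array([10.0, -3.0, 4.0]) + np.outer(t, true_dir)
        pts = pts + rng.normal(0, 0.1, pts.shape)  # 0.1 mm isotropic jitter
        ax = fit_axis(pts)
        # independent oracle: eigen-decomposition of the 3x3 scatter matrix
        c = pts - pts.mean(axis=0)
        lam, vec = np.linalg.eigh(c.T @ c)
        oracle = vec[:, np.argmax(lam)]
        if oracle[np.argmax(np.abs(oracle))] < 0:
            oracle = -oracle
        assert np.allclose(ax.direction, oracle, atol=1e-9)
        angle = np.degrees(np.arccos(np.clip(abs(ax.direction @ true_dir), 0, 1)))
        assert angle < 2.0

    def test_residual_is_rms_perpendicular_distance(self):
        # points offset symmetrically from the x axis by 1 mm in y, with the
        # pattern chosen so the cross-covariance vanishes and the principal
        # direction stays exactly along x
        pts = np.array([[0.0, 1, 0], [10, -1, 0], [20, -1, 0], [30, 1, 0]])
        ax = fit_axis(pts)
        assert np.allclose(ax.direction, [1, 0, 0], atol=1e-9)
        assert ax.fit_residual == pytest.approx(1.0, abs=1e-9)

    def test_coincident_points_are_degenerate(self):
        with pytest.raises(DegenerateAxisError):
            fit_axis(np.array([[1.0, 2, 3], [1, 2, 3]]))

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(DegenerateAxisError):
            fit_axis(np.array([[1.0, 2, 3]]))

    def test_sign_rule_largest_component_positive(self):
        ax = fit_axis(np.array([[0.0, 0, 0], [0, 0, -10], [0, 0, -20]]))
        assert ax.direction[2] > 0


class TestRotateAboutAxis:
    Z = LineAxis(direction=np.array([0.0, 0, 1]), pivot=np.zeros(3))

    def test_zero_angle_is_identity(self, rng):
        p = rng.uniform(-50, 50, 3)
        assert np.allclose(rotate_about_axis(p, _random_axis(rng), 0.0), p)

    def test_sign_convention_lock(self):
        # Right-hand rule about the direction vector: the motion appears
        # clockwise when sighting along +z, and +90 deg maps x-hat onto y-hat.
        out = rotate_about_axis(np.array([1.0, 0, 0]), self.Z, 90.0)
        assert np.allclose(out, [0, 1, 0], atol=1e-12)

    def test_matches_quaternion_oracle(self, rng):
        for _ in range(25):
            ax = _random_axis(rng)
            p = rng.uniform(-80, 80, 3)
            theta = rng.uniform(-720, 720)
            got = rotate_about_axis(p, ax, theta)
            # independent oracle: translate to pivot, quaternion rotation, back
            q = Rotation.from_rotvec(np.radians(theta) * ax.direction)
            expected = q.apply(p - ax.pivot) + ax.pivot
            assert np.allclose(got, expected, atol=1e-9)

    def test_expanded_scalar_form_equals_rodrigues(self, rng):
        for _ in range(25):
            ax = _random_axis(rng)
            p = rng.uniform(-80, 80, 3)
            theta = rng.uniform(-360, 360)
            assert np.allclose(
                rotate_about_axis(p, ax, theta),
                rotate_about_axis_expanded(p, ax, theta),
                atol=1e-9,
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(x=finite, y=finite, z=finite, t1=st.floats(-360, 360), t2=st.floats(-360, 360))
    def test_rotation_group_property(self, x, y, z, t1, t2):
        ax = LineAxis(direction=np.array([1.0, 1, 1]), pivot=np.array([5.0, -3, 2]))
        p = np.array([x, y, z])
        once = rotate_about_axis(p, ax, t1 + t2)
        twice = rotate_about_axis(rotate_about_axis(p, ax, t1), ax, t2)
        assert np.allclose(once, twice, atol=1e-9)

    def test_distance_and_axial_coordinate_preserved(self, rng):
        ax = _random_axis(rng)
        p = rng.uniform(-80, 80, 3)
        out = rotate_about_axis(p, ax, 123.4)
        assert ax.distance_to(out) == pytest.approx(ax.distance_to(p), abs=1e-9)
        assert ax.axial_coordinate(out) == pytest.approx(
            ax.axial_coordinate(p), abs=1e-9
        )

    def test_non_unit_direction_normalized_on_construction(self):
        ax = LineAxis(direction=np.array([0.0, 0, 7]), pivot=np.zeros(3))
        assert np.linalg.norm(ax.direction) == pytest.approx(1.0, abs=1e-12)


class TestCandidates:
    def test_default_device_yields_ten_candidates(self, geometry):
        ax = LineAxis(direction=np.array([0.0, 0, 1]), pivot=np.zeros(3))
        cs = generate_candidates(np.array([60.0, 0, -10]), ax, geometry, "blue")
        assert cs.n_positions == 10

    def test_first_candidate_is_home_bit_exactly(self, geometry):
        ax = LineAxis(direction=np.array([0.0, 0, 1]), pivot=np.zeros(3))
        home = np.array([60.0, 0.1, -10.0])
        cs = generate_candidates(home, ax, geometry, "blue")
        assert (cs.position(1) == home).all()

    def test_consecutive_angular_separation_is_step(self, geometry, rng):
        ax = _random_axis(rng)
        home = ax.pivot + 60.0 * _perp(ax.direction) + 5.0 * ax.direction
        cs = generate_candidates(home, ax, geometry, "blue")
        for k in range(cs.n_positions):
            a = cs.candidates[k] - ax.pivot
            b = cs.candidates[(k + 1) % cs.n_positions] - ax.pivot
            a -= (a @ ax.direction) * ax.direction
            b -= (b @ ax.direction) * ax.direction
            cosang = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
            assert np.degrees(np.arccos(np.clip(cosang, -1, 1))) == pytest.approx(
                36.0, abs=1e-6
            )

    def test_orbit_radius_and_axial_coordinate_constant(self, geometry, rng):
        ax = _random_axis(rng)
        home = ax.pivot + 75.0 * _perp(ax.direction) - 12.0 * ax.direction
        cs = generate_candidates(home, ax, geometry, "green")
        dists = ax.distance_to(cs.candidates)
        axial = ax.axial_coordinate(cs.candidates)
        assert np.allclose(dists, ax.distance_to(home), atol=1e-6)
        assert np.allclose(axial, ax.axial_coordinate(home), atol=1e-6)

    def test_full_orbit_closes(self, geometry):
        ax = LineAxis(direction=np.array([1.0, 2, 3]), pivot=np.array([4.0, 5, 6]))
        p = np.array([50.0, -20.0, 10.0])
        out = p
        for _ in range(geometry.positions_per_wheel):
            out = rotate_about_axis(out, ax, geometry.angular_step_deg)
        assert np.allclose(out, p, atol=1e-9)

    def test_home_on_axis_is_degenerate(self, geometry):
        ax = LineAxis(direction=np.array([0.0, 0, 1]), pivot=np.zeros(3))
        with pytest.raises(DegenerateOrbitError):
            generate_candidates(np.array([0.0, 0, -10]), ax, geometry, "blue")


def _perp(d: np.ndarray) -> np.ndarray:
    a = np.array([1.0, 0, 0]) if abs(d[0]) < 0.9 else np.array([0.0, 1, 0])
    u = a - (a @ d) * d
    return u / np.linalg.norm(u)
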