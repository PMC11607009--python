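"""Rigid fit, FRE/FLE estimators and the analytic TRE model."""

import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from fidkit import (
    DegenerateFiducialsError,
    PhantomSpec,
    RigidTransform,
    UndefinedEstimatorError,
    WheelConfiguration,
    estimate_fle,
    evaluate_session,
    measure_tre,
    predict_tre,
    predict_tre_monte_carlo,
    register_rigid,
    simulate_tracking_session,
)


def _random_rigid(rng) -> RigidTransform:
    r = Rotation.random(rng=rng).as_matrix()
    return RigidTransform(r, rng.uniform(-100, 100, 3))


class TestRegisterRigid:
    def test_identity_on_identical_point_sets(self, rng):
        pts = rng.uniform(-50, 50, (5, 3))
        t, fre = register_rigid(pts, pts)
        assert np.allclose(t.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(t.translation, 0, atol=1e-10)
        assert fre < 1e-10

    def test_exact_recovery_of_known_motion(self, rng):
        for _ in range(20):
            pts = rng.uniform(-80, 80, (4, 3))
            truth = _random_rigid(rng)
            t, fre = register_rigid(pts, truth.apply(pts))
            assert np.allclose(t.rotation, truth.rotation, atol=1e-9)
            assert np.allclose(t.translation, truth.translation, atol=1e-9)
            assert fre < 1e-9

    def test_fre_matches_six_parameter_numerical_minimizer(self, rng):
        """The closed-form fit attains the optimum of the explicit 6-DOF
        least-squares problem (independent general-purpose optimizer)."""
        for _ in range(3):
            src = rng.uniform(-60, 60, (4, 3))
            truth = _random_rigid(rng)
            tgt = truth.apply(src) + rng.normal(0, 0.5, src.shape)
            _, fre_closed = register_rigid(src, tgt)

            def cost(params):
                rot = Rotation.from_rotvec(params[:3]).as_matrix()
                resid = src @ rot.T + params[3:] - tgt
                return np.sqrt((resid**2).sum(axis=1).mean())

            x0 = np.concatenate(
                [Rotation.from_matrix(truth.rotation).as_rotvec(), truth.translation]
            )
            res = minimize(cost, x0, method="Nelder-Mead",
                           options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
            assert fre_closed <= res.fun + 1e-9
            assert abs(fre_closed - res.fun) < 1e-6

    def test_fewer_than_three_points_rejected(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0]])
        with pytest.raises(DegenerateFiducialsError):
            register_rigid(pts, pts)

    def test_collinear_points_trip_reflection_guard(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(DegenerateFiducialsError):
            register_rigid(pts, pts)

    def test_fre_invariant_under_common_rigid_motion(self, rng):
        src = rng.uniform(-50, 50, (6, 3))
        tgt = src + rng.normal(0, 1.0, src.shape)
        _, fre0 = register_rigid(src, tgt)
        motion = _random_rigid(rng)
        _, fre1 = register_rigid(motion.apply(src), motion.apply(tgt))
        assert fre1 == pytest.approx(fre0, abs=1e-9)


class TestTransformSerialization:
    def test_json_round_trip(self, tmp_path, rng):
        t = _random_rigid(rng)
        t.to_json(tmp_path / "t.json")
        back = RigidTransform.from_json(tmp_path / "t.json")
        assert np.allclose(back.rotation, t.rotation, atol=1e-15)
        assert np.allclose(back.translation, t.translation, atol=1e-15)

    def test_homogeneous_matrix_file_round_trip(self, tmp_path, rng):
        t = _random_rigid(rng)
        t.to_matrix_file(tmp_path / "t.txt")
        back = RigidTransform.from_matrix_file(tmp_path / "t.txt")
        assert np.allclose(back.as_matrix(), t.as_matrix(), atol=1e-12)

    def test_reflection_rejected_on_construction(self):
        with pytest.raises(ValueError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestEstimateFle:
    def test_zero_fre_gives_zero_fle(self):
        assert estimate_fle([0.0, 0.0, 0.0], 4) == 0.0

    def test_printed_formula_arithmetic(self):
        # N = 4, all FREs 0.5 mm: mu = 0.25 mm^2, FLE^2 = 2 * 0.25 = 0.5 mm^2
        assert estimate_fle([0.5, 0.5, 0.5], 4) == pytest.approx(
            np.sqrt(0.5), abs=1e-12
        )

    @pytest.mark.parametrize("n", [0, 1, 2])
    def test_undefined_below_three_fiducials(self, n):
        with pytest.raises(UndefinedEstimatorError):
            estimate_fle([0.5], n)

    def test_empty_or_negative_repeats_rejected(self):
        with pytest.raises(UndefinedEstimatorError):
            estimate_fle([], 4)
        with pytest.raises(UndefinedEstimatorError):
            estimate_fle([0.3, -0.1], 4)

    def test_monte_carlo_recovery_of_true_fle(self, small_spec):
        """Simulated sessions: the FRE-based estimator recovers the true FLE
        RMS — roughly at 10 repeats, closely at 10^4 repeats."""
        true_fle = small_spec.tracker_fle_rms_mm
        home = WheelConfiguration.home(small_spec.geometry)
        few = simulate_tracking_session(small_spec, home, n_repeats=10, rng=1)
        est_few = estimate_fle(
            [float(f) for f in _session_fres(few)], few.n_fiducials
        )
        assert abs(est_few - true_fle) / true_fle < 0.25
        many = simulate_tracking_session(small_spec, home, n_repeats=10_000, rng=2)
        est_many = estimate_fle(
            [float(f) for f in _session_fres(many)], many.n_fiducials
        )
        assert abs(est_many - true_fle) / true_fle < 0.05

    @pytest.mark.parametrize("n_fid", [4, 6, 8, 10])
    def test_mean_squared_fre_approaches_theory(self, n_fid, rng):
        """<FRE^2> -> (1 - 2/N) FLE^2 for isotropic FLE, any fiducial count."""
        from fidkit.registration import _register_batch

        fle = 0.4
        fid = rng.uniform(-50, 50, (n_fid, 3))
        reps = 4000
        noisy = fid + rng.normal(0, fle / np.sqrt(3), (reps, n_fid, 3))
        _, _, fre = _register_batch(noisy, np.broadcast_to(fid, noisy.shape))
        expected = (1 - 2 / n_fid) * fle**2
        assert np.mean(fre**2) == pytest.approx(expected, rel=0.05)


def _session_fres(session):
    from fidkit.registration import _register_batch

    src = session.fiducials_tracker
    tgt = np.broadcast_to(session.fiducials_image, src.shape)
    _, _, fre = _register_batch(src, tgt)
    return fre


class TestPredictTre:
    def test_centroid_limit_is_fle_over_sqrt_n(self, rng):
        fid = rng.uniform(-40, 40, (5, 3))
        tre = predict_tre(fid, fid.mean(axis=0), fle_rms=0.6)
        assert tre == pytest.approx(0.6 / np.sqrt(5), rel=1e-12)

    def test_zero_fle_means_zero_tre(self, rng):
        fid = rng.uniform(-40, 40, (4, 3))
        assert predict_tre(fid, rng.uniform(-80, 80, 3), 0.0) == 0.0

    def test_collinear_fiducials_rejected(self):
        fid = np.array([[0.0, 0, 0], [10, 0, 0], [20, 0, 0], [30, 0, 0]])
        with pytest.raises(DegenerateFiducialsError):
            predict_tre(fid, np.array([5.0, 5, 5]), 0.4)

    def test_matches_monte_carlo_registration_oracle(self):
        # regular tetrahedron, target offset along a principal axis
        fid = 40.0 * np.array(
            [[1.0, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]]
        )
        target = fid.mean(axis=0) + np.array([55.0, 0, 0])
        analytic = predict_tre(fid, target, 0.4)
        mc = predict_tre_monte_carlo(fid, target, 0.4, n_trials=50_000, rng=3)
        assert abs(analytic - mc) / mc < 0.03

    def test_invariant_under_fiducial_relabeling(self, rng):
        fid = rng.uniform(-40, 40, (6, 3))
        target = rng.uniform(-60, 60, 3)
        perm = rng.permutation(6)
        assert predict_tre(fid, target, 0.4) == pytest.approx(
            predict_tre(fid[perm], target, 0.4), rel=1e-12
        )

    def test_equivariant_under_rigid_motion(self, rng):
        fid = rng.uniform(-40, 40, (4, 3))
        target = rng.uniform(-60, 60, 3)
        motion = _random_rigid(rng)
        assert predict_tre(fid, target, 0.4) == pytest.approx(
            predict_tre(motion.apply(fid), motion.apply(target), 0.4), rel=1e-9
        )

    def test_monotone_away_from_centroid(self, rng):
        fid = rng.uniform(-40, 40, (4, 3))
        centroid = fid.mean(axis=0)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        tres = [
            predict_tre(fid, centroid + s * direction, 0.4)
            for s in (0.0, 10.0, 25.0, 50.0, 100.0)
        ]
        assert all(a < b for a, b in zip(tres, tres[1:]))


class TestMeasureTre:
    def test_identity_coincident_is_zero(self):
        t = RigidTransform.identity()
        assert measure_tre(t, np.zeros(3), np.zeros(3)) == 0.0

    def test_identity_one_mm_apart(self):
        t = RigidTransform.identity()
        assert measure_tre(t, np.zeros(3), np.array([1.0, 0, 0])) == 1.0

    def test_session_mean_tre_matches_prediction(self, small_spec):
        """End-to-end: RMS of repeated measured TREs tracks the analytic
        prediction for the session's noise level."""
        home = WheelConfiguration.home(small_spec.geometry)
        session = simulate_tracking_session(small_spec, home, n_repeats=500, rng=9)
        report = evaluate_session(session)
        for measured, predicted in zip(report.tre_measured, report.tre_predicted):
            assert abs(measured - predicted) / predicted < 0.10
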