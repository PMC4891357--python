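"""Endpoint-kinematics battery on constructed trajectories."""
import numpy as np
import pytest

from ucmreach import (
    TipTrajectory,
    accuracy_errors,
    curvature,
    detect_bounds,
    phase_times,
    tangential_velocity,
    time_normalize,
)
from ucmreach.errors import (
    DetectionFailureError,
    InsufficientDataError,
    InvalidInputError,
)
from ucmreach.kinematics import MovementBounds


def brute_force_bounds(traj, velocity, start, target, speed=25.0, radius=10.0):
    """Sample-by-sample scan of the two detection predicates."""
    d_start = np.linalg.norm(traj.position - start, axis=1)
    d_target = np.linalg.norm(traj.position - target, axis=1)
    s = None
    for i in range(traj.n_samples):
        if velocity[i] > speed and d_start[i] > radius:
            s = i
            break
    assert s is not None
    for j in range(s + 1, traj.n_samples):
        if velocity[j] < speed and d_target[j] < radius:
            return s, j
    raise AssertionError("no end found")


class TestTangentialVelocity:
    def test_constant_speed_line(self):
        t = np.arange(50) * 0.01
        pos = np.outer(t * 100.0, [1.0, 0.0, 0.0])
        traj = TipTrajectory(t, pos)
        np.testing.assert_allclose(tangential_velocity(traj), 100.0, atol=1e-9)

    def test_stationary(self):
        t = np.arange(10) * 0.01
        traj = TipTrajectory(t, np.ones((10, 3)))
        np.testing.assert_allclose(tangential_velocity(traj), 0.0, atol=1e-12)

    def test_minimum_jerk_peak_closed_form(self, clean_reach):
        traj, _, _ = clean_reach
        v = tangential_velocity(traj)
        # peak speed of the quintic profile: 15/8 * amplitude / duration
        assert v.max() == pytest.approx(1.875 * 300.0 / 1.0, rel=0.01)

    def test_nonuniform_sampling_rejected(self):
        t = np.array([0.0, 0.01, 0.03, 0.04])
        traj = TipTrajectory(t, np.zeros((4, 3)))
        with pytest.raises(InvalidInputError):
            tangential_velocity(traj)


class TestDetectBounds:
    def test_matches_brute_force_scan(self, clean_reach):
        traj, start, target = clean_reach
        v = tangential_velocity(traj)
        b = detect_bounds(traj, v, start, target)
        assert (b.start_index, b.end_index) == brute_force_bounds(
            traj, v, start, target
        )

    def test_sub_threshold_trajectory_fails_start(self):
        t = np.arange(100) * 0.01
        pos = np.outer(t * 10.0, [1.0, 0.0, 0.0])  # 10 mm/s, never > 25
        traj = TipTrajectory(t, pos)
        with pytest.raises(DetectionFailureError) as exc:
            detect_bounds(traj, tangential_velocity(traj), pos[0], pos[0] + 300)
        assert exc.value.which == "start"

    def test_stopping_short_fails_end(self, clean_reach):
        traj, start, target = clean_reach
        far_target = target + np.array([20.0, 0.0, 0.0])
        with pytest.raises(DetectionFailureError) as exc:
            detect_bounds(traj, tangential_velocity(traj), start, far_target)
        assert exc.value.which == "end"

    def test_idempotent_on_cropped_trajectory(self, clean_reach):
        traj, start, target = clean_reach
        v = tangential_velocity(traj)
        b = detect_bounds(traj, v, start, target)
        cropped = TipTrajectory(
            traj.time[b.start_index : b.end_index + 1],
            traj.position[b.start_index : b.end_index + 1],
        )
        b2 = detect_bounds(cropped, tangential_velocity(cropped), start, target)
        assert b2.start_index == 0
        assert b2.end_index == cropped.n_samples - 1


class TestPhaseTimes:
    def test_minimum_jerk_symmetry_over_true_span(self, clean_reach):
        # over the true movement span the quintic profile is symmetric
        traj, start, target = clean_reach
        v = tangential_velocity(traj)
        onset = int(np.flatnonzero(v > 1e-9)[0]) - 1  # last stationary sample
        offset = int(np.flatnonzero(v > 1e-9)[-1]) + 1
        b = MovementBounds(onset, offset, traj.time[offset] - traj.time[onset])
        acc, dec = phase_times(v, b, traj.time)
        assert abs(acc - dec) <= 0.010 + 1e-12  # within one 100 Hz sample
        assert acc + dec == pytest.approx(b.movement_time, abs=1e-12)

    def test_detected_bounds_shorten_acceleration_phase(self, clean_reach):
        # the study's conjunction rule starts the movement only once the
        # tip leaves the 10 mm start dot (already at ~146 mm/s), so the
        # detected acceleration phase is systematically shorter than the
        # deceleration phase even for a symmetric profile
        traj, start, target = clean_reach
        v = tangential_velocity(traj)
        b = detect_bounds(traj, v, start, target)
        acc, dec = phase_times(v, b, traj.time)
        assert acc + dec == pytest.approx(b.movement_time, abs=1e-12)
        assert dec - acc == pytest.approx(0.107, abs=0.02)

    def test_monotone_decreasing_velocity(self):
        t = np.arange(10) * 0.01
        v = np.linspace(100.0, 10.0, 10)
        b = MovementBounds(0, 9, 0.09)
        acc, dec = phase_times(v, b, t)
        assert acc == 0.0 and dec == pytest.approx(0.09)

    def test_peak_at_final_sample(self):
        t = np.arange(10) * 0.01
        v = np.linspace(10.0, 100.0, 10)
        b = MovementBounds(0, 9, 0.09)
        acc, dec = phase_times(v, b, t)
        assert dec == 0.0 and acc == pytest.approx(0.09)


class TestCurvature:
    def test_straight_path_zero(self, clean_reach):
        traj, start, target = clean_reach
        b = MovementBounds(0, traj.n_samples - 1, traj.time[-1])
        assert curvature(traj, b, start, target, "horizontal") < 1e-9
        assert curvature(traj, b, start, target, "vertical") < 1e-9

    def test_constructed_bulge(self):
        t = np.arange(101) * 0.01
        x = np.linspace(0.0, 300.0, 101)
        y = 15.0 * np.sin(np.pi * x / 300.0)  # bulge +y, max 15 at midpoint
        pos = np.column_stack([x, y, np.zeros_like(x)])
        traj = TipTrajectory(t, pos)
        b = MovementBounds(0, 100, 1.0)
        start, target = pos[0], pos[-1]
        assert curvature(traj, b, start, target, "horizontal") == pytest.approx(15.0)
        assert curvature(traj, b, start, target, "vertical") == pytest.approx(0.0)

    def test_circular_arc_sagitta(self):
        # arc in the x-z plane: chord 300 mm, radius 300 mm ->
        # sagitta = r - sqrt(r^2 - (c/2)^2) = 300 - sqrt(300^2 - 150^2)
        r, chord = 300.0, 300.0
        half_angle = np.arcsin(chord / (2 * r))
        theta = np.linspace(-half_angle, half_angle, 101)
        x = r * np.sin(theta) + chord / 2.0
        z = r * np.cos(theta) - np.sqrt(r**2 - (chord / 2) ** 2)
        pos = np.column_stack([x, np.zeros_like(x), z])
        traj = TipTrajectory(np.arange(101) * 0.01, pos)
        b = MovementBounds(0, 100, 1.0)
        sagitta = r - np.sqrt(r**2 - (chord / 2) ** 2)
        got = curvature(traj, b, pos[0], pos[-1], "vertical")
        assert got == pytest.approx(sagitta, abs=0.5)
        assert sagitta == pytest.approx(40.19, abs=0.01)

    def test_translation_invariance(self, rng):
        t = np.arange(50) * 0.01
        pos = np.cumsum(rng.standard_normal((50, 3)), axis=0) + np.outer(
            np.linspace(0, 300, 50), [1, 0, 0]
        )
        traj = TipTrajectory(t, pos)
        b = MovementBounds(0, 49, 0.49)
        shift = np.array([123.0, -45.0, 67.0])
        traj2 = TipTrajectory(t, pos + shift)
        for plane in ("horizontal", "vertical"):
            assert curvature(traj, b, pos[0], pos[-1], plane) == pytest.approx(
                curvature(traj2, b, pos[0] + shift, pos[-1] + shift, plane)
            )

    def test_coincident_endpoints_rejected(self, clean_reach):
        traj, start, _ = clean_reach
        b = MovementBounds(0, 10, 0.1)
        with pytest.raises(InvalidInputError):
            curvature(traj, b, start, start, "horizontal")


class TestAccuracyErrors:
    def test_perfect_endpoints(self):
        target = np.array([500.0, 0.0, -300.0])
        abs_err, var_err = accuracy_errors(np.tile(target, (5, 1)), target)
        assert abs_err == 0.0 and var_err == 0.0

    def test_two_point_arithmetic(self):
        target = np.zeros(3)
        endpoints = np.array([[3.0, 0, 0], [0, 5.0, 0]])
        abs_err, var_err = accuracy_errors(endpoints, target)
        assert abs_err == pytest.approx(4.0)
        assert var_err == pytest.approx(np.sqrt(2.0))

    def test_isotropic_noise_matches_monte_carlo(self, rng):
        # chi-distribution mean for 3-D isotropic sigma = 2 mm, against an
        # independent large-sample Monte-Carlo oracle
        sigma = 2.0
        target = np.array([100.0, 50.0, -20.0])
        endpoints = target + sigma * rng.standard_normal((1000, 3))
        abs_err, _ = accuracy_errors(endpoints, target)
        oracle = np.linalg.norm(
            sigma * np.random.default_rng(999).standard_normal((200000, 3)), axis=1
        ).mean()
        assert abs_err == pytest.approx(oracle, rel=0.06)

    def test_single_endpoint_rejected(self):
        with pytest.raises(InsufficientDataError):
            accuracy_errors(np.zeros((1, 3)), np.zeros(3))


class TestTimeNormalize:
    def test_constant_series(self):
        t = np.arange(50) * 0.01
        b = MovementBounds(5, 45, 0.40)
        out = time_normalize(np.full(50, 3.3), t, b)
        assert out.shape == (100,)
        np.testing.assert_allclose(out, 3.3)

    def test_linear_ramp(self):
        t = np.arange(101) * 0.01
        b = MovementBounds(0, 100, 1.0)
        a, bb = 2.0, 12.0
        series = a + (bb - a) * t  # linear in time over the movement
        out = time_normalize(series, t, b)
        k = np.arange(1, 101)
        np.testing.assert_allclose(out, a + (bb - a) * k / 100.0, atol=1e-12)

    def test_round_trip_linear_series(self):
        # a 100-sample series linear in time is reproduced by resampling
        t = np.arange(100) * 0.01
        b = MovementBounds(0, 99, 0.99)
        series = np.linspace(-4.0, 7.0, 100)
        out = time_normalize(series, t, b)
        # the normalized grid spans (t0, t_end]; endpoint matches exactly
        assert out[-1] == pytest.approx(series[-1], abs=1e-9)
        np.testing.assert_allclose(np.diff(out), np.diff(out)[0], atol=1e-9)

    def test_multicolumn_series(self, rng):
        t = np.arange(60) * 0.01
        b = MovementBounds(10, 50, 0.40)
        series = rng.standard_normal((60, 9))
        out = time_normalize(series, t, b)
        assert out.shape == (100, 9)
        np.testing.assert_allclose(out[-1], series[50], atol=1e-12)

    def test_too_few_samples_rejected(self):
        t = np.arange(10) * 0.01
        with pytest.raises(InvalidInputError):
            MovementBounds(3, 3, 0.0)
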