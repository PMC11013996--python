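import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinerehab import landmarks as lm
from kinerehab.kinematics import (JointTriplet, NORMATIVE_ROM_DEG,
                                  ROMSummary, angle_series, angular_velocity,
                                  check_guidelines, compare_to_normative,
                                  coordination, exercise_rom_report,
                                  joint_angle, rom_summary,
                                  trunk_rotation_angle, trunk_rotation_series)
from kinerehab.pipeline import segment_sequence
from kinerehab.signal_prep import MotionSignal, RepetitionSegment
from kinerehab.synthetic import EXERCISE_TEMPLATES
from conftest import single_phase


def atan2_angle(a, b, c):
    """Independent oracle: 2-D angle at b via atan2 of cross/dot."""
    u, v = np.asarray(a) - np.asarray(b), np.asarray(c) - np.asarray(b)
    cross = u[0] * v[1] - u[1] * v[0]
    dot = u[0] * v[0] + u[1] * v[1]
    return abs(math.degrees(math.atan2(cross, dot)))


coord = st.floats(-5, 5, allow_nan=False)


def frame_with_shoulders(xl, xr, zl=0.0, zr=0.0):
    from kinerehab.pose_model import KeypointFrame

    arr = np.zeros((lm.N_LANDMARKS, 4))
    arr[:, 0], arr[:, 1], arr[:, 3] = 0.5, 0.5, 1.0
    arr[lm.LEFT_SHOULDER, 0], arr[lm.RIGHT_SHOULDER, 0] = xl, xr
    arr[lm.LEFT_SHOULDER, 2], arr[lm.RIGHT_SHOULDER, 2] = zl, zr
    return KeypointFrame(arr, 0.0)


class TestJointAngle:
    def test_collinear_is_180(self):
        assert joint_angle((0, 0), (1, 0), (2, 0)) == pytest.approx(180.0)

    def test_right_angle(self):
        assert joint_angle((0, 1), (0, 0), (1, 0)) == pytest.approx(90.0)

    def test_degenerate_raises(self):
        with pytest.raises(ValueError):
            joint_angle((0.5, 0.5), (0.5, 0.5), (1, 0))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(ax=coord, ay=coord, bx=coord, by=coord, cx=coord, cy=coord)
    def test_matches_atan2_oracle(self, ax, ay, bx, by, cx, cy):
        a, b, c = (ax, ay), (bx, by), (cx, cy)
        if np.hypot(ax - bx, ay - by) < 1e-6 or np.hypot(cx - bx, cy - by) < 1e-6:
            return
        want = atan2_angle(a, b, c)
        if min(want, 180.0 - want) < 0.01:
            return  # arccos is ill-conditioned at near-collinearity
        got = joint_angle(a, b, c)
        assert got == pytest.approx(want, abs=1e-9)
        assert 0.0 <= got <= 180.0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(theta=st.floats(0, 2 * np.pi), scale=st.floats(0.1, 10),
           tx=coord, ty=coord)
    def test_similarity_invariance(self, theta, scale, tx, ty):
        a, b, c = np.array([0.1, 0.9]), np.array([0.4, 0.2]), np.array([0.8, 0.7])
        base = joint_angle(a, b, c)
        R = scale * np.array([[np.cos(theta), -np.sin(theta)],
                              [np.sin(theta), np.cos(theta)]])
        pts = [p @ R.T + [tx, ty] for p in (a, b, c)]
        assert joint_angle(*pts) == pytest.approx(base, abs=1e-7)


class TestAngleSeries:
    def test_sa_elbow_stays_straight(self):
        seq, _ = single_phase("SA", 150, 3.0, 3, noise=0.001, seed=1)
        elbow = angle_series(seq, JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_ELBOW,
                                               lm.LEFT_WRIST))
        assert np.all(elbow.values > 175.0)
        assert np.median(elbow.values) > 179.0

    def test_static_pose_gives_constant_series(self):
        seq, _ = single_phase("SS", 40, 2.0, 1, lead_s=2.0)
        hip = angle_series(seq, JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP,
                                             lm.LEFT_KNEE))
        lead = hip.values[:50]
        assert lead.max() - lead.min() < 1e-9

    def test_hip_series_peak_to_peak_matches_rom(self):
        seq, _ = single_phase("SS", 45, 2.0, 3, noise=0.001, seed=2)
        hip = angle_series(seq, JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP,
                                             lm.LEFT_KNEE))
        assert np.ptp(hip.values) == pytest.approx(45, abs=2)

    def test_driven_angles_recovered_on_clean_output(self):
        # generator ground-truth consistency at every frame
        seq, gt = single_phase("SS", 40, 2.0, 3)
        hip = angle_series(seq, JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP,
                                             lm.LEFT_KNEE))
        n = gt.phases[0].end
        t = np.arange(n) / 30.0
        driven = 40 * (1 - np.cos(2 * np.pi * t / 2.0)) / 2
        np.testing.assert_allclose(180.0 - hip.values[:n], driven, atol=0.5)

    def test_too_many_invisible_frames_rejected(self):
        seq, _ = single_phase("SS", 40, 2.0, 3)
        seq.data[: seq.n_frames // 2, lm.LEFT_KNEE, 3] = 0.0
        from kinerehab.kinematics import UnreliableSeriesError

        with pytest.raises(UnreliableSeriesError):
            angle_series(seq, JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP,
                                           lm.LEFT_KNEE))


class TestROM:
    def test_median_of_per_rep_maxima(self):
        fs = 30.0
        vals = np.concatenate([
            amp * np.sin(np.pi * np.arange(30) / 30) for amp in (40, 42, 44, 43, 41)
        ])
        ang = __import__("kinerehab.kinematics", fromlist=["AngleSeries"]).AngleSeries(
            vals, fs)
        reps = [RepetitionSegment(i * 30, (i + 1) * 30, 1.0) for i in range(5)]
        summ = rom_summary(ang, reps, mode="excursion")
        assert summ.median_max == pytest.approx(42, abs=0.5)

    def test_single_repetition(self):
        from kinerehab.kinematics import AngleSeries

        ang = AngleSeries(50 * np.sin(np.pi * np.arange(30) / 30), 30.0)
        summ = rom_summary(ang, [RepetitionSegment(0, 30, 1.0)])
        assert summ.median_max == pytest.approx(50, abs=0.5)

    def test_empty_reps_rejected(self):
        from kinerehab.kinematics import AngleSeries

        with pytest.raises(ValueError):
            rom_summary(AngleSeries(np.zeros(10), 30.0), [])

    def test_rom_recovery_on_generator(self):
        seq, _ = single_phase("SS", 40, 2.0, 5, noise=0.003, seed=7)
        reps, period, _, _ = segment_sequence(seq)
        report = exercise_rom_report(seq, "SS", reps)
        for r in report:
            assert r["median_max_deg"] == pytest.approx(40, abs=2)


class TestAngularVelocity:
    def test_direct_formula(self):
        assert angular_velocity(1.0, 2.0) == pytest.approx(0.5)
        assert angular_velocity(math.pi, 1.0) == pytest.approx(math.pi)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            angular_velocity(1.0, 0.0)

    def test_squat_velocity_from_generator(self):
        seq, _ = single_phase("SQT", 85, 3.0, 5, noise=0.002, seed=3)
        reps, _, _, _ = segment_sequence(seq)
        report = exercise_rom_report(seq, "SQT", reps)
        knee = next(r for r in report if r["measure"] == "squat_knee_flexion")
        expected = math.radians(85) / 3.0
        assert knee["omega_rad_s"] == pytest.approx(expected, rel=0.1)


class TestTrunkRotation:
    def test_neutral_width_is_zero_rotation(self):
        f = frame_with_shoulders(0.42, 0.58)
        assert trunk_rotation_angle(f, 0.16) == pytest.approx(0.0, abs=1e-3)

    def test_half_width_is_sixty_degrees(self):
        f = frame_with_shoulders(0.46, 0.54)
        assert abs(trunk_rotation_angle(f, 0.16)) == pytest.approx(60.0)

    def test_missing_calibration_rejected(self):
        with pytest.raises(ValueError):
            trunk_rotation_angle(frame_with_shoulders(0.42, 0.58), 0.0)

    def test_generator_rotation_recovered(self):
        seq, _ = single_phase("TR", 45, 3.0, 5, noise=0.003, seed=5)
        reps, _, _, _ = segment_sequence(seq)
        report = exercise_rom_report(seq, "TR", reps)
        assert report[0]["median_max_deg"] == pytest.approx(45, abs=3)

    def test_sign_alternates_with_direction(self):
        seq, _ = single_phase("TR", 45, 3.0, 2)
        rot = trunk_rotation_series(seq)
        assert rot.values.max() > 30 and rot.values.min() < -30


class TestCoordination:
    def test_identical_sinusoids_unify(self):
        t = np.arange(300) / 30.0
        x = np.sin(2 * np.pi * t / 2.0)
        res = coordination([MotionSignal(x, 30.0), MotionSignal(x.copy(), 30.0)],
                           period=2.0)
        assert res.unified
        assert res.lag_matrix[0, 1] == pytest.approx(0.0, abs=1 / 30)

    def test_constructed_shift_recovered_exactly(self):
        t = np.arange(450) / 30.0
        lag_samples = 9  # 0.3 s
        x = np.sin(2 * np.pi * t / 2.0)
        y = np.roll(x, lag_samples)
        res = coordination([MotionSignal(x, 30.0), MotionSignal(y, 30.0)],
                           parts=["lead", "follow"], period=2.0)
        assert res.lag_matrix[0, 1] == pytest.approx(0.3, abs=1 / 30)
        assert res.order == ["lead", "follow"]
        assert not res.unified

    def test_lag_matrix_antisymmetric(self, rng):
        t = np.arange(360) / 30.0
        base = np.sin(2 * np.pi * t / 3.0)
        sigs = [MotionSignal(np.roll(base, k) + 0.01 * rng.normal(size=t.size), 30.0)
                for k in (0, 5, 11)]
        res = coordination(sigs, period=3.0)
        np.testing.assert_allclose(res.lag_matrix, -res.lag_matrix.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(res.lag_matrix), 0.0)

    def test_constant_series_has_no_phase(self):
        with pytest.raises(ValueError, match="phase"):
            coordination([MotionSignal(np.zeros(100), 30.0),
                          MotionSignal(np.ones(100), 30.0)])

    def test_tr_arms_lag_trunk(self):
        seq, _ = single_phase("TR", 45, 3.0, 4, noise=0.002, seed=6)
        width = np.abs(seq.data[:, lm.LEFT_SHOULDER, 0]
                       - seq.data[:, lm.RIGHT_SHOULDER, 0])
        spread = np.abs(seq.data[:, lm.LEFT_WRIST, 0]
                        - seq.data[:, lm.RIGHT_WRIST, 0])
        res = coordination([MotionSignal(width, 30.0), MotionSignal(spread, 30.0)],
                           parts=["trunk", "arms"], period=3.0,
                           unify_threshold=0.15)
        assert res.order == ["trunk", "arms"]
        assert not res.unified


class TestGuidelines:
    def test_clean_exercises_have_zero_violations(self):
        for seed in range(4):
            for ex, (rom, per) in EXERCISE_TEMPLATES.items():
                seq, _ = single_phase(ex, rom, per, 4, noise=0.003, seed=800 + seed)
                reps, period, _, _ = segment_sequence(seq)
                assert check_guidelines(ex, seq, reps, 0.15, period) == [], ex

    def test_bent_elbow_flagged_every_repetition(self):
        seq, _ = single_phase("SA", 150, 3.0, 3, noise=0.003, seed=5,
                              errors={"bent_elbow_deg": 40})
        reps, period, _, _ = segment_sequence(seq)
        v = check_guidelines("SA", seq, reps, 0.15, period)
        assert [x.repetition for x in v] == list(range(len(reps)))
        assert all(x.message == "Keep the arms straight!" for x in v)

    def test_bent_knees_flagged_in_forward_bend(self):
        seq, _ = single_phase("FB", 100, 3.5, 3, noise=0.003, seed=5,
                              errors={"bent_knee_deg": 60})
        reps, period, _, _ = segment_sequence(seq)
        rules = {x.rule for x in check_guidelines("FB", seq, reps, 0.15, period)}
        assert rules == {"FB_straight_legs"}

    def test_knees_past_toes_flagged_in_squat(self):
        seq, _ = single_phase("SQT", 85, 3.0, 3, noise=0.003, seed=5,
                              errors={"knees_past_toes": 1})
        reps, period, _, _ = segment_sequence(seq)
        rules = {x.rule for x in check_guidelines("SQT", seq, reps, 0.15, period)}
        assert rules == {"SQT_knees_toes"}

    def test_unified_rotation_flagged(self):
        seq, _ = single_phase("TR", 45, 3.0, 4, noise=0.003, seed=5,
                              errors={"unified_trunk_rotation": 1})
        reps, period, _, _ = segment_sequence(seq)
        rules = {x.rule for x in check_guidelines("TR", seq, reps, 0.15, period)}
        assert "TR_unified" in rules

    def test_tolerance_outside_band_rejected(self):
        seq, _ = single_phase("SA", 150, 3.0, 2)
        with pytest.raises(ValueError):
            check_guidelines("SA", seq, [], tolerance=0.05)

    def test_unknown_exercise_rejected(self):
        seq, _ = single_phase("SA", 150, 3.0, 2)
        with pytest.raises(ValueError):
            check_guidelines("JUMP", seq, [])


class TestNormative:
    def test_hip_abduction_at_norm(self):
        summ = ROMSummary([40.0], 40.0, "SS", "left", "hip_abduction")
        ratio, below = compare_to_normative(summ)
        assert ratio == pytest.approx(1.0)
        assert not below

    def test_half_shoulder_norm_is_below(self):
        summ = ROMSummary([90.0], 90.0, "SA", "left", "shoulder_abduction")
        ratio, below = compare_to_normative(summ)
        assert ratio == pytest.approx(0.5)
        assert below

    def test_squat_knee_flexion_at_norm(self):
        summ = ROMSummary([85.0], 85.0, "SQT", "left", "squat_knee_flexion")
        ratio, _ = compare_to_normative(summ)
        assert ratio == pytest.approx(1.0)

    def test_unknown_measure_rejected(self):
        with pytest.raises(KeyError):
            compare_to_normative(ROMSummary([1.0], 1.0, "SS", "left", "flying"))

    def test_table_values(self):
        assert NORMATIVE_ROM_DEG["hip_abduction"] == 40
        assert NORMATIVE_ROM_DEG["shoulder_abduction"] == 180
        assert NORMATIVE_ROM_DEG["lumbar_rotation"] == 45
        assert NORMATIVE_ROM_DEG["spinal_flexion"] == 100
        assert NORMATIVE_ROM_DEG["squat_hip_flexion"] == 95
        assert NORMATIVE_ROM_DEG["squat_knee_flexion"] == 85
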