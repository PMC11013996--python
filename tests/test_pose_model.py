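import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kinerehab import landmarks as lm
from kinerehab.pose_model import (BodyNotDetectedError, CalibrationError,
                                  CropBox, KeypointFrame, KeypointParseError,
                                  PoseSequence, body_center, compute_crop_box,
                                  extract_signals, full_body_visible,
                                  read_keypoints, reference_distance,
                                  write_keypoints)
from conftest import single_phase


def make_frame(points=None, vis=1.0, t=0.0, index=0):
    arr = np.zeros((lm.N_LANDMARKS, 4))
    arr[:, 0] = 0.5
    arr[:, 1] = 0.5
    arr[:, 3] = vis
    if points:
        for i, (x, y) in points.items():
            arr[i, 0], arr[i, 1] = x, y
    return KeypointFrame(arr, t, index)


def tiny_sequence(n=3, fps=30.0):
    frames = [make_frame(t=i / fps, index=i) for i in range(n)]
    return PoseSequence.from_frames(frames, fps, {"subject": "demo"})


class TestIO:
    @pytest.mark.parametrize("dialect,suffix", [("jsonl", ".jsonl"), ("csv", ".csv")])
    def test_write_read_roundtrip_is_identity(self, tmp_path, dialect, suffix):
        seq = tiny_sequence()
        path = tmp_path / f"kp{suffix}"
        write_keypoints(seq, path, dialect)
        back = read_keypoints(path, dialect)
        np.testing.assert_array_equal(back.data, seq.data)
        np.testing.assert_array_equal(back.t, seq.t)
        assert back.fps == seq.fps
        assert back.meta == seq.meta

    def test_frame_with_32_landmarks_is_rejected(self, tmp_path):
        seq = tiny_sequence()
        path = tmp_path / "kp.jsonl"
        write_keypoints(seq, path)
        lines = path.read_text().splitlines()
        import json

        rec = json.loads(lines[1])
        rec["landmarks"] = rec["landmarks"][:32]
        lines[1] = json.dumps(rec)
        path.write_text("\n".join(lines))
        with pytest.raises(KeypointParseError, match="33 landmarks"):
            read_keypoints(path)

    def test_missing_fps_header_is_an_error(self, tmp_path):
        seq = tiny_sequence()
        path = tmp_path / "kp.jsonl"
        write_keypoints(seq, path)
        lines = path.read_text().splitlines()[1:]  # drop header
        path.write_text("\n".join(lines))
        with pytest.raises(KeypointParseError, match="fps"):
            read_keypoints(path)

    def test_synthetic_trace_has_expected_duration(self):
        seq, _ = single_phase("SS", 40, 2.5, 2, fps=30)  # 150 frames
        assert seq.n_frames == 150
        assert seq.duration == pytest.approx(5.0)


class TestGeometry:
    def test_body_center_is_hip_midpoint(self):
        f = make_frame({lm.LEFT_HIP: (0.4, 0.6), lm.RIGHT_HIP: (0.6, 0.6)})
        assert body_center(f) == pytest.approx((0.5, 0.6))

    def test_body_center_degenerate_hips(self):
        f = make_frame({lm.LEFT_HIP: (0.5, 0.5), lm.RIGHT_HIP: (0.5, 0.5)})
        assert body_center(f) == pytest.approx((0.5, 0.5))

    def test_low_visibility_hips_signal_body_not_detected(self):
        f = make_frame(vis=0.2)
        with pytest.raises(BodyNotDetectedError):
            body_center(f)

    def test_body_center_matches_generator_pelvis(self):
        seq, gt = single_phase("SA", 150, 3.0, 2)
        from kinerehab.synthetic import SkeletonSpec

        px, py = SkeletonSpec().pelvis
        cx, cy = body_center(seq.frame(0))
        assert abs(cx - px) < 1e-9 and abs(cy - py) < 1e-9

    def test_reference_distance_is_mean_of_arm_lengths(self):
        f = make_frame({
            lm.LEFT_SHOULDER: (0.3, 0.3), lm.LEFT_INDEX: (0.3, 0.6),    # 0.30
            lm.RIGHT_SHOULDER: (0.7, 0.3), lm.RIGHT_INDEX: (0.7, 0.7),  # 0.40
        })
        assert reference_distance(f) == pytest.approx(0.35)

    def test_reference_distance_matches_generator_arm_length(self):
        seq, _ = single_phase("SS", 40, 2.0, 2)
        from kinerehab.synthetic import SkeletonSpec

        assert reference_distance(seq.frame(0)) == pytest.approx(
            SkeletonSpec().arm_length, abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(angle=st.floats(0, 2 * np.pi), cx=st.floats(0.2, 0.8),
           cy=st.floats(0.2, 0.8))
    def test_reference_distance_rotation_invariant(self, angle, cx, cy):
        f = make_frame({
            lm.LEFT_SHOULDER: (0.3, 0.3), lm.LEFT_INDEX: (0.35, 0.62),
            lm.RIGHT_SHOULDER: (0.7, 0.3), lm.RIGHT_INDEX: (0.66, 0.68),
        })
        base = reference_distance(f)
        c, s = np.cos(angle), np.sin(angle)
        R = np.array([[c, -s], [s, c]])
        rot = f.landmarks.copy()
        rot[:, :2] = (rot[:, :2] - [cx, cy]) @ R.T + [cx, cy]
        assert reference_distance(KeypointFrame(rot, 0.0)) == pytest.approx(
            base, abs=1e-9)


class TestCropBox:
    def _calib_seq(self, shift=(0.0, 0.0)):
        pts = {
            lm.LEFT_HIP: (0.45, 0.55), lm.RIGHT_HIP: (0.55, 0.55),
            lm.LEFT_SHOULDER: (0.42, 0.3), lm.LEFT_INDEX: (0.42, 0.5),
            lm.RIGHT_SHOULDER: (0.58, 0.3), lm.RIGHT_INDEX: (0.58, 0.5),
        }
        pts = {k: (x + shift[0], y + shift[1]) for k, (x, y) in pts.items()}
        frames = [make_frame(pts, t=i / 30, index=i) for i in range(35)]
        return PoseSequence.from_frames(frames, 30.0)

    def test_box_arithmetic(self):
        box = CropBox(0.5, 0.5, 0.4, 0.4)
        assert box.clipped() == pytest.approx((0.1, 0.1, 0.9, 0.9))

    def test_box_clipping(self):
        box = CropBox(0.9, 0.5, 0.4, 0.4)
        x0, y0, x1, y1 = box.clipped()
        assert (x0, x1) == pytest.approx((0.5, 1.0))

    def test_translation_moves_center_equally(self):
        b0 = compute_crop_box(self._calib_seq())
        b1 = compute_crop_box(self._calib_seq(shift=(0.05, -0.03)))
        assert b1.cx - b0.cx == pytest.approx(0.05, abs=1e-9)
        assert b1.cy - b0.cy == pytest.approx(-0.03, abs=1e-9)
        assert b1.half_w == pytest.approx(b0.half_w, abs=1e-9)

    def test_box_contains_all_landmarks_of_stationary_subject(self):
        seq, _ = single_phase("SS", 40, 2.0, 3, noise=0.001, seed=4)
        box = compute_crop_box(seq)
        xy = seq.data[:, :, :2].reshape(-1, 2)
        x0, y0, x1, y1 = box.clipped()
        assert (xy[:, 0] >= x0).all() and (xy[:, 0] <= x1).all()
        assert (xy[:, 1] >= y0).all() and (xy[:, 1] <= y1).all()

    def test_no_calibration_frame_raises(self):
        frames = [make_frame(vis=0.1, t=i / 30, index=i) for i in range(10)]
        with pytest.raises(CalibrationError, match="step back"):
            compute_crop_box(PoseSequence.from_frames(frames, 30.0))


class TestVisibility:
    def test_fully_visible(self):
        assert full_body_visible(make_frame())

    def test_out_of_frame_ankle(self):
        f = make_frame({lm.LEFT_ANKLE: (0.5, 1.05)})
        assert not full_body_visible(f)

    def test_generator_partial_body_is_flagged_invisible(self):
        seq, _ = single_phase("SS", 40, 2.0, 2, errors={"partial_body": 1})
        assert not full_body_visible(seq.frame(10))


class TestExtractSignals:
    def test_yields_99_signals_of_frame_count_length(self):
        seq, _ = single_phase("SQT", 85, 3.0, 2)
        ss = extract_signals(seq)
        assert len(ss.signals) == 99
        assert all(len(s) == seq.n_frames for s in ss.signals)
        assert all(s.fs == seq.fps for s in ss.signals)

    def test_single_frame_sequence(self):
        seq = tiny_sequence(n=1)
        ss = extract_signals(seq)
        assert len(ss.signals) == 99 and all(len(s) == 1 for s in ss.signals)

    def test_left_hip_x_signal_matches_trace(self):
        seq, _ = single_phase("SS", 40, 2.0, 3)
        ss = extract_signals(seq)
        np.testing.assert_array_equal(
            ss.get(lm.LEFT_HIP, "x").values, seq.data[:, lm.LEFT_HIP, 0])
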