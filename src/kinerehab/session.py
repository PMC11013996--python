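"""Real-time coaching session engine.

A headless state machine that consumes keypoint frames and emits
feedback messages; rendering (screen ribbons, audio) is a thin adapter
concern and never enters the core, which keeps sessions replayable and
byte-for-byte deterministic.

States and transitions::

    WAIT_FULL_BODY --(full body visible for the calibration window)--> CALIBRATING
    CALIBRATING    --(crop box computed)-->                            IDLE
    IDLE           --(motion detected)-->                              RECOGNIZING
    RECOGNIZING    --(first completed repetition classified)-->        TRACKING
    TRACKING       --(inactivity >= pause timeout)-->                  IDLE
    any            --(body lost for a sustained interval)-->           WAIT_FULL_BODY

While WAIT_FULL_BODY the user is prompted to step back; while IDLE a
motivation message is emitted once per idle timeout.  Recognition
fires on the first *completed* repetition of a bout (a rest-return
cycle of the dominant basic-keypoint signal), so its latency is one
execution period; repetitions completed since the bout began are
credited to the counter.  While TRACKING, each completed repetition
increments the counter, is checked against the exercise guidelines
(corrections repeat every violating repetition and stop as soon as a
clean one occurs), and votes on the exercise identity — a configurable
number of consecutive disagreeing votes resets the counter and
announces the new exercise.
"""

from __future__ import annotations

import json
from collections import deque
from dataclasses import dataclass, field
from typing import Deque, Dict, List, Optional, Tuple

import numpy as np

from . import landmarks as lm
from .kinematics import check_guidelines
from .pose_model import (CalibrationError, CropBox, KeypointFrame,
                         PoseSequence, compute_crop_box, full_body_visible)
from .recognition import (ExerciseLabel, ExerciseModel, extract_features,
                          predict_exercise, select_basic_signals)
from .pose_model import extract_signals

__all__ = [
    "SessionConfig",
    "SessionState",
    "FeedbackMessage",
    "SessionLog",
    "SessionEngine",
    "run_session",
    "MODES",
    "ALLOWED_TRANSITIONS",
]

MODES = ("WAIT_FULL_BODY", "CALIBRATING", "IDLE", "RECOGNIZING", "TRACKING")

ALLOWED_TRANSITIONS = {
    ("WAIT_FULL_BODY", "CALIBRATING"),
    ("CALIBRATING", "IDLE"),
    ("IDLE", "RECOGNIZING"),
    ("RECOGNIZING", "TRACKING"),
    ("RECOGNIZING", "IDLE"),
    ("TRACKING", "IDLE"),
    ("IDLE", "WAIT_FULL_BODY"),
    ("RECOGNIZING", "WAIT_FULL_BODY"),
    ("TRACKING", "WAIT_FULL_BODY"),
}

DEFAULT_MESSAGES: Dict[str, str] = {
    "step_back": "Step back until your entire body is visible",
    "motivation": "Time to move! Start your exercise whenever you are ready",
    "recognized": "Recognized exercise: {label}",
    "changed": "New exercise: {label} - repetition counter restarted",
    "count": "Repetitions: {n}",
}

_SERIES = (  # (role, landmark-or-midhip, axis) for the live motion monitor
    ("torso", "midhip", 0), ("torso", "midhip", 1),
    ("left_arm", lm.LEFT_WRIST, 0), ("left_arm", lm.LEFT_WRIST, 1),
    ("right_arm", lm.RIGHT_WRIST, 0), ("right_arm", lm.RIGHT_WRIST, 1),
    ("left_leg", lm.LEFT_ANKLE, 0), ("left_leg", lm.LEFT_ANKLE, 1),
    ("right_leg", lm.RIGHT_ANKLE, 0), ("right_leg", lm.RIGHT_ANKLE, 1),
)


@dataclass
class SessionConfig:
    vis_min: float = 0.5
    calib_window_s: float = 1.0
    crop_scale: float = 2.0
    prompt_interval_s: float = 3.0
    idle_timeout_s: float = 5.0
    pause_timeout_s: float = 3.0
    lost_body_s: float = 1.0
    activity_window_s: float = 0.8
    min_motion: float = 0.02
    smooth_n: int = 5
    min_rep_amplitude: float = 0.03
    rep_enter_frac: float = 0.45
    rep_exit_frac: float = 0.18
    recognition_fallback_s: float = 4.0
    change_votes: int = 2
    guideline_tolerance: float = 0.15
    messages: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MESSAGES))


@dataclass(frozen=True)
class FeedbackMessage:
    kind: str  # prompt | motivation | count | correction | recognition
    text: str
    t: float


@dataclass
class SessionLog:
    events: List[dict] = field(default_factory=list)

    def add(self, t: float, type_: str, **payload) -> None:
        self.events.append({"t": round(float(t), 6), "type": type_,
                            "payload": payload})

    def of_type(self, type_: str) -> List[dict]:
        return [e for e in self.events if e["type"] == type_]

    @property
    def messages(self) -> List[dict]:
        return self.of_type("message")

    def to_json(self) -> str:
        return json.dumps({"events": self.events}, sort_keys=True,
                          separators=(",", ":"))


@dataclass
class _RepDetector:
    """Rest-return repetition detector on a combined excursion signal.

    Tracks the root-mean-square deviation of the strongest co-moving
    monitor series from their rest baselines: a quantity that returns
    to zero only at the rest posture, so a single trace dipping
    mid-repetition (e.g. a non-monotone wrist abscissa) cannot fake a
    cycle boundary.
    """

    baselines: List[float] = field(default_factory=list)
    indices: List[int] = field(default_factory=list)
    amplitude: float = 0.0
    in_rep: bool = False
    peak: float = 0.0
    rep_start: int = 0
    completed: List[Tuple[int, int]] = field(default_factory=list)

    def update(self, e: float, index: int, cfg: SessionConfig) -> Optional[Tuple[int, int]]:
        self.amplitude = max(self.amplitude, e)
        enter = max(cfg.rep_enter_frac * self.amplitude, cfg.min_rep_amplitude)
        exit_ = max(cfg.rep_exit_frac * self.amplitude, 0.4 * cfg.min_rep_amplitude)
        if not self.in_rep:
            if e > enter:
                self.in_rep = True
                self.peak = e
        else:
            self.peak = max(self.peak, e)
            if e < exit_ and self.peak >= enter:
                rep = (self.rep_start, index)
                self.completed.append(rep)
                self.in_rep = False
                self.rep_start = index
                self.peak = 0.0
                return rep
        return None


@dataclass
class SessionState:
    mode: str = "WAIT_FULL_BODY"
    current_exercise: Optional[ExerciseLabel] = None
    rep_count: int = 0
    crop_box: Optional[CropBox] = None
    log: SessionLog = field(default_factory=SessionLog)
    # rolling observation history
    frames: List[KeypointFrame] = field(default_factory=list)
    times: List[float] = field(default_factory=list)
    series: List[List[float]] = field(default_factory=lambda: [[] for _ in _SERIES])
    # bookkeeping
    visible_streak: int = 0
    lost_streak: int = 0
    last_prompt_t: float = float("-inf")
    last_motivation_t: float = float("-inf")
    last_motion_t: float = float("-inf")
    bout_start: Optional[int] = None
    dom_idx: Optional[int] = None
    detector: Optional[_RepDetector] = None
    votes: Deque[int] = field(default_factory=lambda: deque(maxlen=8))
    active_violations: List[str] = field(default_factory=list)


class SessionEngine:
    """Folds keypoint frames through the coaching state machine."""

    def __init__(self, model: ExerciseModel, config: Optional[SessionConfig] = None,
                 fps: float = 30.0):
        self.model = model
        self.cfg = config or SessionConfig()
        self.fps = fps

    # -- helpers ----------------------------------------------------------

    def _append_observation(self, state: SessionState, frame: KeypointFrame) -> None:
        state.frames.append(frame)
        state.times.append(frame.t)
        P = frame.landmarks
        midhip = (P[lm.LEFT_HIP, :2] + P[lm.RIGHT_HIP, :2]) / 2.0
        for i, (_, kp, axis) in enumerate(_SERIES):
            v = midhip[axis] if kp == "midhip" else P[kp, axis]
            state.series[i].append(float(v))

    def _smoothed_tail(self, raw: List[float], k: int) -> np.ndarray:
        """Last k causally smoothed samples of one monitor series."""
        n = self.cfg.smooth_n
        take = raw[-(k + n - 1):]
        x = np.asarray(take, dtype=float)
        if x.size == 0:
            return x
        c = np.concatenate([[0.0], np.cumsum(x)])
        out = np.empty(x.size)
        for i in range(x.size):
            lo = max(0, i - n + 1)
            out[i] = (c[i + 1] - c[lo]) / (i + 1 - lo)
        return out[-k:]

    def _smoothed_value(self, raw: List[float]) -> float:
        n = self.cfg.smooth_n
        return float(np.mean(raw[-n:])) if raw else 0.0

    def _is_moving(self, state: SessionState) -> bool:
        w = max(4, int(round(self.cfg.activity_window_s * self.fps)))
        if len(state.times) < w:
            return False
        p2p = 0.0
        for raw in state.series:
            sm = self._smoothed_tail(raw, w)
            p2p = max(p2p, float(sm.max() - sm.min()))
        return p2p > self.cfg.min_motion

    def _subsequence(self, state: SessionState, start: int, end: int) -> PoseSequence:
        return PoseSequence.from_frames(state.frames[start:end], self.fps)

    def _predict_on(self, state: SessionState, start: int, end: int):
        seq = self._subsequence(state, start, end)
        basic = select_basic_signals(extract_signals(seq))
        fv = extract_features(basic)
        return predict_exercise(self.model, fv)

    def _transition(self, state: SessionState, to: str, t: float) -> None:
        if state.mode != to:
            state.log.add(t, "transition", source=state.mode, target=to)
            state.mode = to

    def _emit(self, state: SessionState, msgs: List[FeedbackMessage],
              kind: str, text: str, t: float) -> None:
        msg = FeedbackMessage(kind, text, t)
        msgs.append(msg)
        state.log.add(t, "message", kind=kind, text=text)

    def _start_bout(self, state: SessionState) -> None:
        backoff = int(round(0.3 * self.fps))
        onset = max(0, len(state.frames) - 1 - backoff)
        state.bout_start = onset
        state.dom_idx = None
        state.detector = None
        state.votes.clear()

    def _ensure_detector(self, state: SessionState) -> None:
        if state.detector is not None or state.bout_start is None:
            return
        warm = int(round(0.5 * self.fps))
        if len(state.frames) - state.bout_start < warm:
            return
        onset = state.bout_start
        spans = sorted(
            ((float(np.ptp(np.asarray(raw[onset:]))), i)
             for i, raw in enumerate(state.series)),
            reverse=True,
        )
        top = spans[0][0]
        indices = [i for ptp, i in spans[:4] if ptp >= 0.5 * top]
        state.dom_idx = indices[0]
        baselines = []
        for i in indices:
            pre = state.series[i][max(0, onset - self.cfg.smooth_n):onset + 1]
            baselines.append(float(np.median(pre)) if pre
                             else state.series[i][onset])
        state.detector = _RepDetector(baselines=baselines, indices=indices,
                                      rep_start=onset)

    def _excursion(self, state: SessionState) -> float:
        det = state.detector
        devs = [self._smoothed_value(state.series[i]) - b
                for i, b in zip(det.indices, det.baselines)]
        return float(np.sqrt(np.mean(np.square(devs))))

    # -- repetition handling ----------------------------------------------

    def _handle_completed_rep(self, state: SessionState, rep: Tuple[int, int],
                              t: float, msgs: List[FeedbackMessage]) -> None:
        cfg = self.cfg
        if state.mode == "RECOGNIZING":
            label, score = self._predict_on(state, rep[0], rep[1])
            state.log.add(t, "prediction", label=label.name, score=round(score, 6))
            changed = (state.current_exercise is not None
                       and label != state.current_exercise)
            state.current_exercise = label
            state.rep_count = 0
            template = cfg.messages["changed"] if changed else cfg.messages["recognized"]
            self._emit(state, msgs, "recognition",
                       template.format(label=label.name), t)
            self._transition(state, "TRACKING", t)
            self._credit_rep(state, rep, t, msgs)
        elif state.mode == "TRACKING":
            self._credit_rep(state, rep, t, msgs)
            label, score = self._predict_on(state, rep[0], rep[1])
            state.log.add(t, "prediction", label=label.name, score=round(score, 6))
            state.votes.append(int(label))
            recent = list(state.votes)[-cfg.change_votes:]
            if (len(recent) == cfg.change_votes
                    and all(v != int(state.current_exercise) for v in recent)
                    and len(set(recent)) == 1):
                state.current_exercise = ExerciseLabel(recent[0])
                state.rep_count = 0
                state.votes.clear()
                self._emit(state, msgs, "recognition",
                           cfg.messages["changed"].format(
                               label=state.current_exercise.name), t)

    def _credit_rep(self, state: SessionState, rep: Tuple[int, int], t: float,
                    msgs: List[FeedbackMessage]) -> None:
        state.rep_count += 1
        state.log.add(t, "rep", count=state.rep_count, start=rep[0], end=rep[1])
        self._emit(state, msgs, "count",
                   self.cfg.messages["count"].format(n=state.rep_count), t)
        self._check_rep_guidelines(state, rep, t, msgs)

    def _check_rep_guidelines(self, state: SessionState, rep: Tuple[int, int],
                              t: float, msgs: List[FeedbackMessage]) -> None:
        if state.current_exercise is None:
            return
        seq = self._subsequence(state, rep[0], rep[1])
        from .signal_prep import RepetitionSegment

        dur = (rep[1] - rep[0]) / self.fps
        try:
            violations = check_guidelines(
                state.current_exercise.name, seq,
                [RepetitionSegment(0, rep[1] - rep[0], dur)],
                self.cfg.guideline_tolerance, period=dur)
        except ValueError:
            violations = []
        if state.current_exercise.name == "TR" and state.bout_start is not None:
            # coordination needs >= 2 cycles: evaluate on the whole bout
            bout_seq = self._subsequence(state, state.bout_start, rep[1])
            try:
                violations += check_guidelines(
                    "TR", bout_seq, [], self.cfg.guideline_tolerance, period=dur)
            except ValueError:
                pass
        state.active_violations = [v.rule for v in violations]
        for v in violations:
            self._emit(state, msgs, "correction", v.message, t)
            state.log.add(t, "violation", rule=v.rule,
                          severity=round(v.severity, 6))

    # -- the step function -------------------------------------------------

    def step(self, state: SessionState,
             frame: KeypointFrame) -> Tuple[SessionState, List[FeedbackMessage]]:
        cfg = self.cfg
        t = frame.t
        msgs: List[FeedbackMessage] = []
        self._append_observation(state, frame)
        visible = full_body_visible(frame, cfg.vis_min)

        if state.mode == "WAIT_FULL_BODY":
            if visible:
                state.visible_streak += 1
            else:
                state.visible_streak = 0
                if t - state.last_prompt_t >= cfg.prompt_interval_s:
                    self._emit(state, msgs, "prompt", cfg.messages["step_back"], t)
                    state.last_prompt_t = t
            if state.visible_streak >= int(round(cfg.calib_window_s * self.fps)):
                self._transition(state, "CALIBRATING", t)
                calib = self._subsequence(
                    state, len(state.frames) - state.visible_streak, len(state.frames))
                try:
                    state.crop_box = compute_crop_box(
                        calib, cfg.calib_window_s, cfg.crop_scale, cfg.vis_min)
                    box = state.crop_box.clipped()
                    state.log.add(t, "crop_box", x0=round(box[0], 6),
                                  y0=round(box[1], 6), x1=round(box[2], 6),
                                  y1=round(box[3], 6))
                except CalibrationError:
                    state.crop_box = None
                self._transition(state, "IDLE", t)
                state.last_motion_t = t
                state.last_motivation_t = t
            return state, msgs

        # body-loss watchdog for all post-calibration modes
        if visible:
            state.lost_streak = 0
        else:
            state.lost_streak += 1
            if state.lost_streak > int(round(cfg.lost_body_s * self.fps)):
                self._transition(state, "WAIT_FULL_BODY", t)
                state.visible_streak = 0
                state.bout_start = None
                state.detector = None
                return state, msgs

        moving = self._is_moving(state)
        if moving:
            state.last_motion_t = t

        if state.mode == "IDLE":
            if moving:
                self._transition(state, "RECOGNIZING", t)
                self._start_bout(state)
            elif (t - max(state.last_motion_t, state.last_motivation_t)
                  >= cfg.idle_timeout_s):
                self._emit(state, msgs, "motivation", cfg.messages["motivation"], t)
                state.last_motivation_t = t
            return state, msgs

        # RECOGNIZING / TRACKING
        self._ensure_detector(state)
        if state.detector is not None:
            rep = state.detector.update(self._excursion(state),
                                        len(state.frames) - 1, cfg)
            if rep is not None:
                self._handle_completed_rep(state, rep, t, msgs)

        if state.mode == "RECOGNIZING":
            started = state.times[state.bout_start] if state.bout_start is not None else t
            if t - started > cfg.recognition_fallback_s:
                end = len(state.frames)
                start = state.bout_start or 0
                label, score = self._predict_on(state, start, end)
                state.log.add(t, "prediction", label=label.name,
                              score=round(score, 6))
                state.current_exercise = label
                state.rep_count = 0
                self._emit(state, msgs, "recognition",
                           cfg.messages["recognized"].format(label=label.name), t)
                self._transition(state, "TRACKING", t)

        if state.mode in ("RECOGNIZING", "TRACKING"):
            if t - state.last_motion_t > cfg.pause_timeout_s:
                self._transition(state, "IDLE", t)
                state.bout_start = None
                state.detector = None
                state.dom_idx = None
        return state, msgs


def run_session(
    source: PoseSequence,
    model: ExerciseModel,
    config: Optional[SessionConfig] = None,
) -> SessionLog:
    """Replay a pose sequence through the session engine.

    Deterministic given the sequence, the fitted model and the
    configuration; an empty source yields an empty log.
    """
    engine = SessionEngine(model, config, fps=source.fps)
    state = SessionState()
    for frame in source.frames:
        state, _ = engine.step(state, frame)
    return state.log
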