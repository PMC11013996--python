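"""End-to-end glue: pose sequence -> repetitions -> features / reports.

Chains the preprocessing stages in their canonical order: extract the
99 per-axis signals, pick the dominant basic-keypoint signal, detect
the active bout, (optionally) SSA-detrend when the camera is not
fixed, estimate the repetition period and segment repetitions; then
either extract per-repetition feature vectors for classification or
run the kinematic ROM / guideline analysis.
"""

from __future__ import annotations

from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .kinematics import check_guidelines, exercise_rom_report
from .pose_model import PoseSequence, extract_signals
from .recognition import (BasicKeypointSet, ExerciseLabel, FEATURE_NAMES,
                          extract_features, select_basic_signals)
from .signal_prep import (AperiodicSignalError, MotionSignal,
                          RepetitionSegment, detect_activity, detrend,
                          estimate_period, segment_repetitions)

__all__ = [
    "dominant_signal",
    "segment_sequence",
    "repetition_feature_rows",
    "build_feature_table",
    "analyze_sequence",
]


def dominant_signal(basic: Sequence[MotionSignal]) -> MotionSignal:
    """The x/y basic signal with maximal variance.

    Drives period estimation and segmentation; depth (z) traces are
    excluded as the least reliable channel of monocular estimation.
    """
    planar = [s for s in basic if s.label[1] in ("x", "y")]
    return max(planar, key=lambda s: float(np.var(s.values)))


def segment_sequence(
    seq: PoseSequence,
    camera_fixed: bool = True,
    bset: Optional[BasicKeypointSet] = None,
) -> Tuple[List[RepetitionSegment], float, List[MotionSignal], Tuple[int, int]]:
    """Repetitions of the main active bout of a sequence.

    Returns ``(reps, period_s, basic_signals, (bout_start, bout_end))``
    with repetition indices global to the sequence.
    """
    sigset = extract_signals(seq)
    basic = select_basic_signals(sigset, bset)
    if not camera_fixed:
        basic = [detrend(s) for s in basic]
    dom = dominant_signal(basic)
    segments = detect_activity(dom)
    active = [s for s in segments if s.kind == "active"]
    if not active:
        return [], float("nan"), basic, (0, 0)

    # First-pass period from the longest active stretch (whole signal as
    # fallback): needed to tell intra-bout dwell from genuine rest.
    longest = max(active, key=lambda s: s.end - s.start)
    try:
        period = estimate_period(
            MotionSignal(dom.values[longest.start:longest.end], dom.fs))
    except AperiodicSignalError:
        period = estimate_period(dom)

    # Movements whose trace flattens quartically at the rest posture can
    # dwell below the activity threshold at every repetition boundary;
    # a "pause" shorter than a repetition cannot be a rest break, so
    # merge active fragments separated by sub-period gaps.
    gap = int(round(0.75 * period * dom.fs))
    merged: List[Tuple[int, int]] = [(active[0].start, active[0].end)]
    for s in active[1:]:
        if s.start - merged[-1][1] <= gap:
            merged[-1] = (merged[-1][0], s.end)
        else:
            merged.append((s.start, s.end))
    b0, b1 = max(merged, key=lambda ab: ab[1] - ab[0])

    # Extend the bout into flanking rest so the first/last repetition is
    # anchored at the true rest level, not at the detection threshold.
    ext = int(round(0.35 * period * dom.fs))
    start, end = max(0, b0 - ext), min(len(dom), b1 + ext)
    for a, b in merged:
        if b <= b0:
            start = max(start, b)
        elif a >= b1:
            end = min(end, a)

    window = MotionSignal(dom.values[start:end], dom.fs, dom.label)
    period = estimate_period(window)
    reps = [
        RepetitionSegment(r.start + start, r.end + start, r.duration)
        for r in segment_repetitions(window, period)
    ]
    return reps, period, basic, (start, end)


def repetition_feature_rows(
    seq: PoseSequence,
    label: Optional[ExerciseLabel] = None,
    subject_id: str = "",
    camera_fixed: bool = True,
    bset: Optional[BasicKeypointSet] = None,
) -> List[dict]:
    """One 285-feature row per detected repetition of a trial."""
    reps, _, basic, _ = segment_sequence(seq, camera_fixed, bset)
    rows = []
    for r in reps:
        segs = [MotionSignal(s.values[r.start:r.end], s.fs, s.label) for s in basic]
        fv = extract_features(segs, label=label, subject_id=subject_id)
        row = {"subject_id": subject_id,
               "label": int(label) if label is not None else 0}
        row.update(dict(zip(FEATURE_NAMES, fv.values)))
        rows.append(row)
    return rows


def build_feature_table(trials: Sequence[dict], camera_fixed: bool = True) -> pd.DataFrame:
    """Feature table for a corpus of trials (see ``synthetic.make_dataset``)."""
    rows: List[dict] = []
    for tr in trials:
        rows += repetition_feature_rows(
            tr["seq"], ExerciseLabel[tr["label"]], tr["subject_id"], camera_fixed)
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])


def analyze_sequence(
    seq: PoseSequence,
    exercise: str,
    tolerance: float = 0.15,
    camera_fixed: bool = True,
) -> dict:
    """Kinematic assessment of one recorded trial of a known exercise.

    Returns repetition segments, the estimated period, per-measure ROM
    summaries with normative ratios and angular velocity, and any
    guideline violations.
    """
    reps, period, _, bout = segment_sequence(seq, camera_fixed)
    if not reps:
        return {"exercise": exercise, "n_repetitions": 0, "repetitions": [],
                "period_s": None, "rom": [], "violations": []}
    rom = exercise_rom_report(seq, exercise, reps)
    violations = check_guidelines(exercise, seq, reps, tolerance, period)
    return {
        "exercise": exercise,
        "n_repetitions": len(reps),
        "repetitions": [{"start": r.start, "end": r.end, "duration_s": r.duration}
                        for r in reps],
        "period_s": period,
        "bout": {"start": bout[0], "end": bout[1]},
        "rom": rom,
        "violations": [v.__dict__ for v in violations],
    }
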