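"""Joint-angle kinematics, ROM testing and execution-error checks.

Angles between body segments are computed with the cosine formula on
landmark triplets; range of motion (ROM) is summarized per repetition
as the median of per-repetition angle maxima and compared against
normative goniometer values (AAOS; Hemmerich et al. for squat
flexion).  Movement coordination between body parts is quantified as
pairwise phase lags by cross-correlation.  Per-exercise guideline
checks turn geometric deviations beyond a 10-20 % tolerance band into
corrective feedback messages.

The camera is assumed frontal.  Measures that live in the frontal
plane (hip/shoulder abduction) use (x, y) only; trunk rotation is
recovered from apparent shoulder-width foreshortening; sagittal
flexion measures (forward bend, squat) opt into the depth coordinate
explicitly, since depth is the least reliable channel of monocular
pose estimation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal as sps

from . import landmarks as lm
from .pose_model import PoseSequence
from .signal_prep import MotionSignal, RepetitionSegment, moving_average

__all__ = [
    "JointTriplet",
    "AngleSeries",
    "ROMSummary",
    "GuidelineViolation",
    "CoordinationResult",
    "UnreliableSeriesError",
    "NORMATIVE_ROM_DEG",
    "EXERCISES",
    "joint_angle",
    "angle_series",
    "rom_summary",
    "angular_velocity",
    "trunk_rotation_angle",
    "trunk_rotation_series",
    "coordination",
    "check_guidelines",
    "compare_to_normative",
    "exercise_rom_report",
]

EXERCISES = ("SS", "SA", "TR", "FB", "SQT")

#: Normative goniometer ROM values, degrees (AAOS; squat values from
#: Hemmerich et al.).
NORMATIVE_ROM_DEG: Dict[str, float] = {
    "hip_abduction": 40.0,
    "shoulder_abduction": 180.0,
    "lumbar_rotation": 45.0,
    "spinal_flexion": 100.0,
    "squat_hip_flexion": 95.0,
    "squat_knee_flexion": 85.0,
}

#: Primary ROM measure per exercise.
EXERCISE_MEASURES: Dict[str, Tuple[str, ...]] = {
    "SS": ("hip_abduction",),
    "SA": ("shoulder_abduction",),
    "TR": ("lumbar_rotation",),
    "FB": ("spinal_flexion",),
    "SQT": ("squat_hip_flexion", "squat_knee_flexion"),
}


class UnreliableSeriesError(ValueError):
    """Too many low-visibility frames to trust an angle series."""


@dataclass(frozen=True)
class JointTriplet:
    """Three landmark indices defining an angle at vertex ``b``."""

    a: int
    b: int
    c: int
    plane: str = "xy"  # xy | xz | xyz

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.c}) != 3:
            raise ValueError("triplet landmarks must be distinct")
        for i in (self.a, self.b, self.c):
            if not (0 <= i < lm.N_LANDMARKS):
                raise ValueError(f"landmark index {i} out of range")
        if self.plane not in ("xy", "xz", "xyz"):
            raise ValueError(f"unknown plane {self.plane!r}")


@dataclass
class AngleSeries:
    """A joint-angle trace in degrees."""

    values: np.ndarray
    fs: float
    joint: Optional[JointTriplet] = None
    exercise: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("angle series must be finite")

    def __len__(self) -> int:
        return self.values.size

    def as_signal(self) -> MotionSignal:
        return MotionSignal(self.values, self.fs, ("angle", self.exercise or "deg"))


@dataclass
class ROMSummary:
    """Per-repetition angle maxima and their median, degrees."""

    per_rep_max: List[float]
    median_max: float
    exercise: str = ""
    side: str = "n/a"  # left | right | n/a
    measure: str = ""

    def __post_init__(self) -> None:
        if not self.per_rep_max:
            raise ValueError("ROM summary needs at least one repetition")
        expected = float(np.median(self.per_rep_max))
        if not math.isclose(self.median_max, expected, abs_tol=1e-9):
            raise ValueError("median_max must equal the median of per_rep_max")


@dataclass(frozen=True)
class GuidelineViolation:
    """One execution-error finding for one repetition."""

    exercise: str
    rule: str
    repetition: int          # 0-based; -1 for bout-level findings
    severity: float          # relative deviation (fraction)
    message: str


@dataclass
class CoordinationResult:
    """Pairwise phase lags between N body-part signals.

    ``lag_matrix[i, j]`` is the time (seconds) by which part ``j`` lags
    part ``i`` (antisymmetric, zero diagonal).  ``order`` ranks parts
    by movement onset, earliest first.  ``unified`` is true when all
    pairwise lags are below the unification threshold — for trunk
    rotation that is the hallmark of moving the body as one block.
    """

    parts: List[str]
    lag_matrix: np.ndarray
    order: List[str]
    unified: bool


# ---------------------------------------------------------------------------
# Angles


def _plane_coords(p: np.ndarray, plane: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if plane == "xy":
        return p[:2]
    if plane == "xz":
        if p.size < 3:
            raise ValueError("xz plane requires 3-component points")
        return p[[0, 2]]
    if p.size < 3:
        raise ValueError("xyz plane requires 3-component points")
    return p[:3]


def joint_angle(a, b, c, plane: str = "xy") -> float:
    """Angle at vertex ``b`` of the triplet (a, b, c), in degrees.

    Cosine formula: ``arccos((a-b)·(c-b) / (|a-b||c-b|))``, computed on
    the coordinates of the requested plane.  Always in [0, 180].
    """
    u = _plane_coords(a, plane) - _plane_coords(b, plane)
    v = _plane_coords(c, plane) - _plane_coords(b, plane)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu < 1e-9 or nv < 1e-9:
        raise ValueError("degenerate triplet: coincident points")
    cosang = float(np.dot(u, v) / (nu * nv))
    return math.degrees(math.acos(max(-1.0, min(1.0, cosang))))


def angle_series(
    seq: PoseSequence,
    joint: JointTriplet,
    vis_min: float = 0.5,
    max_missing_frac: float = 0.10,
    exercise: str = "",
) -> AngleSeries:
    """Per-frame joint angle over a sequence.

    Frames in which any of the three landmarks falls below ``vis_min``
    visibility are linearly interpolated from their neighbours; if more
    than ``max_missing_frac`` of frames are low-visibility the series
    is unreliable and an :class:`UnreliableSeriesError` is raised.
    """
    n = seq.n_frames
    if n == 0:
        raise ValueError("empty sequence")
    vis = seq.data[:, [joint.a, joint.b, joint.c], 3]
    ok = np.all(vis >= vis_min, axis=1)
    if np.mean(~ok) > max_missing_frac:
        raise UnreliableSeriesError(
            f"{np.mean(~ok):.0%} of frames below visibility {vis_min}"
        )
    vals = np.full(n, np.nan)
    for i in np.flatnonzero(ok):
        vals[i] = joint_angle(
            seq.data[i, joint.a, :3], seq.data[i, joint.b, :3],
            seq.data[i, joint.c, :3], joint.plane,
        )
    if not ok.all():
        good = np.flatnonzero(ok)
        if good.size == 0:
            raise UnreliableSeriesError("no visible frames")
        vals = np.interp(np.arange(n), good, vals[good])
    return AngleSeries(vals, seq.fps, joint, exercise)


def rom_summary(
    angles: AngleSeries,
    reps: Sequence[RepetitionSegment],
    mode: str = "excursion",
    exercise: str = "",
    side: str = "n/a",
    measure: str = "",
) -> ROMSummary:
    """Per-repetition ROM maxima and their median.

    ``mode="excursion"`` measures the peak-to-peak angle within each
    repetition — the convention for abduction measures, where every
    repetition starts and ends at the rest posture, so the within-rep
    minimum is the rest angle (more robust than referencing the exact
    boundary sample, which may land a few frames into the movement).
    ``mode="peak"`` takes the maximum magnitude, for measures that are
    zero-referenced by calibration (trunk rotation).  ``mode="flexion"``
    measures the maximum of ``180° - angle``, i.e. how far a nominally
    straight chain flexes — the convention for forward-bend and squat
    measures.
    """
    if not reps:
        raise ValueError("ROM summary needs a non-empty repetition list")
    if mode not in ("excursion", "peak", "flexion"):
        raise ValueError(f"unknown ROM mode {mode!r}")
    per_rep = []
    for r in reps:
        seg = angles.values[r.start:r.end]
        if seg.size == 0:
            raise ValueError("repetition segment outside the angle series")
        if mode == "excursion":
            per_rep.append(float(np.max(seg) - np.min(seg)))
        elif mode == "peak":
            per_rep.append(float(np.max(np.abs(seg))))
        else:
            per_rep.append(float(np.max(180.0 - seg)))
    return ROMSummary(per_rep, float(np.median(per_rep)),
                      exercise or angles.exercise, side, measure)


def angular_velocity(rom: float, duration: float) -> float:
    """Mean angular velocity ``ω = dθ / dt`` in rad/s.

    ``rom`` is the inscribed angle of one repetition in radians and
    ``duration`` the repetition duration in seconds.
    """
    if duration <= 0:
        raise ValueError("repetition duration must be positive")
    return rom / duration


# ---------------------------------------------------------------------------
# Trunk rotation (frontal-plane approximation)


def trunk_rotation_angle(
    frame,
    calib_shoulder_width: float,
    use_z_sign: bool = True,
) -> float:
    """Trunk rotation from apparent shoulder-width foreshortening.

    With a frontal camera, rotating the trunk by ρ shrinks the apparent
    (projected) shoulder width to ``W·cos ρ``, so
    ``ρ = arccos(apparent / calibrated)``.  The sign (which shoulder
    moved toward the camera) is taken from the shoulders' depth
    difference when ``use_z_sign`` is set, else the magnitude is
    returned.  This is a frontal-plane approximation: true lumbar
    rotation is not directly observable from a single frontal camera.
    """
    if calib_shoulder_width <= 0:
        raise ValueError("calibrated shoulder width missing or non-positive")
    sl = frame.landmarks[lm.LEFT_SHOULDER]
    sr = frame.landmarks[lm.RIGHT_SHOULDER]
    apparent = abs(float(sl[0] - sr[0]))
    ratio = min(max(apparent / calib_shoulder_width, 0.0), 1.0)
    rho = math.degrees(math.acos(ratio))
    if use_z_sign:
        # left shoulder closer to the camera (smaller z) => positive.
        sign = 1.0 if sl[2] <= sr[2] else -1.0
        return sign * rho
    return rho


def trunk_rotation_series(
    seq: PoseSequence,
    calib_shoulder_width: Optional[float] = None,
    calib_window: float = 0.5,
    use_z_sign: bool = True,
    smooth_s: float = 0.1,
) -> AngleSeries:
    """Signed trunk-rotation trace; calibrates width on the first frames.

    The apparent-width signal is moving-average smoothed before the
    arccos: near zero rotation the arccos has infinite slope, so raw
    keypoint jitter would otherwise turn into a large spurious rotation
    floor.
    """
    if seq.n_frames == 0:
        raise ValueError("empty sequence")
    width = np.abs(
        seq.data[:, lm.LEFT_SHOULDER, 0] - seq.data[:, lm.RIGHT_SHOULDER, 0]
    )
    width = moving_average(
        MotionSignal(width, seq.fps), max(1, round(smooth_s * seq.fps))
    ).values
    if calib_shoulder_width is None:
        k = max(1, int(round(calib_window * seq.fps)))
        calib_shoulder_width = float(np.median(width[:k]))
    if calib_shoulder_width <= 0:
        raise ValueError("calibrated shoulder width missing or non-positive")
    ratio = np.clip(width / calib_shoulder_width, 0.0, 1.0)
    rho = np.degrees(np.arccos(ratio))
    if use_z_sign:
        sign = np.where(
            seq.data[:, lm.LEFT_SHOULDER, 2] <= seq.data[:, lm.RIGHT_SHOULDER, 2],
            1.0, -1.0)
        rho = sign * rho
    return AngleSeries(rho, seq.fps, None, "TR")


# ---------------------------------------------------------------------------
# Coordination


def _pair_lag(xi: np.ndarray, xj: np.ndarray, fs: float,
              max_lag: Optional[int]) -> float:
    """Lag (s) by which xj lags xi, from the cross-correlation peak."""
    xi = xi - xi.mean()
    xj = xj - xj.mean()
    if np.allclose(xi, 0) or np.allclose(xj, 0):
        raise ValueError("no phase information in a constant series")
    cc = sps.correlate(xi, xj, mode="full")
    lags = sps.correlation_lags(xi.size, xj.size, mode="full")
    if max_lag is not None:
        keep = np.abs(lags) <= max_lag
        cc, lags = cc[keep], lags[keep]
    # xj(t) = xi(t - d): peak of sum xi[t] xj[t - l] at l = -d.
    return float(-lags[int(np.argmax(cc))] / fs)


def coordination(
    series: Sequence[Union[MotionSignal, AngleSeries]],
    parts: Optional[Sequence[str]] = None,
    unify_threshold: Optional[float] = None,
    period: Optional[float] = None,
    max_lag_s: Optional[float] = None,
) -> CoordinationResult:
    """Participation order of N body parts by cross-correlation.

    Each series is mean-centered; the pairwise lag is the argmax of the
    normalized cross-correlation.  Parts are ordered by their lag
    relative to the first-moving part, and the movement counts as
    *unified* when every pairwise |lag| stays below ``unify_threshold``
    (default ``0.15 * period``, or 0.5 s when no period is given).
    When a movement period is supplied, the lag search is restricted to
    ``± period / 2`` to avoid aliasing onto the next cycle.
    """
    if len(series) < 2:
        raise ValueError("coordination needs at least two series")
    fss = {s.fs for s in series}
    if len(fss) != 1:
        raise ValueError("all series must share one sampling rate")
    fs = fss.pop()
    arrays = [np.asarray(s.values, dtype=float) for s in series]
    if len({a.size for a in arrays}) != 1:
        raise ValueError("all series must have equal length")
    if parts is None:
        parts = [f"part{i}" for i in range(len(series))]
    if unify_threshold is None:
        unify_threshold = 0.15 * period if period else 0.5
    if max_lag_s is None and period is not None:
        max_lag_s = period / 2.0
    max_lag = int(round(max_lag_s * fs)) if max_lag_s is not None else None

    n = len(arrays)
    lagm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = _pair_lag(arrays[i], arrays[j], fs, max_lag)
            lagm[i, j] = d
            lagm[j, i] = -d
    rel = lagm[0]  # lag of each part behind part 0
    order_idx = list(np.argsort(rel, kind="stable"))
    off = np.abs(lagm[np.triu_indices(n, k=1)])
    unified = bool(np.all(off < unify_threshold))
    return CoordinationResult(list(parts), lagm, [parts[i] for i in order_idx], unified)


# ---------------------------------------------------------------------------
# Guideline (execution-error) checks


MESSAGES = {
    "SA_straight_arms": "Keep the arms straight!",
    "TR_arms_vertical": "Keep arms vertical to the body axis",
    "TR_unified": "Rotate the trunk, not the whole body as one unit",
    "FB_straight_legs": "Keep the legs straight",
    "SQT_knees_toes": "Keep knees behind toes",
}

_ELBOW = {
    "left": JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_ELBOW, lm.LEFT_WRIST),
    "right": JointTriplet(lm.RIGHT_SHOULDER, lm.RIGHT_ELBOW, lm.RIGHT_WRIST),
}
_KNEE_3D = {
    "left": JointTriplet(lm.LEFT_HIP, lm.LEFT_KNEE, lm.LEFT_ANKLE, "xyz"),
    "right": JointTriplet(lm.RIGHT_HIP, lm.RIGHT_KNEE, lm.RIGHT_ANKLE, "xyz"),
}
_ARM_TRUNK = {
    "left": JointTriplet(lm.LEFT_ELBOW, lm.LEFT_SHOULDER, lm.LEFT_HIP),
    "right": JointTriplet(lm.RIGHT_ELBOW, lm.RIGHT_SHOULDER, lm.RIGHT_HIP),
}


def _clamp_tolerance(tolerance: float) -> float:
    if not (0.10 <= tolerance <= 0.20):
        raise ValueError("tolerance must lie in the 10-20% error-margin band")
    return tolerance


def check_guidelines(
    exercise: str,
    seq: PoseSequence,
    reps: Sequence[RepetitionSegment],
    tolerance: float = 0.15,
    period: Optional[float] = None,
) -> List[GuidelineViolation]:
    """Evaluate the per-exercise execution guidelines on each repetition.

    Rules (deviations beyond ``tolerance``, a fraction in the 10-20 %
    band, are flagged):

    * **SA** — elbows stay extended: the minimum elbow angle of a
      repetition must be at least ``180°·(1 - tolerance)``.
    * **TR** — arms stay perpendicular to the body axis (arm-to-trunk
      angle within ``tolerance`` of 90°), and the trunk must lead the
      arms: a *unified* head/trunk/arm rotation (all pairwise lags
      below 0.15 of the period) is flagged as a bout-level violation.
    * **FB** — legs stay extended (minimum knee angle as for SA).
    * **SQT** — knees stay behind the toes: the knee's horizontal
      outward excursion past the foot tip must not exceed
      ``tolerance`` times the foot length.
    * **SS / SA / TR upright-spine** checks are skipped: with a frontal
      camera they would live in the unreliable depth plane.

    Severity is the relative deviation that triggered the rule.
    """
    if exercise not in EXERCISES:
        raise ValueError(f"unknown exercise {exercise!r}")
    tolerance = _clamp_tolerance(tolerance)
    seq = _smoothed_sequence(seq)  # judge the movement, not the jitter
    out: List[GuidelineViolation] = []

    if exercise == "SA":
        out += _straight_chain_check(seq, reps, tolerance, _ELBOW,
                                     "SA", "SA_straight_arms")
    elif exercise == "FB":
        out += _straight_chain_check(seq, reps, tolerance, _KNEE_3D,
                                     "FB", "FB_straight_legs")
    elif exercise == "TR":
        out += _tr_arm_angle_check(seq, reps, tolerance)
        out += _tr_coordination_check(seq, period)
    elif exercise == "SQT":
        out += _sqt_knee_toe_check(seq, reps, tolerance)
    # SS: no frontal-plane rule beyond the skipped spine check.
    return out


def _straight_chain_check(seq, reps, tolerance, triplets, exercise, rule):
    thr = 180.0 * (1.0 - tolerance)
    series = {s: angle_series(seq, t, exercise=exercise) for s, t in triplets.items()}
    out = []
    for k, r in enumerate(reps):
        min_angle = min(float(np.min(s.values[r.start:r.end])) for s in series.values())
        if min_angle < thr:
            out.append(GuidelineViolation(
                exercise, rule, k, 1.0 - min_angle / 180.0, MESSAGES[rule]))
    return out


def _tr_arm_angle_check(seq, reps, tolerance):
    series = {s: angle_series(seq, t, exercise="TR") for s, t in _ARM_TRUNK.items()}
    out = []
    for k, r in enumerate(reps):
        dev = max(
            float(np.max(np.abs(s.values[r.start:r.end] - 90.0))) / 90.0
            for s in series.values()
        )
        if dev > tolerance:
            out.append(GuidelineViolation(
                "TR", "TR_arms_vertical", k, dev, MESSAGES["TR_arms_vertical"]))
    return out


_TR_UNIFY_THRESHOLD_S = 0.15


def _tr_coordination_check(seq, period):
    """Bout-level: flag head/trunk/arms rotating as a single unit.

    Trunk participation is read from the apparent shoulder width and
    arm participation from the apparent wrist spread — two magnitude
    signals that co-vary under rotation (raw per-wrist abscissae of the
    two arms are anti-correlated, which would alias the lag by half a
    period).  Correct execution has the trunk leading the arms by a
    perceptible fraction of a second; lags below an absolute 0.15 s
    count as a unified, single-block rotation.
    """
    if period and seq.n_frames < 2 * period * seq.fps:
        return []  # lag estimation needs at least two movement cycles
    width = np.abs(seq.data[:, lm.LEFT_SHOULDER, 0] - seq.data[:, lm.RIGHT_SHOULDER, 0])
    spread = np.abs(seq.data[:, lm.LEFT_WRIST, 0] - seq.data[:, lm.RIGHT_WRIST, 0])
    sigs = [MotionSignal(v, seq.fps) for v in (width, spread)]
    try:
        res = coordination(sigs, parts=["trunk", "arms"], period=period,
                           unify_threshold=_TR_UNIFY_THRESHOLD_S)
    except ValueError:
        return []
    if res.unified:
        maxlag = float(np.max(np.abs(res.lag_matrix)))
        sev = max(0.0, 1.0 - maxlag / _TR_UNIFY_THRESHOLD_S)
        return [GuidelineViolation("TR", "TR_unified", -1, sev,
                                   MESSAGES["TR_unified"])]
    return []


def _sqt_knee_toe_check(seq, reps, tolerance):
    """Frontal-plane approximation of the knees-behind-toes rule."""
    out = []
    sides = (
        ("left", lm.LEFT_KNEE, lm.LEFT_FOOT_INDEX, lm.LEFT_HEEL, +1.0),
        ("right", lm.RIGHT_KNEE, lm.RIGHT_FOOT_INDEX, lm.RIGHT_HEEL, -1.0),
    )
    for k, r in enumerate(reps):
        worst = 0.0
        for _, knee, toe, heel, outward in sides:
            foot_len = float(np.median(np.linalg.norm(
                seq.data[r.start:r.end, toe, :3] - seq.data[r.start:r.end, heel, :3],
                axis=1)))
            if foot_len <= 0:
                continue
            exc = (seq.data[r.start:r.end, knee, 0]
                   - seq.data[r.start:r.end, toe, 0]) * outward
            worst = max(worst, float(np.max(exc)) / foot_len)
        if worst > tolerance:
            out.append(GuidelineViolation(
                "SQT", "SQT_knees_toes", k, worst, MESSAGES["SQT_knees_toes"]))
    return out


# ---------------------------------------------------------------------------
# Normative comparison and reporting


def compare_to_normative(
    rom: ROMSummary,
    table: Dict[str, float] = NORMATIVE_ROM_DEG,
) -> Tuple[float, bool]:
    """Ratio of achieved median ROM to the normative value.

    Returns ``(ratio, below_norm)`` with ``below_norm`` true when the
    subject does not reach the literature value.
    """
    measure = rom.measure or (EXERCISE_MEASURES.get(rom.exercise, ("",))[0])
    if measure not in table:
        raise KeyError(f"no normative value for measure {measure!r}")
    ratio = rom.median_max / table[measure]
    return ratio, ratio < 1.0


def _ma_attenuation(n_win: int, f_hz: float, fs: float) -> float:
    """Gain of an n-sample moving average at frequency f (Dirichlet kernel)."""
    x = math.pi * f_hz / fs
    if x < 1e-12:
        return 1.0
    return abs(math.sin(n_win * x) / (n_win * math.sin(x)))


def _smoothed_sequence(seq: PoseSequence, smooth_s: float = 0.07) -> PoseSequence:
    """Moving-average smooth all coordinate traces of a sequence."""
    from scipy.ndimage import uniform_filter1d

    m = max(1, round(smooth_s * seq.fps))
    data = seq.data.copy()
    data[:, :, :3] = uniform_filter1d(
        seq.data[:, :, :3], size=2 * m + 1, axis=0, mode="nearest")
    return PoseSequence(data, seq.t.copy(), seq.fps, dict(seq.meta))


_MEASURE_SPECS: Dict[str, List[dict]] = {
    # measure -> list of (side, triplet-or-rotation, mode)
    "hip_abduction": [
        {"side": "left", "triplet": JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP, lm.LEFT_KNEE), "mode": "excursion"},
        {"side": "right", "triplet": JointTriplet(lm.RIGHT_SHOULDER, lm.RIGHT_HIP, lm.RIGHT_KNEE), "mode": "excursion"},
    ],
    "shoulder_abduction": [
        {"side": "left", "triplet": JointTriplet(lm.LEFT_HIP, lm.LEFT_SHOULDER, lm.LEFT_ELBOW), "mode": "excursion"},
        {"side": "right", "triplet": JointTriplet(lm.RIGHT_HIP, lm.RIGHT_SHOULDER, lm.RIGHT_ELBOW), "mode": "excursion"},
    ],
    "lumbar_rotation": [
        {"side": "n/a", "rotation": True, "mode": "peak"},
    ],
    "spinal_flexion": [
        {"side": "left", "triplet": JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP, lm.LEFT_KNEE, "xyz"), "mode": "excursion"},
    ],
    "squat_hip_flexion": [
        {"side": "left", "triplet": JointTriplet(lm.LEFT_SHOULDER, lm.LEFT_HIP, lm.LEFT_KNEE, "xyz"), "mode": "flexion"},
    ],
    "squat_knee_flexion": [
        {"side": "left", "triplet": JointTriplet(lm.LEFT_HIP, lm.LEFT_KNEE, lm.LEFT_ANKLE, "xyz"), "mode": "flexion"},
    ],
}


def exercise_rom_report(
    seq: PoseSequence,
    exercise: str,
    reps: Sequence[RepetitionSegment],
) -> List[dict]:
    """ROM summaries, normative ratios and angular velocity per measure.

    One record per (measure, side): the per-repetition maxima, their
    median, the normative ratio and the mean angular velocity
    ``ω = ROM / repetition duration`` (rad/s, Eq. ω = dθ/dt with dt one
    repetition).
    """
    if exercise not in EXERCISES:
        raise ValueError(f"unknown exercise {exercise!r}")
    if not reps:
        raise ValueError("need at least one repetition")
    med_dur = float(np.median([r.duration for r in reps]))
    # Smooth the landmark traces before the angle transform: near 0/180
    # the triplet angle folds coordinate jitter into a one-sided bias
    # that no amount of post-hoc angle smoothing can remove.  The window
    # scales with the repetition duration — slower movements tolerate
    # (and, for per-repetition extrema, need) more smoothing, while a
    # fast movement's sharp peak must not be flattened.
    smooth_s = float(np.clip(0.05 * med_dur, 0.07, 0.2))
    seq_s = _smoothed_sequence(seq, smooth_s=smooth_s)
    # The moving average attenuates the movement's fundamental by a known
    # factor; undo it so ROM is unbiased regardless of repetition speed.
    n_win = 2 * max(1, round(smooth_s * seq.fps)) + 1
    alpha = _ma_attenuation(n_win, 1.0 / med_dur, seq.fps)
    out = []
    for measure in EXERCISE_MEASURES[exercise]:
        for spec in _MEASURE_SPECS[measure]:
            if spec.get("rotation"):
                ang = trunk_rotation_series(seq_s)
                ang = AngleSeries(np.abs(ang.values), ang.fs, None, exercise)
            else:
                ang = angle_series(seq_s, spec["triplet"], exercise=exercise)
            summ = rom_summary(ang, reps, spec["mode"], exercise,
                               spec["side"], measure)
            # p2p measures scale with the fundamental's gain alpha; rest-
            # referenced maxima keep the unattenuated DC half: (1+alpha)/2.
            corr = 1.0 / alpha if spec["mode"] == "excursion" else 2.0 / (1.0 + alpha)
            summ = ROMSummary([v * corr for v in summ.per_rep_max],
                              summ.median_max * corr, summ.exercise,
                              summ.side, summ.measure)
            ratio, below = compare_to_normative(summ)
            out.append({
                "exercise": exercise,
                "measure": measure,
                "side": spec["side"],
                "per_rep_max_deg": summ.per_rep_max,
                "median_max_deg": summ.median_max,
                "normative_deg": NORMATIVE_ROM_DEG[measure],
                "ratio": ratio,
                "below_norm": below,
                "omega_rad_s": angular_velocity(math.radians(summ.median_max), med_dur),
            })
    return out
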