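"""Parametric generator of skeleton motion for the five-exercise repertoire.

Emulates what a monocular pose estimator would report for a subject
performing side steps (SS), shoulder abductions (SA), trunk rotations
(TR), standing forward bends (FB) and squats (SQT) in front of a
frontal camera: per-frame normalized ``(x, y, z, visibility)``
landmarks on the BlazePose 33-point topology, with configurable range
of motion, repetition period, pauses, sensor noise, hand-held-camera
drift and injectable execution errors — plus exact ground truth
(labels, repetition boundaries, driven angles, clean landmark
positions) so that every downstream stage can be tested without video
recordings.

The figure is a planar (frontal) kinematic chain rooted at the pelvis.
Joint drives follow a raised-cosine profile
``θ(t) = rom · (1 − cos(2πt/T)) / 2`` — C¹-smooth, starting and ending
each repetition at the rest posture, which gives segmentation
unambiguous boundary anchors.  Sagittal movements (forward bend, squat
knee travel) are rendered in the depth channel; trunk rotation appears
as shoulder-width foreshortening plus antisymmetric shoulder depth,
exactly the signal the kinematics module measures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np

from . import landmarks as lm
from .pose_model import PoseSequence

__all__ = [
    "SkeletonSpec",
    "Phase",
    "MotionScript",
    "PhaseTruth",
    "GroundTruth",
    "EXERCISE_TEMPLATES",
    "simulate",
    "make_dataset",
    "scenario_script",
]


@dataclass(frozen=True)
class SkeletonSpec:
    """Segment lengths of the synthetic figure, normalized image units.

    Defaults place a standing adult comfortably inside the unit image
    at a typical 4-5 m recording distance.  Hip width equals shoulder
    width by design: each hip then sits directly below the same-side
    shoulder, so frontal-plane angle triplets recover the driven joint
    angles exactly (a stylized, not anthropometric, proportion).
    """

    trunk: float = 0.25
    upper_arm: float = 0.12
    forearm: float = 0.11
    hand: float = 0.04
    thigh: float = 0.18
    shank: float = 0.18
    shoulder_width: float = 0.16
    hip_width: float = 0.16
    foot_length: float = 0.06
    head_offset: float = 0.08
    pelvis: Tuple[float, float] = (0.5, 0.55)

    def __post_init__(self) -> None:
        for name in ("trunk", "upper_arm", "forearm", "hand", "thigh", "shank",
                     "shoulder_width", "hip_width", "foot_length", "head_offset"):
            if getattr(self, name) <= 0:
                raise ValueError(f"skeleton segment {name} must be positive")

    @property
    def arm_length(self) -> float:
        """Shoulder-to-index-fingertip length (the RDS of one arm)."""
        return self.upper_arm + self.forearm + self.hand


@dataclass
class Phase:
    """One segment of a motion script: an exercise bout, or idle time."""

    exercise: Optional[str] = None   # SS | SA | TR | FB | SQT | None (idle)
    rom_deg: float = 0.0
    period_s: float = 0.0
    n_reps: int = 0
    duration_s: float = 0.0          # idle phases only
    pause_after_s: float = 0.0
    errors: Dict[str, float] = field(default_factory=dict)
    arm_lag_s: float = 0.4           # TR: how far the arms trail the trunk

    def __post_init__(self) -> None:
        if self.exercise is not None:
            if self.exercise not in ("SS", "SA", "TR", "FB", "SQT"):
                raise ValueError(f"unknown exercise {self.exercise!r}")
            if self.rom_deg <= 0 or self.period_s <= 0 or self.n_reps < 1:
                raise ValueError("exercise phases need rom_deg, period_s > 0, n_reps >= 1")
        known = {"bent_elbow_deg", "bent_knee_deg", "knees_past_toes",
                 "unified_trunk_rotation", "partial_body"}
        unknown = set(self.errors) - known
        if unknown:
            raise ValueError(f"unknown error flags {sorted(unknown)}")


@dataclass
class MotionScript:
    phases: List[Phase]
    fps: float = 30.0
    noise_sd: float = 0.0
    drift_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.noise_sd < 0 or self.drift_sd < 0:
            raise ValueError("noise/drift standard deviations must be >= 0")


@dataclass
class PhaseTruth:
    label: Optional[str]
    start: int                      # global frame index, inclusive
    end: int                        # exclusive
    rep_bounds: List[int]           # n_reps + 1 global frame indices
    rom_deg: Dict[str, float]       # true ROM per kinematic measure
    period_s: float
    errors: Dict[str, float]


@dataclass
class GroundTruth:
    phases: List[PhaseTruth]
    clean: np.ndarray               # (n, 33, 3) pre-noise landmark positions
    warnings: List[str] = field(default_factory=list)

    @property
    def n_repetitions(self) -> int:
        return sum(len(p.rep_bounds) - 1 for p in self.phases if p.label)


#: Per-class (rom_deg, period_s) templates: the study conditions the
#: generator emulates — hip-abduction, shoulder-abduction, lumbar
#: rotation and squat knee-flexion amplitudes near their normative /
#: reported ranges, at self-selected repetition speeds of 2-4 s.
EXERCISE_TEMPLATES: Dict[str, Tuple[float, float]] = {
    "SS": (40.0, 2.0),
    "SA": (150.0, 3.0),
    "TR": (45.0, 3.0),
    "FB": (100.0, 3.5),
    "SQT": (85.0, 3.0),
}

_TRUE_ROM = {
    "SS": lambda rom: {"hip_abduction": rom},
    "SA": lambda rom: {"shoulder_abduction": rom},
    "TR": lambda rom: {"lumbar_rotation": rom},
    "FB": lambda rom: {"spinal_flexion": rom},
    # Two-link leg geometry with a vertical trunk: hip flexion is half
    # the driven knee flexion.
    "SQT": lambda rom: {"squat_knee_flexion": rom, "squat_hip_flexion": rom / 2.0},
}


# ---------------------------------------------------------------------------
# Forward kinematics


def _neutral(S: SkeletonSpec) -> np.ndarray:
    """Standing rest posture, shape (33, 3)."""
    P = np.zeros((lm.N_LANDMARKS, 3))
    px, py = S.pelvis
    pelvis = np.array([px, py, 0.0])
    hipL = pelvis + [S.hip_width / 2, 0, 0]
    hipR = pelvis - [S.hip_width / 2, 0, 0]
    midsh = pelvis + [0, -S.trunk, 0]
    shL = midsh + [S.shoulder_width / 2, 0, 0]
    shR = midsh - [S.shoulder_width / 2, 0, 0]
    nose = midsh + [0, -S.head_offset, 0]

    down = np.array([0.0, 1.0, 0.0])
    P[lm.LEFT_HIP], P[lm.RIGHT_HIP] = hipL, hipR
    P[lm.LEFT_SHOULDER], P[lm.RIGHT_SHOULDER] = shL, shR
    P[lm.NOSE] = nose
    # arms hanging
    for sh_i, el, wr, pk, ix, th in (
        (lm.LEFT_SHOULDER, lm.LEFT_ELBOW, lm.LEFT_WRIST, lm.LEFT_PINKY, lm.LEFT_INDEX, lm.LEFT_THUMB),
        (lm.RIGHT_SHOULDER, lm.RIGHT_ELBOW, lm.RIGHT_WRIST, lm.RIGHT_PINKY, lm.RIGHT_INDEX, lm.RIGHT_THUMB),
    ):
        P[el] = P[sh_i] + S.upper_arm * down
        P[wr] = P[el] + S.forearm * down
        P[ix] = P[wr] + S.hand * down
        P[pk] = P[wr] + 0.9 * S.hand * down
        P[th] = P[wr] + 0.5 * S.hand * down
    # legs
    for hip_i, kn, an, out in (
        (lm.LEFT_HIP, lm.LEFT_KNEE, lm.LEFT_ANKLE, +1.0),
        (lm.RIGHT_HIP, lm.RIGHT_KNEE, lm.RIGHT_ANKLE, -1.0),
    ):
        P[kn] = P[hip_i] + S.thigh * down
        P[an] = P[kn] + S.shank * down
    _place_feet(P, S)
    _place_face(P)
    return P


def _foot_vec(S: SkeletonSpec, out: float) -> np.ndarray:
    v = np.array([0.02 * out, 0.005, -0.055])
    return v / np.linalg.norm(v) * S.foot_length


def _place_feet(P: np.ndarray, S: SkeletonSpec) -> None:
    for an, he, ft, out in (
        (lm.LEFT_ANKLE, lm.LEFT_HEEL, lm.LEFT_FOOT_INDEX, +1.0),
        (lm.RIGHT_ANKLE, lm.RIGHT_HEEL, lm.RIGHT_FOOT_INDEX, -1.0),
    ):
        P[he] = P[an] + np.array([-0.01 * out, 0.025, 0.015])
        P[ft] = P[he] + _foot_vec(S, out)


_FACE_OFFSETS = {
    lm.LEFT_EYE_INNER: (0.008, -0.012, 0.0),
    lm.LEFT_EYE: (0.016, -0.012, 0.0),
    lm.LEFT_EYE_OUTER: (0.024, -0.012, 0.0),
    lm.RIGHT_EYE_INNER: (-0.008, -0.012, 0.0),
    lm.RIGHT_EYE: (-0.016, -0.012, 0.0),
    lm.RIGHT_EYE_OUTER: (-0.024, -0.012, 0.0),
    lm.LEFT_EAR: (0.035, -0.005, 0.01),
    lm.RIGHT_EAR: (-0.035, -0.005, 0.01),
    lm.MOUTH_LEFT: (0.01, 0.015, 0.0),
    lm.MOUTH_RIGHT: (-0.01, 0.015, 0.0),
}


def _place_face(P: np.ndarray) -> None:
    for i, off in _FACE_OFFSETS.items():
        P[i] = P[lm.NOSE] + np.array(off)


def _rest_pose(S: SkeletonSpec, exercise: Optional[str]) -> np.ndarray:
    """Rest stance for a given exercise (33, 3).

    Identical to the neutral standing pose except for trunk rotation,
    whose ready stance holds the arms extended sideways; idle and pause
    frames adjacent to an exercise use its rest stance so that motion
    between phases stays continuous (a subject assumes the stance while
    resting rather than teleporting into it).
    """
    P = _neutral(S)
    if exercise == "TR":
        block = P[None, :, :].copy()
        for out in (+1.0, -1.0):
            d = np.array([[out, 0.0, 0.0]])
            _set_arm(block, S, out, d)
        P = block[0]
    return P


def _raised_cosine(n: int, period_frames: float) -> np.ndarray:
    """0 -> 1 -> 0 per repetition cycle, C1-smooth."""
    t = np.arange(n)
    return 0.5 * (1.0 - np.cos(2.0 * math.pi * t / period_frames))


_ARM_CHAIN = {
    +1.0: (lm.LEFT_SHOULDER, lm.LEFT_ELBOW, lm.LEFT_WRIST,
           lm.LEFT_PINKY, lm.LEFT_INDEX, lm.LEFT_THUMB),
    -1.0: (lm.RIGHT_SHOULDER, lm.RIGHT_ELBOW, lm.RIGHT_WRIST,
           lm.RIGHT_PINKY, lm.RIGHT_INDEX, lm.RIGHT_THUMB),
}
_LEG_CHAIN = {
    +1.0: (lm.LEFT_HIP, lm.LEFT_KNEE, lm.LEFT_ANKLE,
           lm.LEFT_HEEL, lm.LEFT_FOOT_INDEX),
    -1.0: (lm.RIGHT_HIP, lm.RIGHT_KNEE, lm.RIGHT_ANKLE,
           lm.RIGHT_HEEL, lm.RIGHT_FOOT_INDEX),
}


def _set_arm(P: np.ndarray, S: SkeletonSpec, out: float,
             dir_ua: np.ndarray, dir_fa: Optional[np.ndarray] = None) -> None:
    """Place one arm chain for all frames given per-frame directions.

    ``P`` is (n, 33, 3); ``dir_ua``/``dir_fa`` are (n, 3) unit vectors
    for the upper arm and forearm (forearm defaults to the upper arm:
    a straight elbow)."""
    sh, el, wr, pk, ix, th = _ARM_CHAIN[out]
    if dir_fa is None:
        dir_fa = dir_ua
    P[:, el] = P[:, sh] + S.upper_arm * dir_ua
    P[:, wr] = P[:, el] + S.forearm * dir_fa
    P[:, ix] = P[:, wr] + S.hand * dir_fa
    P[:, pk] = P[:, wr] + 0.9 * S.hand * dir_fa
    P[:, th] = P[:, wr] + 0.5 * S.hand * dir_fa


def _set_leg_straight(P: np.ndarray, S: SkeletonSpec, out: float,
                      dir_leg: np.ndarray) -> None:
    hip, kn, an, he, ft = _LEG_CHAIN[out]
    P[:, kn] = P[:, hip] + S.thigh * dir_leg
    P[:, an] = P[:, kn] + S.shank * dir_leg
    P[:, he] = P[:, an] + np.array([-0.01 * out, 0.025, 0.015])
    P[:, ft] = P[:, he] + _foot_vec(S, out)


def _rot_xy(d: np.ndarray, ang: np.ndarray) -> np.ndarray:
    """Rotate (n,3) directions by per-frame angles within the xy plane."""
    c, s = np.cos(ang), np.sin(ang)
    out = np.empty_like(d)
    out[:, 0] = c * d[:, 0] - s * d[:, 1]
    out[:, 1] = s * d[:, 0] + c * d[:, 1]
    out[:, 2] = d[:, 2]
    return out


def _phase_frames(phase: Phase, S: SkeletonSpec, fps: float) -> np.ndarray:
    """Clean landmark positions (n, 33, 3) for one exercise bout."""
    pf = phase.period_s * fps
    n = int(round(phase.n_reps * pf))
    base = np.broadcast_to(_neutral(S), (n, lm.N_LANDMARKS, 3)).copy()
    theta = np.radians(phase.rom_deg) * _raised_cosine(n, pf)
    ex = phase.exercise

    if ex == "SS":
        # bilateral hip ab/adduction: both legs swing out and back.
        for out in (+1.0, -1.0):
            d = np.zeros((n, 3))
            d[:, 0] = np.sin(theta) * out
            d[:, 1] = np.cos(theta)
            _set_leg_straight(base, S, out, d)

    elif ex == "SA":
        # an injected elbow bend develops with the movement (no teleport
        # between phases): full bend at peak abduction, straight at rest.
        bend = math.radians(phase.errors.get("bent_elbow_deg", 0.0))
        prof = theta / max(np.radians(phase.rom_deg), 1e-9)
        for out in (+1.0, -1.0):
            d = np.zeros((n, 3))
            d[:, 0] = np.sin(theta) * out
            d[:, 1] = np.cos(theta)
            d_fa = _rot_xy(d, -bend * out * prof) if bend else None
            _set_arm(base, S, out, d, d_fa)

    elif ex == "TR":
        # alternate rotation direction per repetition
        rep_idx = (np.arange(n) // int(round(pf))).astype(int)
        sign = np.where(rep_idx % 2 == 0, 1.0, -1.0)
        rho = sign * theta
        lag = 0.0 if phase.errors.get("unified_trunk_rotation") else phase.arm_lag_s
        shift = int(round(lag * fps))
        rho_arm = np.concatenate([np.zeros(min(shift, n)), rho[: max(n - shift, 0)]])
        pelvis = np.array([S.pelvis[0], S.pelvis[1], 0.0])
        midsh = pelvis + np.array([0, -S.trunk, 0])
        half = S.shoulder_width / 2.0
        sh_off = np.stack([half * np.cos(rho), np.zeros(n), -half * np.sin(rho)], axis=1)
        base[:, lm.LEFT_SHOULDER] = midsh + sh_off
        base[:, lm.RIGHT_SHOULDER] = midsh - sh_off
        for out in (+1.0, -1.0):
            d = np.stack([np.cos(rho_arm) * out, np.zeros(n),
                          -np.sin(rho_arm) * out], axis=1)
            _set_arm(base, S, out, d)

    elif ex == "FB":
        pelvis = np.array([S.pelvis[0], S.pelvis[1], 0.0])
        lean = np.stack([np.zeros(n), -np.cos(theta), -np.sin(theta)], axis=1)
        midsh = pelvis + S.trunk * lean
        half = S.shoulder_width / 2.0
        base[:, lm.LEFT_SHOULDER] = midsh + [half, 0, 0]
        base[:, lm.RIGHT_SHOULDER] = midsh - [half, 0, 0]
        nose = midsh + S.head_offset * lean
        base[:, lm.NOSE] = nose
        for i, off in _FACE_OFFSETS.items():
            base[:, i] = nose + np.array(off)
        down = np.broadcast_to(np.array([0.0, 1.0, 0.0]), (n, 3))
        for out in (+1.0, -1.0):
            _set_arm(base, S, out, down.copy())
        bend = math.radians(phase.errors.get("bent_knee_deg", 0.0))
        if bend:
            prof = theta / max(np.radians(phase.rom_deg), 1e-9)
            half_b = bend * prof / 2.0
            for out in (+1.0, -1.0):
                _set_bent_leg(base, S, out, half_b, psi=0.0)

    elif ex == "SQT":
        half_g = theta / 2.0
        psi = math.radians(35.0) if phase.errors.get("knees_past_toes") else 0.0
        neutral = _neutral(S)
        for out in (+1.0, -1.0):
            hip, kn, an, he, ft = _LEG_CHAIN[out]
            ankle = neutral[an]
            base[:, an] = ankle
            base[:, he] = ankle + np.array([-0.01 * out, 0.025, 0.015])
            base[:, ft] = base[:, he] + _foot_vec(S, out)
            ell = S.shank  # == thigh by two-link symmetry requirement
            hip_pos = ankle + np.stack(
                [np.zeros(n), -(S.thigh + S.shank) * np.cos(half_g), np.zeros(n)],
                axis=1)
            e = ell * np.sin(half_g)
            d_off = np.array([math.sin(psi) * out, 0.0, -math.cos(psi)])
            base[:, kn] = (hip_pos + ankle) / 2.0 + e[:, None] * d_off
            base[:, hip] = hip_pos
        # trunk rides on the pelvis, staying vertical
        pelvis = (base[:, lm.LEFT_HIP] + base[:, lm.RIGHT_HIP]) / 2.0
        midsh = pelvis + [0, -S.trunk, 0]
        half = S.shoulder_width / 2.0
        base[:, lm.LEFT_SHOULDER] = midsh + [half, 0, 0]
        base[:, lm.RIGHT_SHOULDER] = midsh - [half, 0, 0]
        nose = midsh + [0, -S.head_offset, 0]
        base[:, lm.NOSE] = nose
        for i, off in _FACE_OFFSETS.items():
            base[:, i] = nose + np.array(off)
        down = np.broadcast_to(np.array([0.0, 1.0, 0.0]), (n, 3))
        for out in (+1.0, -1.0):
            _set_arm(base, S, out, down.copy())

    else:  # pragma: no cover - guarded by Phase validation
        raise ValueError(f"unknown exercise {ex!r}")

    return base


def _set_bent_leg(P: np.ndarray, S: SkeletonSpec, out: float,
                  half_bend: np.ndarray, psi: float) -> None:
    """Two-link leg with the knee displaced off the hip-ankle line."""
    hip, kn, an, he, ft = _LEG_CHAIN[out]
    n = P.shape[0]
    hip_pos = P[:, hip]
    length = (S.thigh + S.shank) * np.cos(half_bend)
    ankle = hip_pos + np.stack([np.zeros(n), length, np.zeros(n)], axis=1)
    e = S.shank * np.sin(half_bend)
    d_off = np.array([math.sin(psi) * out, 0.0, -math.cos(psi)])
    P[:, an] = ankle
    P[:, kn] = (hip_pos + ankle) / 2.0 + e[:, None] * d_off
    P[:, he] = ankle + np.array([-0.01 * out, 0.025, 0.015])
    P[:, ft] = P[:, he] + _foot_vec(S, out)


# ---------------------------------------------------------------------------
# Simulation


def simulate(
    script: MotionScript,
    skeleton: Optional[SkeletonSpec] = None,
) -> Tuple[PoseSequence, GroundTruth]:
    """Render a motion script into a pose sequence plus ground truth.

    Deterministic given ``script.seed``.  Gaussian sensor noise
    (``noise_sd``) is i.i.d. per coordinate; camera drift
    (``drift_sd``) is a random walk shared by all landmarks, the
    common-mode artifact SSA detrending is meant to remove.  The
    ``partial_body`` error shifts the figure down until the lower body
    leaves the image (low visibility there); if the clean figure leaves
    the unit image *without* that intent, a warning is recorded in the
    ground truth instead.
    """
    S = skeleton or SkeletonSpec()
    fps = script.fps
    rng = np.random.default_rng(script.seed)

    blocks: List[np.ndarray] = []
    vis_blocks: List[np.ndarray] = []
    truths: List[PhaseTruth] = []
    warnings: List[str] = []
    cursor = 0

    labels = [p.exercise for p in script.phases]

    def _stance_after(i: int) -> Optional[str]:
        """Stance for rest frames following phase i: the upcoming
        exercise's rest stance, else the one just performed."""
        nxt = next((l for l in labels[i + 1:] if l), None)
        prv = next((l for l in reversed(labels[:i + 1]) if l), None)
        return nxt or prv

    def _static(seconds: float, stance: Optional[str]) -> int:
        n = int(round(seconds * fps))
        if n > 0:
            pose = _rest_pose(S, stance)
            blocks.append(np.broadcast_to(pose, (n, lm.N_LANDMARKS, 3)).copy())
            vis_blocks.append(np.ones((n, lm.N_LANDMARKS)))
        return n

    for pi, phase in enumerate(script.phases):
        if phase.exercise is None:
            n = _static(phase.duration_s, _stance_after(pi))
            truths.append(PhaseTruth(None, cursor, cursor + n, [], {},
                                     0.0, dict(phase.errors)))
            cursor += n
            cursor += _static(phase.pause_after_s, _stance_after(pi))
            continue

        block = _phase_frames(phase, S, fps)
        n = block.shape[0]
        vis = np.ones((n, lm.N_LANDMARKS))
        if phase.errors.get("partial_body"):
            block = block + np.array([0.0, 0.25, 0.0])
            vis[block[:, :, 1] > 1.0] = 0.2
        else:
            xy = block[:, :, :2]
            if xy.min() < 0.0 or xy.max() > 1.0:
                warnings.append(
                    f"{phase.exercise}: figure leaves the unit image "
                    f"(x/y range {xy.min():.3f}..{xy.max():.3f})"
                )
        blocks.append(block)
        vis_blocks.append(vis)
        pf = phase.period_s * fps
        bounds = [cursor + int(round(k * pf)) for k in range(phase.n_reps)] + [cursor + n]
        truths.append(PhaseTruth(phase.exercise, cursor, cursor + n, bounds,
                                 _TRUE_ROM[phase.exercise](phase.rom_deg),
                                 phase.period_s, dict(phase.errors)))
        cursor += n
        cursor += _static(phase.pause_after_s, _stance_after(pi))

    if not blocks:
        clean = np.empty((0, lm.N_LANDMARKS, 3))
        vis_all = np.empty((0, lm.N_LANDMARKS))
    else:
        clean = np.concatenate(blocks, axis=0)
        vis_all = np.concatenate(vis_blocks, axis=0)
    n_total = clean.shape[0]

    noisy = clean.copy()
    if script.drift_sd > 0 and n_total:
        drift = rng.normal(0.0, script.drift_sd, size=(n_total, 2)).cumsum(axis=0)
        noisy[:, :, 0] += drift[:, 0:1]
        noisy[:, :, 1] += drift[:, 1:2]
    if script.noise_sd > 0 and n_total:
        noisy += rng.normal(0.0, script.noise_sd, size=noisy.shape)

    data = np.concatenate([noisy, vis_all[:, :, None]], axis=2)
    t = np.arange(n_total) / fps
    seq = PoseSequence(data, t, fps, {"source": "synthetic", "seed": script.seed})
    return seq, GroundTruth(truths, clean, warnings)


# ---------------------------------------------------------------------------
# Corpus generation


def make_dataset(
    n_subjects: int,
    reps_per_exercise: int = 6,
    rom_jitter: float = 0.10,
    period_jitter: float = 0.15,
    skeleton_jitter: float = 0.04,
    noise_sd: float = 0.003,
    fps: float = 29.0,
    seed: int = 0,
) -> List[dict]:
    """Synthetic multi-subject exercise corpus, one trial per (subject, exercise).

    Each subject draws skeleton proportions and per-exercise ROM /
    period from normal jitter around the class templates (defaults:
    ROM +/-10 %, period +/-15 %), mimicking between-subject variation in
    a volunteer cohort.  Returns trial records
    ``{"seq", "label", "subject_id", "truth"}``.
    """
    if n_subjects < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    base = SkeletonSpec()
    trials: List[dict] = []
    for s in range(n_subjects):
        scale = {
            name: getattr(base, name) * float(np.clip(
                1.0 + rng.normal(0.0, skeleton_jitter), 0.8, 1.2))
            for name in ("trunk", "upper_arm", "forearm", "hand", "thigh",
                         "foot_length", "head_offset")
        }
        # thigh and shank stay equal: the two-link knee geometry keeps
        # bone lengths exact only for a symmetric leg.
        scale["shank"] = scale["thigh"]
        width = base.shoulder_width * float(np.clip(
            1.0 + rng.normal(0.0, skeleton_jitter), 0.8, 1.2))
        skel = replace(base, shoulder_width=width, hip_width=width, **scale)
        for label, (rom0, per0) in EXERCISE_TEMPLATES.items():
            rom = rom0 * float(np.clip(1.0 + rng.normal(0.0, rom_jitter), 0.6, 1.4))
            per = max(0.8, per0 * float(np.clip(
                1.0 + rng.normal(0.0, period_jitter), 0.6, 1.4)))
            script = MotionScript(
                phases=[Phase(label, rom, per, reps_per_exercise)],
                fps=fps, noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            seq, truth = simulate(script, skel)
            seq.meta.update({"subject_id": f"S{s:03d}", "label": label})
            trials.append({"seq": seq, "label": label,
                           "subject_id": f"S{s:03d}", "truth": truth})
    return trials


def scenario_script(seed: int = 0) -> MotionScript:
    """The canned live-testing scenario.

    The user idles, performs two error-free side-step repetitions,
    pauses, then performs shoulder abductions — first with excessively
    bent elbows, then cleanly.  Replayed through the session engine it
    must produce: inactivity motivation, SS recognition, two counted
    repetitions, another motivation during the pause, SA recognition
    with a counter reset, "Keep the arms straight!" corrections while
    the elbows are bent, and no corrections once they straighten.
    """
    ss_rom, ss_per = EXERCISE_TEMPLATES["SS"]
    sa_rom, sa_per = EXERCISE_TEMPLATES["SA"]
    return MotionScript(
        phases=[
            Phase(None, duration_s=6.0),
            Phase("SS", ss_rom, ss_per, 2, pause_after_s=6.0),
            Phase("SA", sa_rom, sa_per, 2, errors={"bent_elbow_deg": 40.0}),
            Phase("SA", sa_rom, sa_per, 2, pause_after_s=2.0),
        ],
        fps=30.0,
        noise_sd=0.002,
        seed=seed,
    )
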