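"""Data model and I/O for BlazePose-topology keypoint sequences.

The pose-estimation network itself is treated as an interface: anything
that produces 33 landmarks of ``(x, y, z, visibility)`` per frame can
feed this package, whether a file written by a recorder, the synthetic
motion generator, or a live adapter (any callable mapping an RGB frame
to a :class:`KeypointFrame` — the core never imports video code).

Also hosts the body-centering geometry used for automatic zooming: the
body center (hip midpoint), the per-subject reference distance (RDS,
mean shoulder-to-index-finger length) and the crop box derived from
them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Tuple

import numpy as np

from . import landmarks as lm
from .signal_prep import MotionSignal

__all__ = [
    "Landmark",
    "KeypointFrame",
    "PoseSequence",
    "CropBox",
    "SignalSet",
    "BodyNotDetectedError",
    "CalibrationError",
    "KeypointParseError",
    "read_keypoints",
    "write_keypoints",
    "body_center",
    "reference_distance",
    "compute_crop_box",
    "full_body_visible",
    "extract_signals",
]


class BodyNotDetectedError(ValueError):
    """The landmarks needed for a body measurement are not visible."""


class CalibrationError(ValueError):
    """Calibration geometry (RDS / crop box) cannot be established."""


class KeypointParseError(ValueError):
    """A keypoint file is malformed."""


@dataclass(frozen=True)
class Landmark:
    """One body keypoint in normalized image coordinates."""

    x: float
    y: float
    z: float
    visibility: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.visibility <= 1.0):
            raise ValueError(f"visibility must be in [0,1], got {self.visibility}")
        if not (np.isfinite(self.x) and np.isfinite(self.y) and np.isfinite(self.z)):
            raise ValueError("landmark coordinates must be finite")

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])


@dataclass
class KeypointFrame:
    """All 33 landmarks of one video frame.

    ``landmarks`` is a float array of shape (33, 4) in BlazePose index
    order with columns x, y, z, visibility.
    """

    landmarks: np.ndarray
    t: float
    index: int = 0

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float)
        if self.landmarks.shape != (lm.N_LANDMARKS, 4):
            raise ValueError(
                f"a frame must have exactly {lm.N_LANDMARKS} landmarks, "
                f"got shape {self.landmarks.shape}"
            )
        if self.index < 0:
            raise ValueError("frame index must be >= 0")
        vis = self.landmarks[:, 3]
        if np.any((vis < 0) | (vis > 1)):
            raise ValueError("visibility scores must lie in [0,1]")
        if not np.all(np.isfinite(self.landmarks)):
            raise ValueError("landmark coordinates must be finite")

    def landmark(self, i: int) -> Landmark:
        x, y, z, v = self.landmarks[i]
        return Landmark(x, y, z, v)

    def xy(self, i: int) -> np.ndarray:
        return self.landmarks[i, :2]

    def xyz(self, i: int) -> np.ndarray:
        return self.landmarks[i, :3]

    def visibility(self, i: int) -> float:
        return float(self.landmarks[i, 3])


@dataclass
class PoseSequence:
    """A timestamped sequence of keypoint frames at a fixed frame rate.

    Internally a single ``(n, 33, 4)`` array plus a time vector;
    :attr:`frames` yields :class:`KeypointFrame` views.
    """

    data: np.ndarray           # (n, 33, 4)
    t: np.ndarray              # (n,)
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        if self.data.ndim != 3 or self.data.shape[1:] != (lm.N_LANDMARKS, 4):
            raise ValueError(
                f"data must have shape (n, {lm.N_LANDMARKS}, 4), got {self.data.shape}"
            )
        if self.t.shape != (self.data.shape[0],):
            raise ValueError("timestamp vector must match the frame count")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt < 0):
                raise ValueError("frame timestamps must be nondecreasing")
            med = float(np.median(dt))
            if med > 0 and abs(med - 1.0 / self.fps) > 0.1 / self.fps:
                raise ValueError(
                    f"median frame interval {med:.4f}s inconsistent with fps={self.fps}"
                )

    @classmethod
    def from_frames(
        cls, frames: List[KeypointFrame], fps: float, meta: Optional[dict] = None
    ) -> "PoseSequence":
        if not frames:
            return cls(np.empty((0, lm.N_LANDMARKS, 4)), np.empty(0), fps, meta or {})
        data = np.stack([f.landmarks for f in frames])
        t = np.array([f.t for f in frames])
        return cls(data, t, fps, meta or {})

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.n_frames / self.fps

    def frame(self, i: int) -> KeypointFrame:
        return KeypointFrame(self.data[i], float(self.t[i]), i)

    @property
    def frames(self) -> Iterator[KeypointFrame]:
        for i in range(self.n_frames):
            yield self.frame(i)

    def slice(self, start: int, end: int) -> "PoseSequence":
        return PoseSequence(
            self.data[start:end].copy(), self.t[start:end].copy(), self.fps, dict(self.meta)
        )


@dataclass
class CropBox:
    """Square (by default) body-centered crop region, normalized units."""

    cx: float
    cy: float
    half_w: float
    half_h: float

    def __post_init__(self) -> None:
        if self.half_w <= 0 or self.half_h <= 0:
            raise ValueError("crop-box half-extents must be positive")

    def clipped(self) -> Tuple[float, float, float, float]:
        """(x0, y0, x1, y1) clipped to the unit image."""
        return (
            max(0.0, self.cx - self.half_w),
            max(0.0, self.cy - self.half_h),
            min(1.0, self.cx + self.half_w),
            min(1.0, self.cy + self.half_h),
        )

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.clipped()
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass
class SignalSet:
    """The 99 per-trial motion signals (33 keypoints x {x, y, z})."""

    signals: List[MotionSignal]
    fs: float

    def __post_init__(self) -> None:
        if len(self.signals) != lm.N_LANDMARKS * len(lm.AXES):
            raise ValueError(
                f"a SignalSet must hold exactly {lm.N_LANDMARKS * len(lm.AXES)} signals"
            )
        lengths = {len(s) for s in self.signals}
        if len(lengths) > 1:
            raise ValueError("all signals must have equal length")

    def get(self, keypoint: int, axis: str) -> MotionSignal:
        return self.signals[keypoint * len(lm.AXES) + lm.AXES.index(axis)]


# ---------------------------------------------------------------------------
# File formats


def write_keypoints(seq: PoseSequence, path, dialect: Optional[str] = None) -> None:
    """Write a sequence as keypoint JSONL or CSV (inferred from suffix)."""
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "jsonl"
    if dialect == "jsonl":
        with open(path, "w") as fh:
            fh.write(json.dumps({"fps": seq.fps, "meta": seq.meta}) + "\n")
            for f in seq.frames:
                rec = {
                    "index": f.index,
                    "t": f.t,
                    "landmarks": [[float(v) for v in row] for row in f.landmarks],
                }
                fh.write(json.dumps(rec) + "\n")
    elif dialect == "csv":
        cols = ["index", "t"] + [
            f"k{i}_{a}" for i in range(lm.N_LANDMARKS) for a in ("x", "y", "z", "v")
        ]
        with open(path, "w") as fh:
            fh.write(f"# fps={seq.fps}\n")
            if seq.meta:
                fh.write(f"# meta={json.dumps(seq.meta, sort_keys=True)}\n")
            fh.write(",".join(cols) + "\n")
            for f in seq.frames:
                vals = [str(f.index), repr(float(f.t))]
                vals += [repr(float(v)) for v in f.landmarks.ravel()]
                fh.write(",".join(vals) + "\n")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_keypoints(path, dialect: Optional[str] = None) -> PoseSequence:
    """Read a keypoint file into a validated :class:`PoseSequence`.

    JSONL: a header line ``{"fps": .., "meta": {..}}`` followed by one
    frame per line.  CSV: a ``# fps=..`` comment header then columns
    ``index, t, k{i}_{x|y|z|v}``.  Frames with other than 33 landmarks
    are rejected with a :class:`KeypointParseError` naming the line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "jsonl"

    if dialect == "jsonl":
        frames: List[KeypointFrame] = []
        fps = None
        meta: dict = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    rec = json.loads(line)
                except json.JSONDecodeError as e:
                    raise KeypointParseError(f"{path}:{lineno}: invalid JSON ({e})")
                if "fps" in rec and "landmarks" not in rec:
                    fps = float(rec["fps"])
                    meta = rec.get("meta", {})
                    continue
                pts = rec.get("landmarks")
                if pts is None or len(pts) != lm.N_LANDMARKS:
                    raise KeypointParseError(
                        f"{path}:{lineno}: frame must have {lm.N_LANDMARKS} landmarks, "
                        f"got {0 if pts is None else len(pts)}"
                    )
                try:
                    frames.append(
                        KeypointFrame(np.array(pts, dtype=float), float(rec["t"]),
                                      int(rec.get("index", len(frames))))
                    )
                except (ValueError, KeyError, TypeError) as e:
                    raise KeypointParseError(f"{path}:{lineno}: {e}")
        if fps is None:
            raise KeypointParseError(f"{path}: missing fps header line")
        return PoseSequence.from_frames(frames, fps, meta)

    if dialect == "csv":
        import pandas as pd

        fps = None
        meta = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if body.startswith("fps="):
                    fps = float(body[4:])
                elif body.startswith("meta="):
                    meta = json.loads(body[5:])
        if fps is None:
            raise KeypointParseError(f"{path}: missing '# fps=' header")
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        expected = ["index", "t"] + [
            f"k{i}_{a}" for i in range(lm.N_LANDMARKS) for a in ("x", "y", "z", "v")
        ]
        if list(df.columns) != expected:
            raise KeypointParseError(f"{path}: unexpected column layout")
        data = df[expected[2:]].to_numpy(dtype=float).reshape(-1, lm.N_LANDMARKS, 4)
        return PoseSequence(data, df["t"].to_numpy(dtype=float), fps, meta)

    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Body-centering geometry


def body_center(frame: KeypointFrame, vis_min: float = 0.5) -> Tuple[float, float]:
    """Body center: the (x, y) midpoint between the two hips."""
    lh, rh = frame.landmarks[lm.LEFT_HIP], frame.landmarks[lm.RIGHT_HIP]
    if lh[3] < vis_min or rh[3] < vis_min:
        raise BodyNotDetectedError("body not detected: hip landmarks not visible")
    mid = (lh[:2] + rh[:2]) / 2.0
    return float(mid[0]), float(mid[1])


def reference_distance(frame: KeypointFrame, vis_min: float = 0.5) -> float:
    """Per-subject reference distance (RDS).

    The mean of the two arms' shoulder-to-index-finger Euclidean
    distances, in normalized (x, y) units; sizes the crop box
    independently of the subject's distance from the camera.
    """
    pairs = (
        (lm.LEFT_SHOULDER, lm.LEFT_INDEX),
        (lm.RIGHT_SHOULDER, lm.RIGHT_INDEX),
    )
    dists = []
    for s, i in pairs:
        if frame.visibility(s) < vis_min or frame.visibility(i) < vis_min:
            raise CalibrationError("calibration failed: arm landmarks not visible")
        dists.append(float(np.linalg.norm(frame.xy(s) - frame.xy(i))))
    return float(np.mean(dists))


def full_body_visible(
    frame: KeypointFrame,
    vis_min: float = 0.5,
    essential: Tuple[int, ...] = lm.ESSENTIAL_LANDMARKS,
) -> bool:
    """True iff every essential landmark is visible and inside the image."""
    for i in essential:
        x, y, _, v = frame.landmarks[i]
        if v < vis_min or not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
            return False
    return True


def compute_crop_box(
    seq: PoseSequence,
    calib_window: float = 1.0,
    scale: float = 2.0,
    vis_min: float = 0.5,
) -> CropBox:
    """Personalized body-centered crop box from a calibration window.

    Over the frames of the first ``calib_window`` seconds in which the
    full body is visible, the box center is the median body center and
    the half-extents are ``scale`` times the median RDS (square box;
    clipping to the unit image happens on application).  Raises
    :class:`CalibrationError` when no frame qualifies — the caller
    should prompt the user to step back until fully visible.
    """
    if seq.n_frames == 0:
        raise CalibrationError("step back until fully visible: empty sequence")
    t0 = float(seq.t[0])
    centers, rds = [], []
    for f in seq.frames:
        if f.t - t0 > calib_window:
            break
        if not full_body_visible(f, vis_min):
            continue
        try:
            centers.append(body_center(f, vis_min))
            rds.append(reference_distance(f, vis_min))
        except (BodyNotDetectedError, CalibrationError):
            continue
    if not centers:
        raise CalibrationError("step back until fully visible: no calibration frame")
    cx, cy = np.median(np.asarray(centers), axis=0)
    half = scale * float(np.median(rds))
    return CropBox(float(cx), float(cy), half, half)


def extract_signals(seq: PoseSequence) -> SignalSet:
    """Unstack a pose sequence into its 99 per-axis motion signals."""
    if seq.n_frames == 0:
        raise ValueError("cannot extract signals from an empty sequence")
    signals = [
        MotionSignal(seq.data[:, k, a], seq.fps, (k, lm.AXES[a]))
        for k in range(lm.N_LANDMARKS)
        for a in range(len(lm.AXES))
    ]
    return SignalSet(signals, seq.fps)
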