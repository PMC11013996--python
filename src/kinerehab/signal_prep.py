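"""Motion time-series preprocessing.

The raw material is one keypoint-coordinate trace per landmark axis,
sampled at the camera frame rate.  This module turns such traces into
exercise structure:

* activity/pause detection driven by an amplitude threshold,
* singular spectrum analysis (SSA) detrending for hand-held-camera
  drift,
* centered moving-average smoothing,
* period estimation by autocorrelation, and
* period-based segmentation of a bout into single repetitions, the
  unit on which all downstream kinematics and classification operate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy import signal as sps

__all__ = [
    "MotionSignal",
    "ActivitySegment",
    "SSADecomposition",
    "RepetitionSegment",
    "AperiodicSignalError",
    "amplitude_modulation",
    "detect_activity",
    "ssa_decompose",
    "detrend",
    "moving_average",
    "estimate_period",
    "segment_repetitions",
]

Label = Tuple[Union[int, str], str]


class AperiodicSignalError(ValueError):
    """Raised when no repetition period can be found in a signal."""


@dataclass
class MotionSignal:
    """One keypoint-coordinate time series.

    Parameters
    ----------
    values : array of float
        Sample values (normalized image units for keypoint traces).
    fs : float
        Sampling rate in Hz (camera frame rate).
    label : (keypoint, axis)
        Identifies the source trace, e.g. ``(23, "x")`` for the left
        hip abscissa or ``("torso", "y")`` for a derived signal.
    """

    values: np.ndarray
    fs: float
    label: Label = ("", "")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.values.ndim != 1:
            raise ValueError("MotionSignal values must be one-dimensional")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise ValueError("MotionSignal values must be finite")

    def __len__(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        return self.values.size / self.fs


@dataclass(frozen=True)
class ActivitySegment:
    """Half-open sample range [start, end) labelled active or pause."""

    start: int
    end: int
    kind: str  # "active" | "pause"

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("segment start must precede end")
        if self.kind not in ("active", "pause"):
            raise ValueError(f"unknown segment kind {self.kind!r}")

    def duration(self, fs: float) -> float:
        return (self.end - self.start) / fs


@dataclass(frozen=True)
class RepetitionSegment:
    """One exercise repetition as a half-open sample range."""

    start: int
    end: int
    duration: float  # seconds, == (end - start) / fs

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("repetition start must precede end")
        if self.duration <= 0:
            raise ValueError("repetition duration must be positive")


@dataclass
class SSADecomposition:
    """Result of singular spectrum analysis of one signal.

    ``components`` are ordered by decreasing singular value and sum to
    the input exactly (any energy beyond the leading elementary series
    is folded into the last component).  ``trend``, ``periodic`` and
    ``noise`` are grouped reconstructions that also sum to the input.
    """

    components: List[np.ndarray]
    trend: np.ndarray
    periodic: np.ndarray
    noise: np.ndarray
    window: int
    groups: dict = field(default_factory=dict)


def amplitude_modulation(sig: MotionSignal, eps: float = 1e-3) -> np.ndarray:
    """Percentage amplitude modulation between consecutive samples.

    ``m[i] = 100 * |x[i+1] - x[i]| / max(|x[i]|, eps)``; the ``eps``
    floor (default 1e-3 normalized units) guards against blow-ups when
    the reference sample is near zero.
    """
    x = sig.values
    if x.size < 2:
        raise ValueError("amplitude modulation needs at least two samples")
    denom = np.maximum(np.abs(x[:-1]), eps)
    return 100.0 * np.abs(np.diff(x)) / denom


def moving_average(sig: MotionSignal, M: int) -> MotionSignal:
    """Centered moving average with half-window of M samples.

    ``x̄[i]`` is the mean of ``x[i-M .. i+M]``; at the boundaries the
    window shrinks to the available samples, so the output has the same
    length as the input and no padding bias.  Computed as a per-sample
    mean (not a convolution) so it matches a windowed-mean oracle to
    the last bit.
    """
    if M < 0:
        raise ValueError("half-window M must be >= 0")
    x = sig.values
    if M == 0 or x.size == 0:
        return MotionSignal(x.copy(), sig.fs, sig.label)
    n = x.size
    out = np.empty(n, dtype=float)
    for i in range(n):
        lo = max(0, i - M)
        hi = min(n, i + M + 1)
        out[i] = np.mean(x[lo:hi])
    return MotionSignal(out, sig.fs, sig.label)


def _runs(mask: np.ndarray) -> List[Tuple[int, int, bool]]:
    """Consecutive runs of a boolean mask as (start, end, value)."""
    runs: List[Tuple[int, int, bool]] = []
    n = mask.size
    start = 0
    for i in range(1, n + 1):
        if i == n or mask[i] != mask[start]:
            runs.append((start, i, bool(mask[start])))
            start = i
    return runs


def detect_activity(
    sig: MotionSignal,
    threshold_pct: float = 30.0,
    min_active_s: float = 0.5,
    min_pause_s: float = 2.0,
    window_s: float = 0.5,
    smooth_s: float = 0.15,
    min_motion: float = 0.02,
) -> List[ActivitySegment]:
    """Partition a signal into active (exercise) and pause segments.

    A sample counts as active when the local amplitude modulation — the
    peak-to-peak displacement of the smoothed signal inside a sliding
    window of ``window_s`` seconds — exceeds ``threshold_pct`` percent
    of the signal's robust global amplitude (its 2.5–97.5 percentile
    range, floored at ``min_motion`` normalized units so that a signal
    that never really moves is all pause).  Runs shorter than
    ``min_active_s`` / ``min_pause_s`` are merged into their
    neighbours, so brief dwell at a movement extremum does not split a
    bout and jitter does not create phantom activity.

    Returns an ordered, disjoint partition of ``[0, n)``.
    """
    n = len(sig)
    if n < 2:
        raise ValueError("activity detection needs at least two samples")
    fs = sig.fs
    smooth = moving_average(sig, max(1, round(smooth_s * fs))).values
    win = max(2, round(window_s * fs)) | 1  # odd, centered
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    p2p = maximum_filter1d(smooth, win, mode="nearest") - minimum_filter1d(
        smooth, win, mode="nearest"
    )
    lo, hi = np.percentile(smooth, [2.5, 97.5])
    ref = max(hi - lo, min_motion)
    mask = 100.0 * p2p / ref > threshold_pct

    # Debounce: repeatedly absorb the shortest undersized run into its
    # neighbours until every run meets its minimum duration.
    min_len = {True: max(1, round(min_active_s * fs)),
               False: max(1, round(min_pause_s * fs))}
    while True:
        runs = _runs(mask)
        if len(runs) <= 1:
            break
        short = [r for r in runs if (r[1] - r[0]) < min_len[r[2]]]
        if not short:
            break
        s = min(short, key=lambda r: r[1] - r[0])
        mask[s[0]:s[1]] = not s[2]

    return [
        ActivitySegment(a, b, "active" if v else "pause")
        for a, b, v in _runs(mask)
    ]


def _low_frequency_share(x: np.ndarray, fs: float, f_cut: float) -> float:
    """Fraction of a component's spectral energy below f_cut.

    More robust than the argmax frequency for broadband trend-corrective
    components (zero-padded so the resolution exceeds the bin spacing
    fs/n of short signals)."""
    nfft = max(1024, 4 * x.size)
    p = np.abs(np.fft.rfft(x, n=nfft)) ** 2
    total = p.sum()
    if total <= 0:
        return 1.0
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return float(p[freqs < f_cut].sum() / total)


def ssa_decompose(
    sig: MotionSignal,
    L: Optional[int] = None,
    n_components: int = 12,
    f_trend_hz: float = 0.1,
    e_noise: float = 0.01,
    expected_period_s: float = 2.0,
) -> SSADecomposition:
    """Singular spectrum analysis of a signal into 12 summable components.

    The signal is embedded into an ``L x K`` trajectory matrix
    (``K = n - L + 1``), decomposed by SVD, and the leading
    ``n_components - 1`` rank-one terms are reconstructed into
    elementary series by diagonal averaging; all residual energy is
    folded into the last component so the set sums to the input
    exactly.  Components are then grouped into three series:

    * **trend** — components carrying the majority of their spectral
      energy below ``f_trend_hz`` (slow camera drift, posture shifts),
    * **noise** — non-trend components carrying less than ``e_noise``
      of the total component energy,
    * **periodic** — everything else (the exercise oscillation).

    The default window is ``min(n // 2, 2 * fs * expected_period_s)``
    so that drift and exercise periodicity separate.
    """
    x = sig.values
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValueError("SSA requires finite values")
    if L is None:
        L = int(min(n // 2, round(2 * sig.fs * expected_period_s)))
        L = max(L, 2)
    if L < 2:
        raise ValueError("SSA window L must be >= 2")
    if n <= L:
        raise ValueError(f"signal length {n} must exceed window L={L}")
    if n_components < 2:
        raise ValueError("need at least two components")
    if n_components > L:
        raise ValueError("n_components must not exceed the window L")

    K = n - L + 1
    # Trajectory (Hankel) matrix: column j is x[j : j + L].
    idx = np.arange(L)[:, None] + np.arange(K)[None, :]
    X = x[idx]
    U, s, Vt = np.linalg.svd(X, full_matrices=False)

    def diagonal_average(M: np.ndarray) -> np.ndarray:
        out = np.zeros(n)
        counts = np.zeros(n)
        rows = np.arange(L)[:, None] + np.arange(K)[None, :]
        np.add.at(out, rows.ravel(), M.ravel())
        np.add.at(counts, rows.ravel(), 1.0)
        return out / counts

    m = min(n_components - 1, s.size)
    components: List[np.ndarray] = []
    for i in range(m):
        components.append(diagonal_average(s[i] * np.outer(U[:, i], Vt[i])))
    while len(components) < n_components - 1:
        components.append(np.zeros(n))
    # Residual fold: the last component carries whatever the leading
    # elementary series missed, making summability exact.
    components.append(x - np.sum(components, axis=0))

    energies = np.array([float(np.sum(c**2)) for c in components])
    total = energies.sum()
    trend_idx, periodic_idx, noise_idx = [], [], []
    for i, c in enumerate(components):
        share = _low_frequency_share(c, sig.fs, f_trend_hz)
        frac = energies[i] / total if total > 0 else 0.0
        # Majority-slow components are trend; minor components that still
        # lean slow are trend correctives (e.g. the second eigentriple of
        # a pure ramp), not noise — broadband flat spectra score ~f/fs.
        if share >= 0.5 or (frac < e_noise and share >= 0.2):
            trend_idx.append(i)
        elif frac < e_noise:
            noise_idx.append(i)
        else:
            periodic_idx.append(i)

    def group(ixs: Sequence[int]) -> np.ndarray:
        if not ixs:
            return np.zeros(n)
        return np.sum([components[i] for i in ixs], axis=0)

    return SSADecomposition(
        components=components,
        trend=group(trend_idx),
        periodic=group(periodic_idx),
        noise=group(noise_idx),
        window=L,
        groups={"trend": trend_idx, "periodic": periodic_idx, "noise": noise_idx},
    )


def detrend(sig: MotionSignal, ssa: Optional[SSADecomposition] = None) -> MotionSignal:
    """Subtract the SSA trend from a signal.

    Removes slow common-mode drift such as hand-held-camera wander; only
    needed when the recording device is not fixed.
    """
    if ssa is None:
        ssa = ssa_decompose(sig)
    if ssa.trend.size != sig.values.size:
        raise ValueError("SSA decomposition does not match the signal length")
    return MotionSignal(sig.values - ssa.trend, sig.fs, sig.label)


def estimate_period(
    sig: MotionSignal,
    min_s: float = 0.5,
    max_s: float = 10.0,
    prominence: float = 0.3,
) -> float:
    """Repetition period of a quasi-periodic signal, in seconds.

    The lag of the first autocorrelation peak whose prominence exceeds
    ``prominence`` (relative to the zero-lag value), searched between
    ``min_s`` and ``max_s``.  The signal should span at least two full
    movement cycles.  Raises :class:`AperiodicSignalError` when no such
    peak exists (e.g. noise or a static pose).
    """
    x = sig.values - np.mean(sig.values)
    n = x.size
    if n < 4:
        raise AperiodicSignalError("signal too short for period estimation")
    acf = np.correlate(x, x, mode="full")[n - 1:]
    if acf[0] <= 0:
        raise AperiodicSignalError("no phase information in a constant signal")
    acf = acf / acf[0]
    lo = max(2, int(round(min_s * sig.fs)))
    hi = min(n - 2, int(round(max_s * sig.fs)))
    if hi <= lo:
        raise AperiodicSignalError("signal shorter than the minimum period")
    peaks, _ = sps.find_peaks(acf[: hi + 1], prominence=prominence)
    peaks = peaks[peaks >= lo]
    if peaks.size == 0:
        raise AperiodicSignalError("aperiodic signal: no autocorrelation peak")
    return float(peaks[0] / sig.fs)


def segment_repetitions(
    sig: MotionSignal,
    period: float,
    smooth_s: float = 0.15,
    tol: float = 0.3,
    min_excursion_frac: float = 0.3,
) -> List[RepetitionSegment]:
    """Split an active movement bout into single repetitions.

    Boundaries are placed where the smoothed signal returns closest to
    its rest value (the bout-start level) in a ``±tol * period``
    neighbourhood of each successive period multiple — every exercise
    in the repertoire starts and ends a repetition at the rest posture,
    so rest proximity marks cycle boundaries regardless of the trace's
    sign or orientation.  Segments whose peak excursion is below
    ``min_excursion_frac`` of the bout maximum (flat tails) are
    dropped.  Returns an empty list when the period exceeds the signal.
    """
    if period <= 0:
        raise ValueError("period must be positive")
    n = len(sig)
    p = int(round(period * sig.fs))
    if p < 2 or p > n:
        return []
    smooth = moving_average(sig, max(1, round(smooth_s * sig.fs))).values
    # The bout is assumed to begin at rest; a tight baseline window keeps
    # the slow initial rise of the movement out of the rest estimate.
    baseline = np.median(smooth[:3])
    d = np.abs(smooth - baseline)

    bounds = [0]
    while True:
        lo = bounds[-1] + int(round((1 - tol) * p))
        hi = min(bounds[-1] + int(round((1 + tol) * p)) + 1, n)
        if hi - lo < 2 or lo >= n:
            break
        j = lo + int(np.argmin(d[lo:hi]))
        bounds.append(j)
        if n - j < int(round((1 - tol) * p)):
            break

    dmax = float(d.max()) if n else 0.0
    reps = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if dmax > 0 and float(d[a:b].max()) < min_excursion_frac * dmax:
            continue
        reps.append(RepetitionSegment(a, b, (b - a) / sig.fs))
    return reps
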