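# Methods

This note documents the models and procedures implemented in
`kinerehab`, their assumptions, the tunable parameters and the design
choices made where several readings were defensible.

## Setting and coordinate conventions

The input is the output contract of a monocular full-body pose
estimator: per frame, 33 landmarks in BlazePose index order, each with
normalized image coordinates (x right, y **down**, origin top-left),
a relative depth z on the same scale as x (smaller = closer to the
camera), and a visibility score in [0, 1].  The camera is frontal, at
a few meters' distance, nominally fixed; frame rates of 29–30 fps are
assumed throughout the defaults.

Monocular depth is the least reliable channel.  All frontal-plane
measures (hip and shoulder abduction, trunk-rotation magnitude,
activity detection, segmentation) therefore use x/y only; depth is
consulted exactly where stated below (rotation sign; sagittal flexion
triplets on synthetic data).

## Body-centering geometry

The body center is the hip midpoint; the per-subject reference
distance (RDS) is the mean of the two shoulder-to-index-finger
Euclidean distances in (x, y).  The crop box is square, centered on the
median body center over a 1 s calibration window, with half-extent
`scale × median RDS`; `scale` defaults to 2.0 (box side = 4 RDS), which
comfortably contains a standing adult with raised arms.  The box is
clipped to the unit image on application.  A session computes one box
after full-body detection rather than one per frame: the calibration
median is robust to jitter and a stable box avoids oscillating zoom.

## Activity detection

The aim is an amplitude criterion: a segment is active when the signal
moves by more than 30 % of its own movement amplitude.  We implement it
as a windowed measure: a sample is active when the peak-to-peak
displacement of the smoothed signal within a centered 0.5 s window
exceeds 30 % of the signal's robust global amplitude (2.5–97.5
percentile range, floored at 0.02 normalized units so that a signal
that never really moves is all pause).  Runs shorter than 0.5 s
(active) / 2.0 s (pause) are merged into their neighbours.

A per-sample relative difference `100·|Δx|/|x|` was considered and
rejected: it is scale-free, so it exceeds any fixed threshold only near
zero crossings of the centered signal (~15 % of moving samples at
30 fps) while pause jitter around a near-zero baseline exceeds it
almost always — the detector would invert.  The windowed peak-to-peak
form keeps the 30 % threshold meaningful at any movement amplitude.

The minimum pause of 2.0 s reflects a physical fact exploited
throughout: raised-cosine-like movements dwell quadratically (their
foreshortening projections quartically) at the rest posture, so
sub-second "quiet" intervals recur at every repetition boundary and
must not split a bout, while genuine rest breaks last seconds.  At the
pipeline level, residual fragments separated by less than 0.75 of the
estimated period are re-merged — a pause shorter than one repetition
cannot be a rest break.

## SSA detrending

Hand-held recording adds a common-mode random-walk drift to all
landmarks.  Singular spectrum analysis embeds each signal into an
`L × (n−L+1)` trajectory matrix (default `L = min(n/2, 2·fs·2 s)`, so
drift and exercise periodicity separate), takes the SVD, and
reconstructs the leading 11 rank-one terms by diagonal averaging; all
residual energy is folded into a 12th component so the set sums to the
input exactly (tested to 1e-8 relative).  Components are grouped into:

* **trend** — majority of spectral energy below 0.1 Hz; minor
  components (< 1 % energy) that still lean slow (≥ 20 % below the
  cutoff) join the trend as correctives — the second eigentriple of a
  pure ramp is of this kind, and leaving it out visibly bends the
  extracted trend;
* **noise** — remaining components below 1 % of total energy;
* **periodic** — the rest.

Detrending subtracts the trend.  It is applied only when the camera is
declared non-fixed (`camera_fixed: false`), mirroring the intended use.
w-correlation grouping is a known alternative; the spectral rule was
chosen for determinism and speed.

## Period estimation and repetition segmentation

The repetition period is the lag of the first autocorrelation peak
with prominence ≥ 0.3 (relative to the zero-lag value), searched
between 0.5 s and 10 s; at least two full cycles are required, and
failure raises an "aperiodic signal" error.  The prominence floor was
set so that white-noise autocorrelation excursions (≈ n^{-1/2}) do not
qualify while genuine two-cycle bouts (peak ≈ 0.5) do.

Segmentation anchors repetition boundaries where the smoothed signal
returns closest to its rest level (the bout-start value) within ±30 %
of each successive period multiple.  All five exercises start and end
each repetition at the rest posture, so rest proximity marks cycle
boundaries regardless of the trace's sign or orientation; flat tail
segments (< 30 % of the bout's maximal excursion) are dropped.  The
driving signal is the maximal-variance x/y trace among the five basic
keypoints (z is excluded as unreliable).

## Kinematic measures

Joint angles use the cosine formula on a landmark triplet in a chosen
plane (`xy` default; `xyz` where depth is explicitly trusted).  Frames
in which any triplet landmark falls below 0.5 visibility are linearly
interpolated; above 10 % missing the series is rejected as unreliable.

Per-exercise ROM measures:

| exercise | measure | triplet / formula | plane | per-rep statistic |
|---|---|---|---|---|
| SS | hip abduction (L/R) | shoulder–hip–knee | xy | peak-to-peak |
| SA | shoulder abduction (L/R) | hip–shoulder–elbow | xy | peak-to-peak |
| TR | lumbar rotation | arccos(width/W), sign from shoulder depth | — | peak magnitude |
| FB | spinal flexion | shoulder–hip–knee | xyz | peak-to-peak |
| SQT | hip / knee flexion | shoulder–hip–knee / hip–knee–ankle | xyz | max(180° − θ) |

Conventions worth stating:

* **Peak-to-peak excursion** is used instead of "deviation from the
  segment-start angle": boundary samples can land a few frames into
  the movement, where the start angle is already several degrees off
  rest; within-repetition extremes are robust to that and identical
  for rest-anchored cycles.
* **Pre-angle smoothing.** Landmark traces are moving-average smoothed
  before the angle transform (window 5 % of the repetition duration,
  clamped to 0.07–0.2 s).  Near 0°/180° the triplet angle folds
  coordinate jitter into a one-sided bias that post-hoc angle smoothing
  cannot remove.  The moving average attenuates the movement's
  fundamental by a known Dirichlet-kernel gain α; the per-repetition
  extrema are compensated (peak-to-peak ÷ α; rest-referenced maxima
  × 2/(1+α)), so ROM is unbiased across repetition speeds.  Measured on
  the generator at its default jitter (σ = 0.003), recovery over a
  20–90° × 2–4 s grid is within 2° in every seeded trial, and within
  2° on average (occasional single trials to ~2.7°) at σ = 0.005.
* **Trunk rotation** smooths the apparent-width signal before the
  arccos (infinite slope at zero rotation) and reports the per-rep
  peak magnitude, which is zero-referenced by the width calibration.

Angular velocity is ω = ROM (rad) / median repetition duration.
Coordination between N series is the antisymmetric matrix of
cross-correlation peak lags of the mean-centered signals (search
restricted to ±half a period when one is known), an onset order, and a
"unified" verdict when all pairwise |lags| fall below a threshold
(default 0.15 × period).

## Guideline (execution-error) checks

Per repetition, with a tolerance fraction clamped to the 10–20 % band
(default 0.15):

* **SA** — minimum elbow angle ≥ 180°(1−tol), else "Keep the arms
  straight!".
* **FB** — minimum knee angle ≥ 180°(1−tol), else "Keep the legs
  straight".
* **TR** — arm-to-trunk angle within tol of 90°, else "Keep arms
  vertical to the body axis"; and a bout-level coordination check:
  trunk participation read from the apparent shoulder width, arm
  participation from the apparent wrist spread (two magnitude signals
  that co-vary under rotation — raw per-wrist abscissae of the two
  arms are anti-correlated and would alias the lag by half a period).
  Lags below an absolute 0.15 s mean the body rotates as one block:
  "Rotate the trunk, not the whole body as one unit".  The check needs
  at least two cycles and is skipped on shorter windows.
* **SQT** — frontal-plane knees-behind-toes approximation: the knee's
  horizontal outward excursion past the foot tip must not exceed
  tol × foot length (3-D heel-to-toe distance).  With no sagittal
  camera this is an approximation and is labelled as such.
* Upright-spine checks for SS/SA/TR are deliberately skipped: from a
  frontal camera they would live in the unreliable depth plane.

Sequences are smoothed (0.07 s) before checking so the rules judge the
movement, not the jitter.  Severity is the relative deviation that
triggered the rule.

## Feature extraction and classification

Basic keypoints default to the virtual mid-hip point (torso), the
wrists (arms) and the ankles (legs) — distal points carry the most
motion signal.  Per repetition and per signal: 12 time-domain features
(mean, max, min, RMS, variance, SD, crest factor = max|x|/RMS,
kurtosis, skewness, median, peak-to-peak, energy = Σx²) and 7 spectral
features of the Hann-windowed, mean-removed periodogram over
[0, fs/2] (mean, max, total, SD, peak frequency, kurtosis, skewness of
the band power).  19 × 15 signals = 285 features in a fixed order.
Constant signals take the conventions crest = 1, skew = kurt = 0.

Features are z-scored (they mix heterogeneous scales) before PCA,
which retains the smallest leading component set with ≥ 90 % cumulative
explained variance — retained dimensionality is data-dependent by
design rather than hard-coded.  Classifiers: random forest (100
trees), SVM with linear / cubic-polynomial / RBF kernels (C = 1, RBF
γ = scale), and a decision tree as the overfit-prone baseline; all
seeded.  Evaluation uses a subject-wise split (greedy seeded draw of
test subjects until the test repetition count is nearest the 30 %
target; a leakage assertion sits in the evaluation path itself) plus
stratified 10-fold cross-validation on the training set.  Reported
test metrics: accuracy, macro F1 / precision / sensitivity /
specificity, per-class accuracy, the confusion matrix, and training /
inference wall time.

## Session engine

A deterministic state machine over the modes WAIT_FULL_BODY →
CALIBRATING → IDLE → RECOGNIZING → TRACKING, with pauses returning to
IDLE and sustained body loss (1 s) returning to WAIT_FULL_BODY from
any post-calibration mode.  Defaults: step-back prompt every 3 s,
motivation every 5 s of idleness, pause timeout 3 s, recognition
fallback window 4 s, exercise change after 2 consecutive disagreeing
repetition votes.

Live motion is monitored on ten smoothed x/y traces (5 basic keypoints)
over a 0.8 s window against the 0.02 minimum-motion floor.  Repetition
detection tracks the RMS deviation of the strongest co-moving traces
from their rest baselines — a combined excursion that returns to zero
only at the rest posture, so one non-monotone trace (a bent-arm wrist
abscissa, say) cannot fake a cycle boundary — with hysteresis (enter at
45 % of the running amplitude, exit at 18 %).  Recognition fires on the
first *completed* repetition and classifies exactly that segment, so
its latency is one execution period and live windows match the
training distribution; repetitions completed since the bout began are
credited to the counter.  Corrections are re-evaluated on every
completed repetition: they repeat while the violation holds and stop
with the first clean repetition.  Counting increments at repetition
completion (not at the peak).

Everything is driven by frame timestamps, so a replayed sequence gives
a byte-identical session log.

## Synthetic motion generator

The generator renders a planar kinematic chain rooted at the pelvis
into BlazePose-style frames.  Joint drives are raised cosines
θ(t) = ROM·(1−cos 2πt/T)/2 — C¹-smooth, rest-anchored at both ends of
every repetition, which gives segmentation unambiguous anchors.  Class
templates (ROM, period): SS 40°/2 s, SA 150°/3 s, TR 45°/3 s,
FB 100°/3.5 s, SQT 85°/3 s — amplitudes near the corresponding
normative or reported ranges at self-selected repetition speeds.
Defaults for noise (σ = 0.003 normalized units i.i.d. per coordinate)
approximate pose-estimator jitter; camera drift is a common-mode
random walk (the exact artifact SSA detrending removes); per-subject
variation draws skeleton proportions (±4 %), ROM (±10 %) and period
(±15 %) around the templates.  The default benchmark corpus is 20
subjects × 5 exercises × 6 repetitions (600 ground-truth repetitions)
at 29 fps.

Deliberate stylizations, and what they imply about the tests:

* Hip width equals shoulder width, so each hip sits directly below the
  same-side shoulder and frontal triplets recover driven angles
  exactly; clean-signal recovery tests are exact by construction and
  say nothing about anthropometric variation beyond the jittered
  proportions.
* Side steps are simultaneous bilateral hip ab/adduction.  Alternating
  single-leg steps would give every individual keypoint trace a period
  of two repetitions, breaking the period = repetition-duration
  identity the segmentation relies on.
* Sagittal movement (forward-bend lean, squat knee travel) is rendered
  in the depth channel and measured with xyz triplets; real monocular
  depth is far noisier than the synthetic one, so those measures are
  validated only up to the generator's idealization.
* Squats keep the trunk vertical over a symmetric two-link leg, making
  hip flexion exactly half the knee flexion; the separate 95°/85°
  norms cannot both be matched by this geometry (the knee is driven).
* Trunk rotation alternates direction per repetition; the arms trail
  the trunk by 0.4 s in correct execution, and the
  `unified_trunk_rotation` error removes that lag.  Injected errors
  develop with the movement (full bend at peak, none at rest) so
  posture stays continuous across phases.
* Idle and pause frames adopt the rest stance of the adjacent exercise
  (arms extended around TR), again for continuity; scripts mixing TR
  with other exercises will still show one stance change at the TR
  bout's far end.
* Bone lengths are conserved to 1e-9 in clean output (tested); the
  generator does not model soft-tissue or perspective effects, and
  landmark "visibility" is binary-ish (1.0, or 0.2 when a body part is
  shifted out of frame by the `partial_body` error).

Passing the pipeline tests on this generator demonstrates internal
consistency — each stage recovers what the generator put in, at
realistic jitter — not clinical validity on real recordings.

## Numerical choices and degenerate inputs

* Cosine-formula angles clamp the cosine to [−1, 1]; coincident points
  (norm < 1e-9) raise.  The arccos form is ill-conditioned within
  ~0.01° of collinearity; oracle comparisons at 1e-9° exclude that
  sliver.
* `moving_average` is computed as a literal per-sample mean (not a
  convolution) so it matches a windowed-mean oracle bit-for-bit;
  boundary windows shrink.
* SSA summability is exact by residual folding; tolerance in tests is
  1e-8 relative.
* Amplitude modulation floors its denominator at 1e-3 normalized
  units.
* Seeds: every stochastic element (generator, subject draws, splits,
  classifiers, permutation controls) takes an explicit seed; derived
  seeds stay below 2³¹.

## Scaled problem sizes

Test and acceptance runs use desk-scale sizes chosen as package
defaults: the 20-subject benchmark corpus above, 12-cell ROM grids with
one seeded trial per cell (20 per cell in the development
characterization), 108 period-recovery trials, 15 seeded sessions for
repetition-count fidelity and 20 × 200-frame streams for state-machine
fuzzing.  The full acceptance script completes in about a minute on one
CPU.

## Known limitations

* All validation is synthetic; real pose-estimator noise is
  heteroscedastic, autocorrelated and occlusion-prone in ways the
  i.i.d. Gaussian model does not capture.
* The knees-behind-toes and lumbar-rotation geometries are
  frontal-plane approximations, flagged as such in reports.
* The session engine assumes one person in frame and does not handle
  camera cuts; multi-person tracking and rendering overlays are out of
  scope.
* Live video capture is an adapter concern: any callable mapping an
  RGB frame to a keypoint frame can drive the engine, but no such
  adapter ships with the package.
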