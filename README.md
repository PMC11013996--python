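# kinerehab

Kinematic assessment, exercise recognition and real-time corrective
feedback from body-keypoint video traces.

Tele-exercise systems let patients and older adults train at home in
front of an ordinary camera while a monocular pose estimator (BlazePose
topology: 33 landmarks per frame, normalized `(x, y, z, visibility)`)
streams their body keypoints.  `kinerehab` is the analysis layer of
such a system for a five-exercise rehabilitation repertoire — side
steps (SS), shoulder abductions (SA), trunk rotations (TR), standing
forward bends (FB) and squats (SQT).  It is a library first: the
pose-estimation network itself is treated as an interface, and a
built-in synthetic skeleton-motion generator makes every stage testable
without video recordings.

## What it computes

**Kinematics.** Joint angles come from the cosine formula on landmark
triplets, θ = arccos((a−b)·(c−b) / |a−b||c−b|); trunk rotation from
apparent shoulder-width foreshortening, ρ = arccos(w/W).  Range of
motion (ROM) is summarized per repetition by the angle maxima and
reported as their median, compared with normative goniometer values
(AAOS: hip abduction 40°, shoulder abduction 180°, lumbar rotation 45°,
spinal flexion 100°; Hemmerich: squat hip/knee flexion 95°/85°).  Mean
angular velocity is ω = dθ/dt with dt one repetition.  Movement
coordination between N body parts is the matrix of pairwise
cross-correlation lags.

**Signal preparation.** Each trial yields 99 time series (33 keypoints
× x, y, z).  Activity and pauses are separated by a 30 % amplitude
threshold; hand-held-camera drift is removed by singular spectrum
analysis (12 summable components grouped into trend, periodicity and
noise, with the trend subtracted); smoothing is a centered moving
average x̄ᵢ = (2M+1)⁻¹ Σⱼ x[i+j]; the repetition period is the first
autocorrelation peak, and the bout is segmented into single repetitions
at its rest-return points.

**Recognition.** Each repetition of the 15 basic-keypoint signals
(torso, both wrists, both ankles × 3 axes) is described by 19 features
(12 time-domain, 7 band-power spectral), a 285-dim vector, optionally
PCA-reduced to ≥ 90 % variance, and classified by RF / linear, poly and
RBF SVM / decision tree with a subject-wise 70/30 split so the test set
holds only unseen people.

**Coaching.** A deterministic state machine consumes frames and emits
feedback: step-back prompts, automatic body-centered crop-box
calibration (from the hip midpoint and the shoulder-to-index reference
distance), inactivity motivation, exercise recognition from the first
completed repetition, repetition counting, exercise-change handling,
and per-exercise guideline corrections within a 10–20 % tolerance band
(e.g. "Keep the arms straight!" during shoulder abductions).

## Worked example

```bash
python examples/05_coaching_session.py
```

trains a linear-SVM exercise recognizer on a small synthetic corpus and
replays the scripted coaching scenario (idle → 2 side-steps → pause →
shoulder abductions with bent elbows → clean abductions):

```
t=  5.97s  [motivation ] Time to move! Start your exercise whenever you are ready
t=  7.80s  [recognition] Recognized exercise: SS
t=  7.80s  [count      ] Repetitions: 1
t=  9.80s  [count      ] Repetitions: 2
t= 15.63s  [motivation ] Time to move! Start your exercise whenever you are ready
t= 18.87s  [recognition] New exercise: SA - repetition counter restarted
t= 18.87s  [count      ] Repetitions: 1
t= 18.87s  [correction ] Keep the arms straight!
t= 21.83s  [count      ] Repetitions: 2
t= 21.83s  [correction ] Keep the arms straight!
t= 24.83s  [count      ] Repetitions: 3
t= 27.83s  [count      ] Repetitions: 4
```

The engine motivates the idle user, recognizes each exercise after one
execution period, counts the two side-steps, restarts the counter at
the exercise change, corrects the bent elbows on exactly the two faulty
repetitions, and falls silent once the arms straighten.

The other examples cover motion generation (`01`), the squat ROM report
with normative ratios (`02` — knee flexion median 84.8° against the 85°
norm, ratio 1.00), signal preprocessing incl. SSA drift removal (`03`)
and classifier training (`04` — linear SVM at 100 % held-out accuracy on
the linearly separable five-class problem).

A thin CLI wraps the same calls: `kinerehab simulate`, `kinerehab
analyze`, `kinerehab train` (see `--help`).

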