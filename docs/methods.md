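# Methods

This note documents the models implemented in `semg_motionmap`, the
synthetic data they are exercised on, the numerical choices, and the
limitations a user should know before trusting numbers produced by the
bundled benchmarks.

## Signal model and preprocessing

Surface EMG is treated as an amplitude-modulated stochastic carrier:
muscle activation scales a zero-mean band-limited Gaussian process, with
additive 50 Hz mains interference, low-frequency baseline drift and
wide-band sensor noise.  The conditioning chain is

1. 20 Hz 4th-order Butterworth high-pass (motion artifact),
2. 200 Hz 4th-order Butterworth low-pass (wide-band noise),
3. 50 Hz notch (Q = 30),

all applied forward–backward (`sosfiltfilt`) for zero phase.  Motion
artifact is low-frequency, so the artifact stage is a high-pass; a
`literal_lowpass` flag builds a second 20 Hz low-pass instead for users
who want that textual variant, but it destroys the EMG band and is not
the default.  Amplitude features are MAV (mean |x|) and RMS on sliding
windows; RMS ≥ MAV always (Cauchy–Schwarz) and both are ≥ 0.  Interval
scaling maps each channel's feature range onto [0, 1] using the training
extremes; at transform time out-of-range values clamp, since a fresh
session can exceed the fitted extremes.  The stand-alone
`moving_average` smoother is causal with left-edge hold (output length
equals input length, constants preserved); the regression pipeline
instead smooths feature frames with a *centred* boxcar so that smoothed
features stay aligned with angle truth sampled at window centres.

Default sampling rates: 200 Hz for the 8-channel armband, 1000 Hz for
the 7-channel electrode montage; both configurable.

## Hybrid gesture classifier

Input is an 8 × 200 (channel × time) window.  Because each channel is a
different electrode site, convolution and pooling act only along time;
kernels span one channel, making the conv stack exactly equivariant to
channel permutations (a tested property).  The reference stack —
conv 32 maps k=13 → pool 4 → conv 64 k=8 → pool 4 → conv 128 k=6 — maps
length 200 to 5, giving terminal maps (128, 5, 8) and a flattened
5120-vector.  The handcrafted route computes per-channel RMS plus mean
(spectral centroid) and median frequency of the magnitude spectrum, DC
excluded; an all-zero channel yields zeros.  Inside the classifier the
frequency features are divided by the Nyquist rate so all fused inputs
are O(1).  Two dense layers (width 128, ReLU, inverted dropout 0.5, then
a 4-way output) produce scores; softmax cross-entropy is minimised by
mini-batch SGD at learning rate 0.00681292 with batch 128 for 40 epochs.
All parameters, shuffling and dropout masks derive from one seed, so
training histories are bit-reproducible.  The layers are written
directly in numpy (im2col + BLAS matmuls with explicit backprop), which
keeps inference deterministic and the dependency set minimal.

Class order is fixed as (clench, relax, palm_up, palm_down); argmax ties
resolve to the lowest class index.

## Backprop angle regressor

One 8-20-1 network per degree of freedom: inputs are the 7 interval-
scaled muscle features plus motion time normalised to [0, 1) within each
repetition; the hidden layer is logistic sigmoid, the output linear in
[0, 1] and min–max mapped to the DOF's planning range.  Weights start
uniform in [−0.5, 0.5]; thresholds at zero.  The update rule is the
momentum form

    Δθ(k+1) = (1 − mc)·η·g + mc·Δθ(k),

with g the descent direction of E = 1/(2n)·Σ wᵢ(yᵢ − ŷᵢ)² (the 1/n
keeps η's scale independent of dataset size; wᵢ are optional per-sample
weights, default 1).  Between epochs η follows the three-branch schedule
on the full-pass SSE: ×1.05 on decrease, ×0.7 when SSE grows beyond 4%,
otherwise unchanged.  When the shrink branch fires, the step is kept —
only η changes.  A divergence guard aborts if SSE exceeds 10⁶ × its
initial value.  Analytic gradients are verified against central finite
differences, and the mc = 0, fixed-η configuration reproduces a plain
gradient-descent loop to 1e−10.

Two optional extensions, both off by default so the plain algorithm is
what unit tests exercise:

* **mini-batch updates** (`batch_size`): momentum memory carried across
  shuffled batches, with the η schedule still driven by full-pass SSE.
  Full-batch updates converge too slowly on the ~12k-frame benchmark
  training set to fit transition segments within a sensible epoch
  budget; the reference experiments use batch 64.
* **weight decay** (`weight_decay`): an L2 term on the weight matrices.
  Single-DOF training data underdetermine the 7-channel decode — several
  weight configurations fit the training sessions equally well but
  differ wildly on multi-joint motions.  A small penalty (3e−4 in the
  reference experiments) biases the fit away from redundant
  cross-channel weights and measurably improves combined-motion
  generalisation.

One network per DOF (rather than one multi-output net) keeps the
inactive-DOF test meaningful and matches a single-output architecture.
`predict_trajectory` clamps predictions to the planning range ± 5°; the
reference experiment additionally smooths predicted traces with a
centred 21-frame (1.05 s) boxcar, which removes frame-level jitter at
negligible lag cost since true joint motion is slow against the 50 ms
frame step.

## IMU kinematics

Quaternions are Hamilton-convention, stored (w, x, y, z), frames
right-handed.  Calibration re-expresses a sensor stream relative to the
chest-worn base and a reference pose: q(t) → conj(q_rel(t₀)) ⊗ q_rel(t)
with q_rel = conj(q_base) ⊗ q_sensor; the result is identity at t₀ and
invariant to any common world-frame rotation.  The shoulder decomposes
by intrinsic Z–X–Y Euler angles (z = flexion, x = abduction,
y = rotation), flagged within 1° of the x = ±90° singularity.  The elbow
uses the exact two-axis form R = Rx(flexion)·Ry(pronation), recovered in
closed form from the rotation matrix with no singular configuration.
Angle traces are unwrapped to avoid ±180° jumps.  The synthetic
generator composes its IMU streams with the same conventions, so
generate → decompose round trips are exact to numerical precision; no
claim is made that any specific physical IMU uses these conventions.

## Synthetic acquisition sessions

The generators emulate the acquisition protocol: each repetition is a
1 s minimum-jerk rise to the target angle, 3 s hold, 1 s return and 5 s
rest, five repetitions per session; per-DOF targets must lie in the
planning ranges (shoulder 0–90° per axis, elbow 0–120°, forearm
−30–150°).  Muscle activation follows a 7 × 5 synergy matrix: each DOF
has a dominant muscle (deltoid middle/anterior/posterior for the three
shoulder DOFs, biceps for elbow flexion, the forearm-rotator electrode
for forearm rotation), plus physiological co-activation (triceps
co-contracts with elbow flexion, trapezius supports abduction) and weak
cross-talk ≤ 0.1.  The per-DOF drive combines a phasic velocity term
α·|θ̇|/ω_ref (α = 0.8, ω_ref = 300 °/s) and a position-holding term
β·|θ|/θ_ref (β = 0.5), plus a tonic baseline of 0.02, clipped to [0, 1].
The position-proportional holding term is what makes hold-phase
amplitude decodable; a binary hold indicator would erase amplitude
information.  EMG is the envelope times a unit-RMS 20–150 Hz Gaussian
carrier plus 0.05 mains at 50 Hz, 0.05 drift below 1 Hz and 0.01 white
noise.  Gesture windows use fixed channel-emphasis templates per class;
an `overlap` parameter pulls the palm-up/palm-down templates toward
their mean (1 = identical), reproducing the confusability of those two
gestures.

What the generator does **not** model: motor-unit action potentials,
electrode lift/impedance changes, fatigue, subject-to-subject
variability, or genuinely asynchronous multi-joint coordination (in
combined motions all active DOFs share the protocol timing).  Passing
benchmarks on these data therefore demonstrates internal consistency of
the pipeline, not field performance on human recordings.

## Reference benchmarks and their limits

*Gesture benchmark*: 200 windows per class at overlap 0.3, stratified
75/25 split.  The classes are separable by construction at this overlap,
and the hybrid classifier reaches ≥ 90% held-out accuracy with
clench/relax recall ≥ 95%.

*Angle benchmark*: per-DOF networks trained on the 25 single-DOF
sessions (5 DOFs × 5 amplitude groups covering each range), evaluated on
a combined abduction-and-raise session (shoulder abduction 72°, elbow
flexion 96°, forearm rotation 78°) never seen in training.  Features:
300 ms RMS windows at 50 ms steps, 9-frame centred smoothing, interval
scaling fitted on the training sessions.  Every other frame is used for
training (~12k frames); training runs 600 epochs of batch-64 momentum
updates with the adaptive η schedule.  Zero-target frames carry sample
weight 2 — the exposed wᵢ of the weighted error — because suppressing a
stationary joint while others move is as much part of the task as
tracking motion.

Two structural limits matter when reading the angle numbers:

1. **Envelope-estimation noise floor.**  Windowed RMS of a stochastic
   carrier has relative standard deviation ≈ 1/√(2BT) (B ≈ 130 Hz of
   carrier band inside the filter passband, T ≈ 0.7 s effective
   averaging), i.e. ~5% per frame, and the noise is multiplicative in
   the activation level.  During a hold at angle θ the best achievable
   frame-wise decode therefore has error sd ≈ 0.05·θ — about 4.6° at
   96° — verified by an oracle that inverts the true synergy matrix
   (hold sd 4.6°, max ≈ 12°).  The *maximum* absolute error over a
   ~1000-frame session is consequently an order of magnitude above its
   mean, and no frame-wise regressor can push it below roughly 10°
   under these study conditions.  Mean absolute errors and the
   inactive-DOF bound are the informative quantities at this noise
   level.
2. **Single-DOF → combined-motion transfer.**  Training data contain no
   simultaneous multi-joint activity, so the decode in the combined
   region is extrapolation; weight decay reduces, but does not
   eliminate, the resulting bias.

Inactive DOFs (shoulder flexion and rotation in the combined session)
are predicted near zero — typically within ~2°, consistent with the
expectation that stationary joints are identifiable — because their
noise is multiplicative on near-tonic envelopes and the training set
contains abundant "other joints active, this joint still" evidence.

## Command mapping

The controller is a pure (state, event) → (state, commands) function:
clench/relax toggle the claw (idempotent), palm-up enters ESTOP and
suppresses every subsequent joint command, palm-down resumes and is
accepted only from ESTOP.  Per-window gesture predictions are debounced
(default: 3 identical consecutive labels) before becoming events.  The
safety property — no JOINT_SET is ever emitted in ESTOP mode — is
checked by exhaustive enumeration of all event sequences up to length 6.

## Problem sizes

The bundled experiments are sized for a single CPU: 800 gesture windows
(8 × 200 each), 25 + 1 simulated 50 s sessions at 1 kHz, ~12k training
frames per regressor.  All randomness flows from explicit integer
seeds.
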