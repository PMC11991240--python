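# Methods

## Problem setting

A subject walks a straight lane of known length (default 10 m) wearing one
six-axis IMU on each heel, logging at 200 Hz: three angular-velocity channels
(deg/s), three specific-force channels (g) and the attitude estimator's Euler
angles (deg). The package reconstructs each foot's trajectory, removes
integration drift, segments the walk into the eight canonical gait-cycle
states, derives spatiotemporal gait parameters, and reduces the walk to one
asymmetry/consistency score designed to track a clinician's observational
gait assessment (a 31-item instrument where 0 is normal walking and higher
is worse). Hemiparetic gait after stroke is the motivating case: uneven step
lengths, stance times and pitch arcs between the affected and unaffected
sides.

Axis conventions throughout: x forward along the lane, y to the subject's
left, z up; pitch is dorsal-positive (toe up), so a heel strike shows a
dorsal pitch peak and push-off a plantar trough. The body-to-earth rotation
is intrinsic Z-Y-X, `R = Rz(yaw) @ Ry(-pitch) @ Rx(roll)`; the attitude
source never states a rotation order, so this is fixed here as a convention
and used consistently by the reconstruction and the simulator.

## Strapdown reconstruction

Specific force is rotated to the earth frame sample-by-sample, gravity
(9.80665 m/s²) is subtracted, and the free acceleration is doubly
integrated by the trapezoidal rule with zero initial velocity (the subject
stands still before walking; recordings include stationary padding). A flag
covers attitude sources that already output gravity-free "earth
acceleration". No sensor-fusion orientation estimation is performed: the
Euler stream is taken as given.

## Three-axis drift calibration

Double integration drifts without bound, so three anchors from the protocol
geometry are applied; all three commute and each is idempotent:

* **Stance windows.** Maximal intervals where the gyro magnitude stays below
  20 deg/s for at least 0.2 s. A planted foot does not rotate; a swinging
  foot turns at hundreds of deg/s, so these thresholds separate the phases
  robustly. Both are configurable.
* **X (scale).** The forward position read at the last stance window's
  midpoint must equal the lane length; the entire x series is rescaled by
  `lane / X_end`. Pure rescaling (rather than a time-linear error model) is
  used; it reproduces the observed behaviour of walks whose final distance
  overshoots the lane.
* **Y (heading drift).** The walk starts and ends on the lane line, so the
  lateral offset accumulated between the first and last stance windows is
  drift. The default removes it as a ramp linear in forward position —
  a constant shift cannot flatten drift that accumulates during the walk —
  with the literal constant-shift correction available as `y_mode=constant`.
  The ramp is normalized by the window means of x, which makes the endpoint
  condition exact and the operation idempotent. Window means (not single
  samples) are used for the y anchors for noise robustness.
* **Z (height baseline).** Foot height is zero whenever the foot is flat on
  the ground. Height anchors are read at both edges of every stance window
  and every 0.4 s inside long windows, and the piecewise-linear baseline
  through the anchors is subtracted. Multiple anchors per window matter:
  accelerometer bias makes the height drift quadratically, with metre-scale
  terminal velocity after ~10 s, and a single mid-window knot (or a
  hold-constant extrapolation past the last knot) leaves centimetre-scale
  residuals. Anchors are point reads, not window means; with point reads the
  calibrated height is exactly zero at every anchor and re-running the
  calibration is the identity, which would not hold for mean-based anchors
  under curved drift.

## Gait-cycle segmentation

The eight states are detected from the two calibrated trajectories and pitch
series, with the right foot as primary (tested) foot by default and the
rules mirrored under `primary=left`. Per cycle — the span between two
consecutive primary-foot pitch maxima:

1. **Initial contact**: primary pitch maximum (heel strike).
2. **Loading response**: earliest secondary pitch minimum whose forward
   rate is "almost unchanged", fixed as |dx/dt| below 5% of the session's
   mean forward speed. Two numerical refinements make this rule robust to
   residual integration drift: the rate is measured against a local drift
   baseline (median velocity over the ~0.3 strides before the candidate,
   when the secondary foot is certainly planted), and it is evaluated as the
   minimum over the candidate's localization jitter (±2% of a stride) since
   the trough sits on a flat pitch plateau.
3. **Mid-stance**: first instant the secondary foot's x overtakes the
   primary's (linear-interpolated crossing).
4. **Terminal stance**: earliest secondary pitch maximum after mid-stance.
5. **Pre-swing**: earliest primary pitch minimum after terminal stance.
6. **Initial swing**: peak of the primary foot's height in the remainder of
   the cycle.
7. **Mid-swing**: first zero-crossing of the primary pitch after initial
   swing (foot parallel to the floor), linear-interpolated. With the
   dorsal-positive convention the foot rises from its plantar trough through
   zero toward the next heel strike, so this crossing is upward; the
   detector accepts either direction and so is convention-agnostic.
8. **Terminal swing**: the next primary pitch maximum, which is also the
   next cycle's initial contact — cycles chain, and each spans 7 segments.

Pitch extrema use a 5 deg prominence and 0.4 s separation floor. Ties break
toward the earliest candidate; a cycle missing any event before the next
heel strike is dropped and logged.

**Parameters.** A landing is a foot's heel strike (primary: initial
contact; secondary: terminal stance). Per foot the package reports
(standard deviation, mean) — sample SD, n−1 — of: gait cycle time and
length (consecutive same-foot landings), one-step move time and length
(landing of one foot to the next landing of the other), and the stop angle
(pitch averaged over each flat-foot stance window; pitch is used rather
than roll by analogy with every other rule). When stance windows are not
supplied, the foot-flat phase is approximated as the 30–42% span of each
cycle after the landing.

## The gait score

Per cycle i the pitch extrema of both feet are read at the corresponding
events (`P_L,max,i` at the left's heel strike, `P_L,min,i` at its push-off,
likewise for the right), and per-foot stride times T1_i, T2_i between
consecutive same-foot heel strikes. With e, f, g, h the per-foot means of
maxima/minima, c, d, k, m their extremes over cycles, a and b the mean
left-right differences of per-step maxima and minima, ArangeL = e − f,
ArangeR = g − h, p = |T̄1 − T̄2| and q = (T̄1 + T̄2)/2:

    score = [a + b + (c−e) + (k−g) + (f−d) + (h−m)] / min(ArangeL, ArangeR)
            × (p/q + 1)

The first factor collects spatial asymmetry (a, b) and per-foot
inconsistency (c−e, k−g, f−d, h−m), normalized by the smaller foot's pitch
range so the score is invariant to overall pitch amplitude; the second
factor inflates it by the temporal asymmetry p/q. The formula's difference
terms are printed as signed quantities in the source material, but their
stated interpretation (larger a ⇒ more asymmetric ⇒ higher score) and the
non-negative clinical scale require magnitude semantics, so a, b and p are
taken as absolute values by default; `signed=True` retains the raw
differences. Under the default the score is non-negative, zero exactly for
a perfectly symmetric and perfectly repeatable gait, invariant to
left/right relabelling, to positive rescaling of all pitch angles, and to
rescaling of all stride times. When feet yield unequal step counts the
left-right pairing truncates to the shorter list with a warning.

**Clinical validation.** The package ships the published 26-subject table
of physician scores versus IMU scores and recomputes the product-moment
correlation and the mid-rank (tie-corrected) Spearman correlation, with
two-tailed significance via the t transform. The recomputed values are
r = 0.7526 and ρ = 0.9341 at full precision.

## The convolutional regressor

An alternative to explicit strapdown reconstruction: learn the mapping from
raw six-axis windows to calibrated coordinates. The architecture is an
encoder-decoder of exactly 11 one-dimensional convolutions, every kernel 41
wide: input conv to 64 filters; four encoder stages (conv doubling filters
to 128/256/512/1024, max-pool halving the length); a 1024-filter bottleneck
conv; four decoder stages (conv halving filters, nearest-neighbour unpool
doubling the length); output conv to 3 channels. ReLU follows every conv
but the last. The enumerated encoder/decoder ladder alone yields ten
convolutions; the explicit bottleneck is this package's resolution to the
stated 11-layer depth while preserving the 64→1024→64 mirror. Pooling
type, unpooling, activation, optimizer and batch size are unspecified
upstream and fixed here as conventional defaults, all exposed in the
configuration: max-pooling, nearest-neighbour unpooling, ReLU, Adam
(default rate 1e-3, β₂ = 0.99) with global-norm gradient clipping at 1.0,
a two-epoch linear warmup and an optional cosine decay. Batch
normalization follows every hidden convolution, with the final 30% of
epochs run on frozen running statistics so small-batch statistic noise
does not cap the attainable precision. Inputs are standardized per
channel; targets are centred by the per-position training-mean trajectory
and scaled by a single pooled standard deviation, so the untrained
(small-gain-output) network already predicts the cohort-mean walk,
capacity is spent on per-trial deviations, and the loss remains a true
squared distance in metres (per-axis scaling would overweight the
centimetre-scale height channel). Losses are reported in m², the held-out
error as pooled RMSE in metres next to a train-mean-predictor baseline.

The network, backpropagation, batch-norm and Adam are implemented directly
on numpy: convolutions are lowered to patch-matrix multiplications
(im2col) with the batch folded into the GEMM rows so the large weight
matrices stream once per call, the input gradient is recovered by a col2im
fold, and scratch buffers persist across steps to avoid allocator churn.
Training is bit-for-bit reproducible for a fixed seed on a fixed BLAS
configuration. The default window length is 1392 samples (divisible by
2⁴, as pooling requires; other lengths are zero-padded/cropped
symmetrically); the desk-scale experiments below use 96-point windows.

A ±10-point sliding-window moving average (21-point plateau response,
edges shrink to the available window) is provided to smooth the
prediction's sample-to-sample irregularity.

## The synthetic cohort

No recordings are distributable, so every claim is exercised on a forward
model of straight-lane walking with exact ground truth:

* **Kinematics.** Heel strikes at stride period T (default 1.35 s), stride
  length L (default 1.25 m), swing occupying 40% of the stride. The forward
  advance during swing follows a seventh-order smoothstep (C³ — with a
  merely C² profile the jerk discontinuities at swing boundaries alias into
  the trapezoidal re-integration and the noise-free round trip misses by
  centimetres; with C³ it closes to ~0.3 mm over 10 m). Heel height is a
  warped sin⁴ bump (5 cm default) peaking ~37% into the swing; pitch rises
  to its dorsal peak (25°) exactly at heel strike, falls to zero as the
  foot flattens, dips to the plantar trough (−15°) at push-off, all as
  quintic arcs. Phase warps are chosen so the event order is guaranteed and
  the overtake of the planted foot lands midway through single support. The
  subject starts and finishes with both feet on the line: the left foot
  leads by half a cycle and takes a closing half-step at the end (without
  it the affected foot would end a half-step short and the X rescale would
  be wrong by construction).
* **Asymmetry dials.** `left_step_share` splits the stride length between
  the two steps (0.5 symmetric); per-foot pitch amplitudes scale the
  affected side's arcs; `stride_time_asym` makes the left heel strike lag a
  growing fraction of the cycle so its mean stride time is longer by
  exactly that fraction — in steady lane walking both feet must share one
  period, so a per-stride lag is the mechanism that yields a nonzero mean
  stride-time difference over a finite walk. Its magnitude is capped so the
  lag never collides with the opposite foot's pre-swing.
* **Sensors.** Body-frame specific force and pitch-rate gyro are obtained
  by exact analytic differentiation and inverse rotation of the true
  kinematics — no numerical differentiation. Imperfections layered on top:
  white accelerometer noise (g), white gyro noise (deg/s), a constant
  accelerometer bias on all body axes (default 0.005 g; the source of the
  quadratic height drift and the overshooting forward distance), a constant
  heading offset written into the recorded yaw (the AHRS heading error that
  makes the integrated path veer), and optional white noise on the recorded
  Euler angles.
* **Cohorts.** `simulate_cohort` grades severity along a 10-point grid
  scaling pitch asymmetry up to 40% and stride-time asymmetry up to 0.8%,
  and (by default) draws per-subject stride count (6–10), stride length
  (1.0–1.5 m) and stride time (1.15–1.55 s) from realistic adult ranges.
  Sub-seeds derive deterministically from the cohort seed.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: turning, stopping and restarting, stairs or
treadmill gait, roll/yaw foot dynamics (only pitch rotates), soft-tissue
and mounting artefacts, attitude-estimator transients, coloured sensor
noise, and any within-session stride-to-stride variability beyond the
systematic asymmetries above. The score's clinical validity rests on the
packaged 26-subject table, not on the simulator.

## Scaled-down experiment sizes

The desk-scale analogue of the regressor experiment mirrors the structure
of the original acquisition, in which a handful of participants walked a
short lane repeatedly: it trains the full 11-conv architecture on 120
simulated walks — a stratified three-subject panel spanning
hemiparetic-slow to healthy-brisk gait, 40 repetitions each with 2%
trial-to-trial stride jitter — randomly split 96 train / 24 held out, each
recording anti-alias averaged onto a 96-point window covering a fixed 12 s
span, trained for 44 epochs on one CPU. Held-out trials therefore come
from the same walkers as the training trials, which is what such a split
of repeated lab recordings measures. The published experiment's test error
(5.42 cm) depends on recordings that are not distributable and is
therefore not a reproduction target; the analogue instead asserts that the
architecture learns the signal-to-coordinate mapping to better than 0.10 m
held-out RMSE and beats the train-mean predictor at least fivefold. A
harder variant — 120 *distinct* simulated subjects with continuously
varied gait, forcing extrapolation to unseen walkers — is expressible with
`simulate_cohort` but is not part of the acceptance experiment: the source
study never tested between-subject generalization. Event-detection
robustness is measured on cohorts of eight-stride sessions at 0.05 g
accelerometer noise, 1 deg/s gyro noise and 0.05 deg Euler noise.

## Numerical notes and limitations

* Event times at pitch extrema are sample-aligned (±half a sample);
  mid-stance and mid-swing are linear-interpolated between samples.
* The loading-response drift baseline assumes the secondary foot is planted
  for ≥0.3 strides before its trough, true for walking but not for running.
* `calibrate_y(mode="constant")` is the literal printed correction: it
  re-seats the end of the walk on the start's lane line but, unlike the
  default linear mode, is neither idempotent nor able to flatten mid-walk
  drift.
* Angle-at-stop means are sensitive to the stance-window definition; with
  gyro-derived windows on the simulator they are ~0°, matching the
  foot-flat construction.
* The numpy CNN is CPU-bound: on the order of ten seconds per epoch at the
  desk scale (96 windows of 96 points, ~100 M parameters). Feasibility at
  reduced scale, not throughput, is its purpose.
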