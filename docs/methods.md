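# Methods

## Measurement model

The knee is modelled as a planar hinge in the sagittal plane. Two IMUs sit
laterally on thigh and shank; each reports the inclination of its long axis
from vertical, α_Femur and α_Tibia (degrees, positive with forward rotation
of the distal end). Because the sensors are re-applied daily, each carries an
unknown fixed offset to its segment's mechanical axis (δ_F, δ_T), and

    α_Knee = (α_Femur − δ_F) − (α_Tibia − δ_T) = α_Femur − α_Tibia − δ_Knee.

Only the combined offset δ_Knee = δ_F − δ_T has to be identified. It is
estimated from a static registration pose (operated leg resting on a rigid
box) as the mean raw relative angle over the still window minus the
goniometer reading α_PT taken once in that pose by a clinician. Two
consequences follow directly and are asserted as invariants in the tests:
the registered angle depends on (δ_F, δ_T) only through their difference,
and a goniometer error of ε (α_PT reading ε degrees high) raises every
reported angle by exactly ε — a constant bias that does not affect
within-patient day-to-day comparisons, and that cancels in sensor − video
comparisons because the video series is anchored to the same reading.

## Orientation filter

Each 6-DOF stream is fused with the Madgwick gradient-descent complementary
filter (magnetometer-free IMU variant; only sagittal inclination is used, so
heading drift is irrelevant). Per sample: the quaternion is advanced by the
gyro rotation, then corrected along the normalized gradient of the
gravity-alignment objective, scaled by the gain β.

Numerical choices, all visible in `kneeflex.imu`:

* **Gyro integration uses the quaternion exponential** (exact for a constant
  rate within a step) with trapezoidal averaging of consecutive gyro
  samples. The common forward-Euler quaternion derivative leaves an
  O((ωΔt)³) angle error per step and a half-sample phase delay; the phase
  delay alone is enough to bias the video-synchronization lag by one 60 Hz
  sample.
* **The corrective step is saturated, not strictly normalized**: step =
  β·Δt·∇f/max(‖∇f‖, 1). A strictly normalized step has constant magnitude
  β·Δt regardless of how small the error is, producing a limit cycle of
  roughly β·Δt radians (≈0.1–0.2° at β = 0.1, 50 Hz) around equilibrium on
  clean data. Saturation keeps the published large-error behaviour and makes
  the correction proportional near equilibrium, where the filter then holds
  a static pose to numerical precision. A zero-norm accelerometer sample
  skips the correction entirely.
* **Initialization** is tilt-from-gravity from the first accelerometer
  sample (minimal rotation taking the measured specific-force direction to
  vertical), so static inputs start converged; `init="identity"` is
  available. Accuracy metrics in the tests discard the first 2 s.
* β defaults to 0.1 (dimensionless gain ≈ rad/s of correction authority) —
  the usual convergence/noise compromise at 50 Hz; configurable everywhere.

The sagittal angle is atan2 of the world-frame body-z axis projected on the
sagittal plane, unwrapped along the series; orientations whose long axis is
within ~0.06° of the sagittal-plane normal are rejected as degenerate.

## Video angles

Flexion per frame is 180° minus the internal angle between (hip − knee) and
(ankle − knee), computed with atan2(|cross|, dot) for stability near 0° and
180°. The measure is invariant to image translation, rotation and uniform
scale. Frames with any joint confidence below 0.3 are dropped (per-session
dropped-fraction is exposed as a QC metric; sessions above 20% are flagged
by the pipeline configuration default). A constant keypoint-placement bias
survives the geometry and is removed by the goniometer anchor: after
synchronization, the video series is shifted so its mean over the box-pose
window equals α_PT exactly.

## Synchronization

Both series are cubic-spline resampled to a uniform 60 Hz grid (no
extrapolation; resampling to the native grid is an exact identity). The lag
is the integer sample shift of the video series, in ±max_lag (default 10 s),
maximizing the *normalized* covariance (Pearson correlation) of the overlap,
ties broken toward the smallest |lag|.

The normalization is a deliberate choice. Exercise sessions are strongly
nonstationary — still pose, ramp, steady cycles — and an un-normalized
covariance can prefer a wrong lag whose overlap happens to catch more
high-variance motion (observed in development as a one-to-two-sample bias,
and as full period misses on long steady recordings, where a
period-shifted candidate kept more overlap). The correlation is bounded by 1
with equality only at an exact linear match, so on noise-free data the true
lag is the unique maximizer over any overlap; periodic false candidates are
rejected by the registration-pose segment they fail to match. For a
perfectly periodic signal the ambiguity is real: candidates one period apart
score exact ties, and the smallest-|lag| tie-break (at 1e-9 relative
tolerance, below any physical effect but above floating-point jitter)
returns the true shift when it is within half a period. Sub-sample
refinement is deliberately out of scope.

## Bias statistics and correction

Bias is sensor − video on the aligned grid. Bins are half-open [5k, 5k+5)
by the sensor angle (configurable); per bin: n, mean, mean-absolute, sample
SD (n−1), and the width of the central 95% of bias values. Overall rows are
unweighted across-bin means over non-empty bins inside [0°, 110°); bins
outside that span are reported but excluded. OLS agreement regresses sensor
on video.

The bias-vs-angle model is a continuous piecewise-linear function with three
segments and two free interior breakpoints, fitted to per-bin points (bin
centers 2.5°, 7.5°, …). With breakpoints fixed the model is linear in its
coefficients (intercept, slope, one hinge term per breakpoint) and solved in
closed form; the breakpoints are found by seeded differential evolution over
the interior of the angle range. A minimum breakpoint separation of 2% of
the range is enforced with a finite penalty: without it, data with no
angle-dependent bias collapses the breakpoints and the sliver middle segment
takes unbounded coefficients. The regression direction is bias = f(angle) —
the only orientation usable for correction. Correction subtracts the
predicted bias at the (uncorrected) sensor angle; corrected tables re-bin by
the corrected angle, which is why a corrected table is not pure arithmetic
on the uncorrected one. Prediction outside the fitted range extrapolates
with the nearest segment.

Repeatability statistics: goniometer repeatability is the per-patient
absolute between-visit difference with pooled mean/SD and the min/max of all
readings; pose repeatability demeans repeated δ_Knee values within each
session, then pools per-patient means weighted by repeat counts
(single-repeat sessions contribute zero spread and are flagged).

## Synthetic data

The generator emulates one recording session: a 5 s stationary box pose
(with 0.15° postural sway at 0.3 Hz — patients are never perfectly still), a
2 s raised-cosine ramp, then the cyclic exercise. Waveforms are a raised
cosine or a band-limited (7-harmonic, renormalized) triangle; exercises
decompose the knee angle into segment angles (standing knee bends: 35% thigh
/ 65% shank; long arc quads: thigh fixed at 85°, shank only). Closed-form
angle and rate functions let the gyro signal and the lag-shifted camera
stream be evaluated exactly at arbitrary times.

Sensor model: gyro = segment rate + bias + white noise; accelerometer =
gravity expressed in the (misaligned) sensor frame + white noise. Defaults
are realistic consumer-MEMS figures at 50 Hz bandwidth: gyro noise
0.2 °/s RMS, gyro bias 0.02 °/s, accelerometer noise 0.003 g RMS. Camera
model: hip/knee/ankle keypoints from segment geometry in image (y-down)
pixels, white pixel noise (default 2 px), per-frame dropout (2%), an
optional systematic keypoint-placement bias (split ± between thigh and shank
inclinations — a pure camera rotation cannot bias the angle, which is
rotation-invariant), and a video delay relative to the sensor clock.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real recordings: skin-motion artefact, out-of-sagittal
sensor placement and knee axis obliquity, linear/centripetal accelerations
(gravity-only accelerometer by default), pose-estimation failure modes that
are correlated in time, and camera lens distortion. The simulation is the
controlled setting in which the pipeline's algebra, filters and estimators
can be verified against known truth; clinical accuracy numbers come from the
bundled published tables, not from simulation.

## Degenerate inputs and tie-breaks

Constant angle series are rejected by the lag search (covariance undefined);
coincident keypoints raise (undefined angle); a constant motion profile is
rejected unless explicitly allowed; rolling-SD window detection fails
loudly when no still window exists; empty bins carry n = 0 with null
statistics; single-line piecewise input accepts any breakpoints with equal
slopes and R² = 1.

## Problem sizes

Test and demonstration runs use sessions of 8–60 s of exercise (one to two
thousand 50 Hz samples per sensor), 100 short sessions for the lag-recovery
property, 20 seeds for piecewise parameter recovery, and 12 hinge angles ×
5 placements × 10 s for the static-accuracy bench; these sizes give
fully converged statistics for every assertion while keeping the whole suite
fast to run.
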