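# Methods

## The measurement problem

The pendulum test quantifies knee muscle tone: the examiner raises the
relaxed lower leg to full knee extension and releases it; gravity
swings it about the knee and the oscillation decays toward the natural
resting angle. Spasticity increases the effective damping, truncating
the swing. This package computes the angle–time curve from three
interchangeable sources — an electronic-goniometer CSV export, 2D
pose-estimation keypoints, and 3D pose-estimation keypoints — and
reduces each trial to the pendulum parameters P1, P2, P3.

## Angle computation

All angles use the extension-zero convention: θ = 0° when thigh
(hip→knee, u) and shank (knee→ankle, v) are collinear, growing with
flexion. θ = cos⁻¹(u·v/|u||v|), with the cosine clamped to [−1, 1] so
floating-point overshoot on collinear frames cannot raise a domain
error; outputs therefore always lie in [0°, 180°]. Goniometer files
recorded in the clinical 180°-at-extension convention are converted on
read (180° − angle) via a reader flag.

2D image coordinates are used as-is (y-down): the angle between two
difference vectors is invariant to translation, uniform scaling and
axis reflection, so no flip or calibration is applied. Frames whose
hip/knee/ankle confidence falls below 0.3 (a conventional
pose-estimation default; the threshold is configurable) get their
angle filled by linear interpolation from neighbouring reliable
frames, keeping the sampling grid uniform for the smoother.

For 3D input the knee angle must be measured inside the sagittal
plane, since pose-estimation error moves joints out of it. Two
body-midline vectors span the plane: u_m = mid-shoulder → mid-hip
(longitudinal axis) and v_m = mid-shoulder → nose. The nose is the
only COCO-17 midline landmark off the trunk axis; because the head
sits anterior to the shoulder line, both vectors lie in the sagittal
plane and n = u_m × v_m (unit-normalized) points mediolaterally. The
obvious alternative — the hip-to-hip vector — is *not* usable here:
it is mediolateral itself, so its cross product with the longitudinal
axis is the anterior axis, and projecting that component out of the
leg vectors annihilates flexion entirely. u and v are projected into
the plane (u_h = u − (u·n)n) and the 2D formula is applied to u_h,
v_h. The plane is estimated per frame by default; an `averaged` mode
uses the normalized mean normal, which is more robust to keypoint
noise when the pelvis is static. Segments nearly perpendicular to the
plane (in-plane norm below 10⁻⁶ of the segment length) raise a
degenerate-projection error naming the frame.

## Smoothing

A third-order Savitzky–Golay filter (scipy implementation,
polynomial-fit edge handling) smooths the trace before landmark
extraction. The filter reproduces cubic polynomials exactly, so the
swing peaks that the landmarks depend on are preserved far better than
with a moving average. The window length is not dictated by the
measurement model; the default of 11 frames (≈0.37 s at 30 fps) was
chosen to suppress keypoint jitter while leaving the ~1 Hz swing
untouched, and is configurable (`smoothing.window_frames`).

## Landmarks and parameters

On the flexion-positive axis the leg's physical lowest point is
maximal flexion, i.e. a local *maximum* of θ. Extrema are located with
a prominence filter (default 1.0°: above numerical ripple and typical
post-smoothing keypoint jitter, below any real swing); plateau ties
resolve to the plateau's first frame, and the release sample (global
start, maximal extension) is prepended as the initial extremum.
Validation suites that run on noiseless simulated traces lower the
prominence (0.01°) because at strong damping the second-swing extrema
fall below one degree.

With θ_start the release-frame angle, θ_rest the mean over the final
settling window (default 1 s; a variance above 5 deg² warns that the
trace may not have settled), e1 the first flexion peak, e2 the
following extension trough and e3 the following flexion peak:

    A0 = |θ_start − θ_rest|      A1 = |e1 − θ_start|
    A3 = |e2 − θ_rest|           A4 = |e3 − e2|

and P1 = A1/A0, P2 = A3, P3 = A4/A3. The naming skips A2 by
convention of the parameter set; none is defined or invented. P2 is
conventionally called the "first maximum of oscillation" although it
is defined through the second-swing landmark A3; the definition, not
the name, is implemented. Traces with fewer than three interior
extrema (severe spasticity, ζ ≥ 1, or a swing below the prominence
threshold) raise a typed overdamped-trace error carrying whatever
landmarks were computable; the batch pipeline converts this into a
flagged partial record so study-level code counts exclusions
explicitly. A0 = 0 leaves every ratio undefined (error); A3 = 0
undefines only P3 (flag).

Two open choices were fixed as follows: the resting angle is estimated
from the trace tail (the protocol lets the limb settle; no pre-test
static measurement is assumed to exist), and A0 uses the release-frame
angle rather than a pre-release static angle.

## Statistics

* **Bland–Altman**: bias = mean(y − x), limits of agreement
  bias ± 1.96·SD(differences); proportional bias by OLS of the
  difference on the pairwise mean, with slope p-value and R².
* **ICC**: two-way random-effects, single rater, *consistency* type:
  ICC = (MSR − MSE)/(MSR + (k−1)·MSE) from the complete-case two-way
  ANOVA decomposition, with 95% CI from F-distribution bounds on
  MSR/MSE. Negative estimates are reported as-is and flagged, never
  clamped. An absolute-agreement form,
  (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n), is available behind
  `agreement.icc_form` for sensitivity analysis; it reports the point
  estimate only (no closed-form CI), which the result flags state.
* **Paired limb comparison**: two-sided paired t-test on
  subject-level trial means, with paired Cohen's d =
  mean(diff)/SD(diff). The study table's "effect" column reports the
  raw mean difference (affected − unaffected) — the convention of the
  table layout this reporting reproduces — while d is emitted
  alongside.
* **Spearman vs MAS**: midrank-tied rank correlation (MAS is heavily
  tied), two-sided p, preceded by Tukey IQR screening of the parameter
  values (fences Q1 − 1.5·IQR, Q3 + 1.5·IQR; quartiles by linear
  interpolation of order statistics — fence membership at small n
  depends on this convention, hence it is pinned and tested).
  Screening is applied per device × parameter × muscle stratum by
  default (`agreement.iqr_scope`).
* **Shapiro–Wilk gate** on method differences: results annotate
  downstream parametric analyses, never block them.
* No multiple-testing correction; α = 0.05 throughout.

## Synthetic-data generator

The simulator is the package's ground-truth instrument. The knee is a
linear damped oscillator: for ζ < 1,

    θ(t) = θ_rest + (θ_release − θ_rest)·e^(−ζω_n t)
           ·[cos(ω_d t) + ζ/√(1−ζ²)·sin(ω_d t)],  ω_d = ω_n√(1−ζ²),

whose extrema sit exactly at t_k = kπ/ω_d with amplitudes decaying by
r = exp(−πζ/√(1−ζ²)) per half cycle. This gives closed-form landmarks
(A0 = A, A1 = A(1+r), A3 = Ar², A4 = Ar²(1+r)) and P1 = P3 = 1 + r —
exact, independent oracles for the analysis path. ζ ≥ 1 uses the
critically/overdamped closed forms (monotone settling). Defaults:
ω_n = 5.5 rad/s (≈0.88 Hz, a typical adult lower-leg pendulum
frequency), θ_rest = 70°, θ_release = 0°, 30 fps.

A supine body geometry (bed plane z = 0, longitudinal axis x, nose
anterior to the shoulder line) renders any trace into COCO-17
keypoints: 3D world coordinates, or orthographic 2D projections from a
lateral (90°) or 45°-oblique camera with Gaussian pixel noise and
confidences near 0.9. The camera is orthographic deliberately: the
lateral view then preserves the in-plane angle exactly, giving the 2D
route an exact oracle; no camera model is part of the measurement
method being emulated. The oblique view foreshortens the longitudinal
axis, reproducing the known view-angle bias of uncorrected 2D
analysis.

Cohorts emulate the study protocol: 20 subjects, both limbs, five
trials per limb, each trial emitted simultaneously for all three
devices from the *same* underlying trace (goniometer noise 0.25°,
pixel noise 1.5 px, 3D noise 5 mm). One limb per subject is affected;
its MAS level is drawn from {0, 1, 1+, 2} (the severity range the
emulated protocol covers) and maps to a damping band
(MAS 0 → ζ ≈ 0.10, 1 → 0.25, 1+ → 0.35, 2 → 0.45, sd 0.05, truncated
to [0.02, 0.95]); unaffected limbs draw from the MAS-0 band. This
mapping is a synthetic calibration, not a clinical one. Recordings
last 15 s so that low-damping limbs settle enough for the tail-based
resting-angle estimate; trials whose tail still oscillates are flagged
`unsettled_rest`. Everything is deterministic per seed, byte-for-byte.

An optional velocity-threshold reflex-torque variant multiplies the
damping coefficient above a flexion-velocity threshold, mimicking the
velocity-dependent spastic catch. It has no closed form and is
validated only by the qualitative invariant that stronger reflex gain
lowers P1.

### What the simulator does and does not show

Passing the synthetic suites demonstrates that the pipeline recovers
known dynamics through file IO, rendering, projection, smoothing and
landmark extraction, and that the statistics implement their
definitions. It does not demonstrate clinical validity: the linear
model yields P1 = 1 + r ∈ (1, 2), whereas real spastic limbs show
P1 < 1 (the first swing stops short of the resting angle — reflexive
catch behaviour outside the linear model), and real pose-estimation
error is structured (occlusion, identity swaps, domain shift for
supine poses), not isotropic Gaussian. Cohort-level checks are
therefore qualitative: ordering of limb means, sign and strength of
the MAS correlation, and cross-device ICC.

## Numerical and degenerate-input choices

* arccos argument clamped to [−1, 1]; angles clipped to [0°, 180°].
* Zero-length segments, degenerate midline planes and
  plane-perpendicular segments raise typed errors naming the frame.
* Non-uniform angle-CSV sampling beyond 1% jitter is resampled by
  linear interpolation onto the median-step grid (logged).
* Quartiles by linear interpolation of order statistics; plateau
  extrema take the first frame; study tables are row-order invariant;
  unavailable cells (n below the statistic's minimum) are reported as
  unavailable, never dropped.

## Problem sizes used in the validation suites

The damping-grid oracle runs ζ ∈ {0.05, …, 0.6} on noiseless traces
whose duration grows as damping falls (so the tail settles); the
statistics calibrations use 2000 null replicates (paired t), 200
(Shapiro type-I), 100 (smoother), and 10 000 samples (IQR exceedance);
the end-to-end study uses the default 20-subject cohort (600 trial
files). These sizes give Monte-Carlo standard errors comfortably
inside the asserted bands.

## Known limitations

* The landmark definitions assume a decaying oscillation released
  from maximal extension; traces released below the resting angle or
  dominated by voluntary motion are out of scope.
* The 45° oblique 2D view is analyzed uncorrected (as in uncalibrated
  single-camera practice); its foreshortening bias is reproduced, not
  removed.
* The absolute-agreement ICC omits a confidence interval.
* MAS levels 3–4 are outside the generator's default severity range,
  mirroring the cohort composition the simulator emulates.
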