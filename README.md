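# pendulumtest

Pose-estimation-assisted pendulum test for quantifying knee spasticity.

After a stroke, increased muscle tone (spasticity) in the muscles
crossing the knee changes how the relaxed lower leg swings when it is
released from full extension — the classic *pendulum test*. This
package turns markerless pose-estimation output (2D or 3D keypoint
trajectories in the COCO-17 convention) or electronic-goniometer angle
exports into knee flexion angle–time curves, extracts the swing
landmarks, computes the standard pendulum parameters, and runs the
method-agreement statistics used to validate a video-based system
against a goniometer reference. It is aimed at rehabilitation and
movement-science researchers who have per-frame keypoints (e.g. from
AlphaPose-style 2D or 3D pose estimators) and want objective
spasticity measures without lab hardware.

## Model and parameters

The knee angle θ is computed per frame with 0° at full extension,
increasing with flexion:

* **2D**: θ = cos⁻¹(u·v / |u||v|) with u the hip→knee vector and v the
  knee→ankle vector (invariant to translation, scale, and the image's
  y-down convention).
* **3D**: the sagittal plane is estimated from body-midline landmarks
  (n = u_m × v_m with u_m = mid-shoulder→mid-hip, v_m =
  mid-shoulder→nose), u and v are projected into that plane, and the
  same formula is applied to the in-plane components.

The trace is smoothed with a third-order Savitzky–Golay filter, and
local extrema of the decaying oscillation yield the landmarks

* **A0** — release-to-rest angular distance,
* **A1** — first-swing excursion (release to first flexion peak),
* **A3** — second-swing peak offset from rest,
* **A4** — second-swing excursion,

from which the pendulum parameters follow:

* **P1 = A1/A0** — normalized relaxation index (lower ⇒ more spastic),
* **P2 = A3** — first maximum of oscillation, in degrees,
* **P3 = A4/A3** — relaxation index at half swing.

For a linear damped oscillator with damping ratio ζ < 1 these have the
closed form P1 = P3 = 1 + r with r = exp(−πζ/√(1−ζ²)), which the
built-in simulator uses as an exact oracle for the whole pipeline.

The statistics module provides Bland–Altman bias and 95% limits of
agreement with a proportional-bias regression, two-way random-effects
single-rater ICC of the consistency type, paired t-tests with paired
Cohen's d for affected-vs-unaffected limbs, Spearman correlation with
Modified Ashworth Scale scores after Tukey IQR outlier screening, and
a Shapiro–Wilk normality gate.

## Worked example

Simulate one goniometer-style trial (ζ = 0.2, rest angle 70°, release
at full extension, 0.25° sensor noise) and extract its parameters:

```python
from pendulumtest import PendulumModel, simulate_trace
from pendulumtest.keypoint_io import write_angle_csv

trace = simulate_trace(PendulumModel(zeta=0.2, theta_rest=70.0, duration_s=15.0),
                       noise_sd_deg=0.25, seed=42)
write_angle_csv(trace, "trial.csv")
```

```sh
pendulum-test params trial.csv --out params.json
```

prints nothing on success and writes:

```json
{
 "A0": 69.92520617012443,
 "A1": 106.52062391142213,
 "A3": 19.40304278317793,
 "A4": 29.486570820512874,
 "P1": 1.523350873678698,
 "P2": 19.40304278317793,
 "P3": 1.519687976263041,
 "flags": "",
 "rest_angle": 69.96706926802652
}
```

A0 ≈ 70° is the release-to-rest distance; the first swing overshoots
to 106.5° of excursion, so P1 ≈ 1.52 — within 0.01 of the analytic
1 + exp(−0.2π/√0.96) = 1.5266 for this damping ratio. P3 ≈ P1, as the
damping law predicts, and P2 ≈ 19.4° is the second-swing peak offset.
A severely damped (spastic) limb would drive P1 toward 1 and
eventually produce an `overdamped` flag with partial landmarks.

Other commands: `pendulum-test angles` (keypoints → smoothed angle
CSV), `pendulum-test simulate-cohort` (synthetic multi-subject study
on disk), and `pendulum-test study` (trial table → ICC, limb
comparison and MAS-correlation tables plus Bland–Altman scatter data).

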