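"""Synthetic pendulum-test data with known ground truth.

The knee is modelled as a linear damped oscillator: released from full
extension, the lower leg swings about its natural resting angle with
natural frequency ω_n and damping ratio ζ.  The underdamped closed
form

    θ(t) = θ_rest + (θ_release − θ_rest) · e^(−ζω_n t)
           · [cos(ω_d t) + (ζ/√(1−ζ²))·sin(ω_d t)],    ω_d = ω_n√(1−ζ²)

has its extrema exactly at t_k = kπ/ω_d with amplitudes decaying by
r = exp(−πζ/√(1−ζ²)) per half cycle, which yields exact closed-form
swing landmarks (A0 = A, A1 = A(1+r), A3 = A·r², A4 = A·r²(1+r)) and
hence P1 = P3 = 1 + r — the analytic oracle the analysis pipeline is
validated against.  Spasticity damps the swing, so cohorts map higher
Modified Ashworth Scale (MAS) levels to higher ζ.

A supine body geometry renders any angle trace into COCO-17 keypoint
trajectories: 3D world coordinates, or orthographic 2D projections
from a lateral (90°) or 45°-oblique camera with pixel noise and
near-0.9 confidences.  The orthographic lateral view preserves the
in-plane knee angle exactly, giving the 2D route an exact oracle too.

An optional velocity-threshold reflex-torque variant (piecewise
damping that kicks in above a flexion-velocity threshold) mimics the
spastic catch; it has no closed form and is validated only by the
qualitative invariant that stronger reflex gain lowers P1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import KP_INDEX, N_KEYPOINTS, AngleTrace, KeypointTrajectory, TrialMetadata
from .errors import UndefinedOracleError
from .keypoint_io import (
    write_angle_csv,
    write_keypoints_2d,
    write_keypoints_3d,
    write_trial_table,
)
from .swing_analysis import Extremum, SwingLandmarks


def half_cycle_decay_ratio(zeta: float) -> float:
    """Amplitude decay per half cycle, r = exp(−πζ/√(1−ζ²)), for ζ < 1."""
    if not 0 <= zeta < 1:
        raise UndefinedOracleError(f"decay ratio defined for 0 <= zeta < 1, got {zeta}")
    return float(np.exp(-np.pi * zeta / np.sqrt(1.0 - zeta**2)))


@dataclass
class PendulumModel:
    """Linear damped-oscillator knee model for one trial.

    ``omega_n`` defaults to 5.5 rad/s (≈0.88 Hz), a typical adult
    lower-leg pendulum frequency; ``theta_rest`` is the natural resting
    knee angle and ``theta_release`` the release angle (0° = full
    extension).
    """

    omega_n: float = 5.5
    zeta: float = 0.25
    theta_rest: float = 70.0
    theta_release: float = 0.0
    duration_s: float = 10.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.omega_n <= 0:
            raise ValueError("omega_n must be positive")
        if self.zeta < 0:
            raise ValueError("zeta must be non-negative")
        if self.duration_s * self.fps < 10:
            raise ValueError("model must span at least 10 samples")

    @property
    def amplitude(self) -> float:
        return abs(self.theta_release - self.theta_rest)


def _theta_closed_form(model: PendulumModel, t: np.ndarray) -> np.ndarray:
    z, w = model.zeta, model.omega_n
    a = model.theta_release - model.theta_rest
    if z < 1:
        wd = w * np.sqrt(1 - z**2)
        env = np.exp(-z * w * t)
        shape = np.cos(wd * t) + (z / np.sqrt(1 - z**2)) * np.sin(wd * t)
    elif z == 1:
        env = np.exp(-w * t)
        shape = 1 + w * t
    else:
        wo = w * np.sqrt(z**2 - 1)
        env = np.exp(-z * w * t)
        shape = np.cosh(wo * t) + (z / np.sqrt(z**2 - 1)) * np.sinh(wo * t)
    return model.theta_rest + a * env * shape


def simulate_trace(
    model: PendulumModel,
    noise_sd_deg: float = 0.0,
    seed: int = 0,
    device: str = "goniometer",
    side: str = "right",
) -> AngleTrace:
    """Sample the model at its fps with additive Gaussian angle noise.

    Deterministic for a fixed seed.  ζ < 1 uses the underdamped closed
    form; ζ ≥ 1 the critically/overdamped closed forms (monotone
    settling — downstream landmark extraction reports such traces as
    overdamped).
    """
    n = int(round(model.duration_s * model.fps))
    t = np.arange(n) / model.fps
    theta = _theta_closed_form(model, t)
    if noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd_deg, size=n)
    return AngleTrace(
        angles=np.clip(theta, 0.0, 180.0), fps=model.fps, side=side, device=device
    )


def simulate_trace_reflex(
    model: PendulumModel,
    reflex_gain: float = 0.0,
    velocity_threshold_deg_s: float = 150.0,
    noise_sd_deg: float = 0.0,
    seed: int = 0,
    device: str = "goniometer",
    side: str = "right",
) -> AngleTrace:
    """Damped oscillator with a velocity-threshold reflex torque.

    Above ``velocity_threshold_deg_s`` of flexion velocity the damping
    coefficient is multiplied by (1 + reflex_gain), mimicking the
    velocity-dependent spastic catch.  Integrated by RK4 on the sample
    grid; ``reflex_gain=0`` recovers the linear model.
    """
    n = int(round(model.duration_s * model.fps))
    dt = 1.0 / model.fps
    w, z = model.omega_n, model.zeta
    rest = model.theta_rest

    def deriv(state):
        th, om = state
        c = 2 * z * w
        if abs(om) > velocity_threshold_deg_s:
            c *= 1.0 + reflex_gain
        return np.array([om, -c * om - w**2 * (th - rest)])

    theta = np.empty(n)
    state = np.array([model.theta_release, 0.0])
    for i in range(n):
        theta[i] = state[0]
        k1 = deriv(state)
        k2 = deriv(state + 0.5 * dt * k1)
        k3 = deriv(state + 0.5 * dt * k2)
        k4 = deriv(state + dt * k3)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
    if noise_sd_deg > 0:
        rng = np.random.default_rng(seed)
        theta = theta + rng.normal(0.0, noise_sd_deg, size=n)
    return AngleTrace(
        angles=np.clip(theta, 0.0, 180.0), fps=model.fps, side=side, device=device
    )


def closed_form_extrema(model: PendulumModel) -> SwingLandmarks:
    """Analytic swing landmarks of the underdamped model (the oracle).

    With A = |θ_release − θ_rest| and r the half-cycle decay ratio:
    A0 = A, A1 = A(1+r), A3 = A·r², A4 = A·r²(1+r); the k-th extremum
    sits at t_k = kπ/ω_d with signed offset A·(−r)^k from rest (k = 0
    is the release itself).
    """
    if not model.zeta < 1:
        raise UndefinedOracleError(
            f"closed-form extrema require zeta < 1, got {model.zeta}"
        )
    a = model.amplitude
    r = half_cycle_decay_ratio(model.zeta)
    wd = model.omega_n * np.sqrt(1 - model.zeta**2)
    extrema = []
    for k in range(4):
        t_k = k * np.pi / wd
        angle = model.theta_rest + (model.theta_release - model.theta_rest) * (-r) ** k
        extrema.append(
            Extremum(
                frame_index=int(round(t_k * model.fps)),
                angle=float(angle),
                kind="trough" if k % 2 == 0 else "peak",
            )
        )
    return SwingLandmarks(
        A0=a,
        A1=a * (1 + r),
        A3=a * r**2,
        A4=a * r**2 * (1 + r),
        rest_angle=model.theta_rest,
        extrema_used=tuple(extrema),
    )


# ---------------------------------------------------------------------------
# Keypoint rendering
# ---------------------------------------------------------------------------

@dataclass
class BodyGeometry:
    """Supine body layout in world coordinates (metres).

    The subject lies on a bed at z = 0 with the longitudinal axis along
    +x (head toward −x) and z pointing up (anteriorly for a supine
    pose).  The tested thigh is horizontal along +x; the shank rotates
    about the knee within the sagittal (x–z) plane by the knee angle.
    """

    thigh_length: float = 0.45
    shank_length: float = 0.40
    torso_length: float = 0.50
    hip_half_width: float = 0.10
    shoulder_half_width: float = 0.17
    side: str = "right"
    pixels_per_m: float = 500.0
    image_center: tuple[float, float] = (960.0, 540.0)

    def __post_init__(self) -> None:
        for name in ("thigh_length", "shank_length", "torso_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.side not in ("left", "right"):
            raise ValueError("side must be 'left' or 'right'")


def _static_template(geom: BodyGeometry, resting_deg: float) -> np.ndarray:
    """3D positions of the 16 non-swinging keypoints plus knee anchors."""
    y = {"left": 1.0, "right": -1.0}
    kp = np.zeros((N_KEYPOINTS, 3))
    kp[KP_INDEX["left_hip"]] = (0.0, geom.hip_half_width, 0.0)
    kp[KP_INDEX["right_hip"]] = (0.0, -geom.hip_half_width, 0.0)
    kp[KP_INDEX["left_shoulder"]] = (-geom.torso_length, geom.shoulder_half_width, 0.0)
    kp[KP_INDEX["right_shoulder"]] = (-geom.torso_length, -geom.shoulder_half_width, 0.0)
    # Head: the nose sits anterior to (above, for a supine pose) the
    # shoulder line — the off-axis midline landmark the sagittal-plane
    # estimate relies on.
    kp[KP_INDEX["nose"]] = (-geom.torso_length - 0.22, 0.0, 0.10)
    for s in ("left", "right"):
        kp[KP_INDEX[f"{s}_eye"]] = (-geom.torso_length - 0.24, y[s] * 0.03, 0.11)
        kp[KP_INDEX[f"{s}_ear"]] = (-geom.torso_length - 0.18, y[s] * 0.07, 0.06)
        kp[KP_INDEX[f"{s}_elbow"]] = (-geom.torso_length / 2, y[s] * 0.21, 0.0)
        kp[KP_INDEX[f"{s}_wrist"]] = (0.0, y[s] * 0.22, 0.0)
    # The non-tested leg rests at the resting flexion angle.
    other = "left" if geom.side == "right" else "right"
    ohip = kp[KP_INDEX[f"{other}_hip"]]
    oknee = ohip + np.array([geom.thigh_length, 0.0, 0.0])
    kp[KP_INDEX[f"{other}_knee"]] = oknee
    th = np.radians(resting_deg)
    kp[KP_INDEX[f"{other}_ankle"]] = oknee + geom.shank_length * np.array(
        [np.cos(th), 0.0, -np.sin(th)]
    )
    return kp


def supine_keypoints_3d(trace: AngleTrace, geom: BodyGeometry) -> np.ndarray:
    """World-coordinate keypoints (n_frames × 17 × 3) for an angle trace."""
    n = len(trace)
    rest = float(np.mean(trace.angles[-max(1, int(trace.fps)):]))
    template = _static_template(geom, rest)
    coords = np.tile(template, (n, 1, 1))
    hip = template[KP_INDEX[f"{geom.side}_hip"]]
    knee = hip + np.array([geom.thigh_length, 0.0, 0.0])
    coords[:, KP_INDEX[f"{geom.side}_knee"]] = knee
    th = np.radians(trace.angles)
    shank = geom.shank_length * np.stack(
        [np.cos(th), np.zeros(n), -np.sin(th)], axis=1
    )
    coords[:, KP_INDEX[f"{geom.side}_ankle"]] = knee + shank
    return coords


def _project_2d(coords: np.ndarray, geom: BodyGeometry, view: str) -> np.ndarray:
    """Orthographic camera projection to pixel coordinates (y-down).

    ``view='90'`` looks along the mediolateral axis (lateral view,
    angle-preserving for sagittal motion); ``view='45'`` is rotated 45°
    about the vertical, foreshortening the longitudinal axis.
    """
    phi = {"90": 0.0, "45": np.pi / 4}[str(view)]
    e1 = np.array([np.cos(phi), -np.sin(phi), 0.0])  # image x (horizontal)
    e2 = np.array([0.0, 0.0, -1.0])                  # image y (down)
    s = geom.pixels_per_m
    cx, cy = geom.image_center
    px = coords @ e1 * s + cx
    py = coords @ e2 * s + cy
    return np.stack([px, py], axis=-1)


def render_keypoints(
    trace: AngleTrace,
    geom: BodyGeometry | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    dims: int = 2,
    view: str = "90",
) -> KeypointTrajectory:
    """Render an angle trace as a noisy COCO-17 keypoint trajectory.

    3D output gives world coordinates (length units) with isotropic
    Gaussian noise; 2D output orthographically projects along the
    chosen camera view, adds pixel noise, and draws confidences near
    0.9 (all seeded, deterministic).
    """
    geom = geom or BodyGeometry(side=trace.side or "right")
    world = supine_keypoints_3d(trace, geom)
    rng = np.random.default_rng(seed)
    if dims == 3:
        coords = world + (rng.normal(0.0, noise_sd, world.shape) if noise_sd > 0 else 0.0)
        return KeypointTrajectory(coords=coords, fps=trace.fps, source_tag="3d-pose")
    if dims != 2:
        raise ValueError("dims must be 2 or 3")
    coords = _project_2d(world, geom, view)
    if noise_sd > 0:
        coords = coords + rng.normal(0.0, noise_sd, coords.shape)
    conf = np.clip(rng.normal(0.9, 0.03, coords.shape[:2]), 0.0, 1.0)
    return KeypointTrajectory(
        coords=coords, confidence=conf, fps=trace.fps, source_tag="2d-pose"
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortSpec:
    """Layout and dynamics of a synthetic multi-subject study.

    Defaults emulate a 20-subject protocol with five trials per limb
    and both limbs tested.  Affected-limb MAS levels are drawn from
    ``mas_probs``; each limb's damping ratio is drawn from the
    MAS-conditional band in ``zeta_by_mas`` (means increase with MAS —
    spasticity damps the swing).  The mapping is a synthetic, not a
    clinical, calibration: under P1 ≈ 1 + r it spans unaffected P1
    near 1.1 down to severely affected P1 near 0.7.
    """

    n_subjects: int = 20
    trials_per_limb: int = 5
    mas_probs: dict[float, float] = field(
        default_factory=lambda: {0.0: 0.15, 1.0: 0.35, 1.5: 0.25, 2.0: 0.25}
    )
    zeta_by_mas: dict[float, tuple[float, float]] = field(
        default_factory=lambda: {
            0.0: (0.10, 0.05),
            1.0: (0.25, 0.05),
            1.5: (0.35, 0.05),
            2.0: (0.45, 0.05),
        }
    )
    zeta_bounds: tuple[float, float] = (0.02, 0.95)
    zeta_trial_sd: float = 0.02
    gonio_noise_deg: float = 0.25
    pixel_noise: float = 1.5
    noise_3d: float = 0.005
    camera_view_2d: str = "90"
    duration_s: float = 15.0
    fps: float = 30.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.mas_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mas_probs must sum to 1, got {total}")
        means = [self.zeta_by_mas[m][0] for m in sorted(self.zeta_by_mas)]
        if any(b <= a for a, b in zip(means, means[1:])):
            raise ValueError("zeta means must increase with MAS")


def _truncated_normal(rng, mean, sd, lo, hi):
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return float(v)
    return float(np.clip(mean, lo, hi))


_MAS_LADDER = (0.0, 1.0, 1.5, 2.0)


def simulate_cohort(
    spec: CohortSpec, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a full synthetic study on disk.

    Per subject: one limb is affected (MAS drawn from ``mas_probs``,
    extensor tone driving ζ; flexor MAS one ladder step below with
    probability one-half), the other unaffected (MAS 0 band).  Each of
    the five trials per limb is emitted for all three devices —
    goniometer angle CSV (low noise), 2D keypoint JSON (pixel noise),
    and 3D keypoint JSON — all rendered from the *same* underlying
    trial trace, mirroring simultaneous recording.

    Returns the trial-metadata table and the per-limb ground-truth
    table (ζ and the analytic P1 = P3 = 1 + r); both are also written
    to ``trial_table.csv`` / ``ground_truth.csv``.  Fully deterministic
    per seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    mas_levels = sorted(spec.mas_probs)
    mas_p = [spec.mas_probs[m] for m in mas_levels]

    records: list[TrialMetadata] = []
    truth_rows = []
    for si in range(spec.n_subjects):
        subject_id = f"S{si + 1:02d}"
        affected_side = "left" if rng.random() < 0.5 else "right"
        rest = _truncated_normal(rng, 70.0, 4.0, 55.0, 85.0)
        for limb in ("left", "right"):
            affected = limb == affected_side
            if affected:
                mas_ext = float(rng.choice(mas_levels, p=mas_p))
                step = _MAS_LADDER.index(mas_ext)
                mas_flex = (
                    _MAS_LADDER[max(0, step - 1)] if rng.random() < 0.5 else mas_ext
                )
            else:
                mas_ext = mas_flex = 0.0
            mean, sd = spec.zeta_by_mas[mas_ext]
            zeta_limb = _truncated_normal(rng, mean, sd, *spec.zeta_bounds)
            truth_rows.append(
                {
                    "subject_id": subject_id,
                    "limb": limb,
                    "affected": affected,
                    "mas_extensor": mas_ext,
                    "zeta": zeta_limb,
                    "analytic_P1": 1.0 + half_cycle_decay_ratio(min(zeta_limb, 0.999)),
                    "analytic_P3": 1.0 + half_cycle_decay_ratio(min(zeta_limb, 0.999)),
                }
            )
            for trial in range(1, spec.trials_per_limb + 1):
                zeta_trial = float(
                    np.clip(rng.normal(zeta_limb, spec.zeta_trial_sd), *spec.zeta_bounds)
                )
                release = float(np.clip(rng.normal(0.0, 2.0), 0.0, 8.0))
                model = PendulumModel(
                    zeta=zeta_trial,
                    theta_rest=rest,
                    theta_release=release,
                    duration_s=spec.duration_s,
                    fps=spec.fps,
                )
                # Independent sub-seeds, all derived from the cohort rng.
                seeds = rng.integers(0, 2**31 - 1, size=3)
                stem = f"{subject_id}_{limb}_t{trial}"

                gonio = simulate_trace(
                    model, spec.gonio_noise_deg, int(seeds[0]),
                    device="goniometer", side=limb,
                )
                gpath = out / f"{stem}_gonio.csv"
                write_angle_csv(gonio, gpath)

                clean = simulate_trace(model, 0.0, 0, device="", side=limb)
                geom = BodyGeometry(side=limb)
                traj2d = render_keypoints(
                    clean, geom, noise_sd=spec.pixel_noise, seed=int(seeds[1]),
                    dims=2, view=spec.camera_view_2d,
                )
                p2path = out / f"{stem}_pose2d.json"
                write_keypoints_2d(traj2d, p2path)

                traj3d = render_keypoints(
                    clean, geom, noise_sd=spec.noise_3d, seed=int(seeds[2]), dims=3
                )
                p3path = out / f"{stem}_pose3d.json"
                write_keypoints_3d(traj3d, p3path)

                for device, path, view in (
                    ("goniometer", gpath, "none"),
                    ("pose2d", p2path, spec.camera_view_2d),
                    ("pose3d", p3path, "none"),
                ):
                    records.append(
                        TrialMetadata(
                            subject_id=subject_id,
                            limb=limb,
                            affected=affected,
                            mas_flexor=mas_flex,
                            mas_extensor=mas_ext,
                            device=device,
                            camera_view=view,
                            trial_index=trial,
                            path=str(path.name),
                        )
                    )

    write_trial_table(records, out / "trial_table.csv")
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "ground_truth.csv", index=False, float_format="%.6f")
    meta = pd.read_csv(out / "trial_table.csv")
    return meta, truth
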