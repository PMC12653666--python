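"""Knee flexion angle from keypoints, and trace smoothing.

2D route: the knee angle is the angle between the hip→knee vector u
and the knee→ankle vector v, θ = arccos(u·v / |u||v|), giving 0° at
full extension (collinear thigh and shank) and increasing with flexion.
The formula is invariant to translation, uniform scaling, and the
y-down image convention, so pixel coordinates are used as-is.

3D route: the sagittal plane is estimated from body-midline landmarks,
u and v are projected into that plane (their component along the plane
normal n is removed), and the same arccos formula is applied to the
in-plane components uh, vh.

Smoothing: a third-order Savitzky–Golay filter, which preserves the
peaks and troughs the landmark extraction depends on far better than a
moving average (it reproduces cubic polynomials exactly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

from .core import KP_INDEX, AngleTrace, KeypointTrajectory
from .errors import DegenerateGeometryError, ParameterError

#: Keypoints whose confidence gates a 2D frame (per analyzed side).
_LOWER_LIMB = {"left": ("left_hip", "left_knee", "left_ankle"),
               "right": ("right_hip", "right_knee", "right_ankle")}

#: Minimum vector norm (relative to segment scale) before geometry is
#: declared degenerate.
_NORM_TOL = 1e-9


def _angles_between(u: np.ndarray, v: np.ndarray, context: str) -> np.ndarray:
    """Per-frame angle in degrees between row vectors u and v.

    The cosine is clamped to [−1, 1] before arccos: floating-point
    overshoot on collinear frames must not raise a domain error.
    """
    nu = np.linalg.norm(u, axis=1)
    nv = np.linalg.norm(v, axis=1)
    bad = (nu < _NORM_TOL) | (nv < _NORM_TOL)
    if np.any(bad):
        frame = int(np.argmax(bad))
        raise DegenerateGeometryError(
            f"{context}: zero-length segment vector at frame {frame}",
            frame_index=frame,
        )
    cos = np.einsum("ij,ij->i", u, v) / (nu * nv)
    return np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))


def _side_indices(side: str) -> tuple[int, int, int]:
    if side not in _LOWER_LIMB:
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    hip, knee, ankle = _LOWER_LIMB[side]
    return KP_INDEX[hip], KP_INDEX[knee], KP_INDEX[ankle]


def _fill_low_confidence(
    angles: np.ndarray, conf: np.ndarray | None, idx: tuple[int, int, int],
    min_confidence: float,
) -> np.ndarray:
    """Linearly interpolate angles over frames with unreliable keypoints.

    Pose estimators occasionally lose a joint for a few frames; filling
    by interpolation keeps the sampling grid uniform for the smoother.
    """
    if conf is None or min_confidence <= 0:
        return angles
    flagged = np.min(conf[:, list(idx)], axis=1) < min_confidence
    if not flagged.any():
        return angles
    if flagged.all():
        raise DegenerateGeometryError(
            "all frames fall below the keypoint-confidence threshold"
        )
    t = np.arange(len(angles))
    out = angles.copy()
    out[flagged] = np.interp(t[flagged], t[~flagged], angles[~flagged])
    return out


def knee_angle_2d(
    traj: KeypointTrajectory,
    side: str,
    min_confidence: float = 0.3,
) -> AngleTrace:
    """Per-frame knee flexion angle from a 2D keypoint trajectory.

    Frames where any of the side's hip/knee/ankle confidences fall
    below ``min_confidence`` get their angle filled by linear
    interpolation from neighbouring reliable frames.
    """
    if traj.dims != 2:
        raise ValueError("knee_angle_2d requires a 2D trajectory")
    ih, ik, ia = _side_indices(side)
    u = traj.coords[:, ik] - traj.coords[:, ih]   # hip -> knee
    v = traj.coords[:, ia] - traj.coords[:, ik]   # knee -> ankle
    angles = _angles_between(u, v, "knee_angle_2d")
    angles = _fill_low_confidence(angles, traj.confidence, (ih, ik, ia), min_confidence)
    return AngleTrace(angles=angles, fps=traj.fps, side=side, device="pose2d")


def plane_normal(um: np.ndarray, vm: np.ndarray) -> np.ndarray:
    """Unit normal n = um × vm of the plane spanned by two vectors."""
    n = np.cross(um, vm)
    norm = np.linalg.norm(n)
    scale = np.linalg.norm(um) * np.linalg.norm(vm)
    if norm < 1e-9 * max(scale, 1e-30):
        raise DegenerateGeometryError(
            "degenerate plane: midline vectors are (near-)collinear"
        )
    return n / norm


@dataclass
class SegmentVectors:
    """Per-frame segment and midline vectors for the 3D angle route.

    Arrays are ``(n_frames, 3)``: u hip→knee, v knee→ankle, um and vm
    the body-midline vectors spanning the sagittal plane, n the unit
    plane normal, uh/vh the in-plane components of u and v.
    """

    u: np.ndarray
    v: np.ndarray
    um: np.ndarray
    vm: np.ndarray
    n: np.ndarray
    uh: np.ndarray | None = None
    vh: np.ndarray | None = None


def sagittal_plane(
    traj: KeypointTrajectory,
    side: str = "right",
    mode: str = "per_frame",
) -> SegmentVectors:
    """Estimate the sagittal plane from body-midline landmarks.

    The plane must contain the body's longitudinal axis and its
    anterior–posterior axis, so its normal points mediolaterally.  Two
    midline vectors span it: um = mid-shoulder → mid-hip (longitudinal)
    and vm = mid-shoulder → nose (tilted anteriorly — the nose is the
    only COCO-17 midline landmark off the trunk axis).  n = um × vm,
    normalized per frame; ``mode='averaged'`` replaces per-frame
    normals with the normalized mean normal, which is more robust to
    keypoint noise when the pelvis is static.
    """
    if traj.dims != 3:
        raise ValueError("sagittal_plane requires a 3D trajectory")
    if mode not in ("per_frame", "averaged"):
        raise ValueError(f"unknown plane mode {mode!r}")
    mid_shoulder = 0.5 * (traj.keypoint("left_shoulder") + traj.keypoint("right_shoulder"))
    mid_hip = 0.5 * (traj.keypoint("left_hip") + traj.keypoint("right_hip"))
    nose = traj.keypoint("nose")
    um = mid_hip - mid_shoulder
    vm = nose - mid_shoulder
    raw = np.cross(um, vm)
    norms = np.linalg.norm(raw, axis=1)
    scale = np.linalg.norm(um, axis=1) * np.linalg.norm(vm, axis=1)
    bad = norms < 1e-9 * np.maximum(scale, 1e-30)
    if np.any(bad):
        frame = int(np.argmax(bad))
        raise DegenerateGeometryError(
            f"degenerate sagittal plane (collinear midline vectors) at frame {frame}",
            frame_index=frame,
        )
    n = raw / norms[:, None]
    if mode == "averaged":
        mean_n = n.mean(axis=0)
        mean_norm = np.linalg.norm(mean_n)
        if mean_norm < 1e-9:
            raise DegenerateGeometryError("averaged plane normal vanishes")
        n = np.tile(mean_n / mean_norm, (traj.n_frames, 1))
    ih, ik, ia = _side_indices(side)
    u = traj.coords[:, ik] - traj.coords[:, ih]
    v = traj.coords[:, ia] - traj.coords[:, ik]
    return SegmentVectors(u=u, v=v, um=um, vm=vm, n=n)


def project_into_plane(vec: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Remove the component of ``vec`` along unit normal ``n`` (row-wise)."""
    return vec - np.einsum("ij,ij->i", vec, n)[:, None] * n


def knee_angle_3d(
    traj: KeypointTrajectory,
    side: str,
    plane_mode: str = "per_frame",
) -> AngleTrace:
    """Knee flexion angle from 3D keypoints via sagittal-plane projection.

    The thigh and shank vectors are projected into the sagittal plane
    (out-of-plane component removed) and the angle between the in-plane
    components is returned, same convention as the 2D route.
    """
    sv = sagittal_plane(traj, side=side, mode=plane_mode)
    sv.uh = project_into_plane(sv.u, sv.n)
    sv.vh = project_into_plane(sv.v, sv.n)
    # A segment (near-)perpendicular to the sagittal plane has no
    # meaningful in-plane direction.
    for name, h, orig in (("thigh", sv.uh, sv.u), ("shank", sv.vh, sv.v)):
        rel = np.linalg.norm(h, axis=1) / np.maximum(np.linalg.norm(orig, axis=1), 1e-30)
        if np.any(rel < 1e-6):
            frame = int(np.argmax(rel < 1e-6))
            raise DegenerateGeometryError(
                f"{name} segment perpendicular to the sagittal plane at frame {frame}",
                frame_index=frame,
            )
    angles = _angles_between(sv.uh, sv.vh, "knee_angle_3d")
    return AngleTrace(angles=angles, fps=traj.fps, side=side, device="pose3d")


def smooth(
    trace: AngleTrace,
    window_frames: int = 11,
    polyorder: int = 3,
) -> AngleTrace:
    """Savitzky–Golay smoothing of an angle trace.

    ``window_frames`` must be odd, larger than ``polyorder`` and no
    longer than the trace; edge frames are handled by polynomial fit on
    the truncated window, so the output has the same length.  The
    default 11-frame window (~0.37 s at 30 fps) suppresses keypoint
    jitter while preserving the ~1 Hz swing peaks.
    """
    n = len(trace)
    if window_frames % 2 == 0 or window_frames < 5:
        raise ParameterError(
            f"window_frames must be an odd integer >= 5, got {window_frames}"
        )
    if window_frames <= polyorder:
        raise ParameterError("window_frames must exceed polyorder")
    if window_frames > n:
        raise ParameterError(
            f"window_frames ({window_frames}) exceeds trace length ({n})"
        )
    sm = savgol_filter(trace.angles, window_frames, polyorder, mode="interp")
    return trace.replace_angles(np.clip(sm, 0.0, 180.0), smoothed=True)
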