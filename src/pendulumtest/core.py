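"""Core domain containers shared by the whole pipeline.

Two currencies flow through the package: raw keypoint trajectories
(what a pose-estimation network emits) and knee-angle time series
(what the goniometer records and what the kinematics module derives
from keypoints).  Everything downstream — landmark extraction,
pendulum parameters, agreement statistics — works on angle traces
or on per-trial parameter records.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# The 17-landmark COCO skeleton convention used by 2D and 3D pose
# estimators alike.  Order matters: keypoint files are indexed by it.
COCO_KEYPOINTS: tuple[str, ...] = (
    "nose",
    "left_eye",
    "right_eye",
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
)
KP_INDEX: dict[str, int] = {name: i for i, name in enumerate(COCO_KEYPOINTS)}
N_KEYPOINTS = len(COCO_KEYPOINTS)

#: Modified Ashworth Scale levels.  The clinical "1+" rating sits between
#: 1 and 2 and is stored as the distinct ordinal level 1.5.
MAS_LEVELS: tuple[float, ...] = (0.0, 1.0, 1.5, 2.0, 3.0, 4.0)
MAS_TOKEN_MAP: dict[str, float] = {
    "0": 0.0,
    "0.0": 0.0,
    "1": 1.0,
    "1.0": 1.0,
    "1+": 1.5,
    "1.5": 1.5,
    "2": 2.0,
    "2.0": 2.0,
    "3": 3.0,
    "3.0": 3.0,
    "4": 4.0,
    "4.0": 4.0,
}

DEVICES = ("goniometer", "pose2d", "pose3d")
SIDES = ("left", "right")
CAMERA_VIEWS = ("45", "90", "none")


@dataclass
class KeypointTrajectory:
    """Per-frame keypoint coordinates with optional confidences.

    Parameters
    ----------
    coords
        Array of shape ``(n_frames, 17, dims)`` with ``dims`` 2 or 3.
        2D coordinates are in pixels using the image convention
        (y increases downward); knee-angle computation is invariant to
        that choice, so no flip is applied.  3D coordinates are in any
        consistent length unit.
    confidence
        ``(n_frames, 17)`` per-keypoint scores in [0, 1]; present for
        2D detections only.
    fps
        Sampling rate of the source video, frames per second.
    frame_ids
        Optional original frame identifiers, strictly increasing.
    """

    coords: np.ndarray
    fps: float = 30.0
    confidence: np.ndarray | None = None
    source_tag: str = ""
    frame_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != N_KEYPOINTS:
            raise ValueError(
                f"coords must have shape (n_frames, {N_KEYPOINTS}, dims); "
                f"got {self.coords.shape}"
            )
        if self.coords.shape[2] not in (2, 3):
            raise ValueError(f"dims must be 2 or 3, got {self.coords.shape[2]}")
        if not (self.fps > 0):
            raise ValueError("fps must be positive")
        if self.confidence is not None:
            self.confidence = np.asarray(self.confidence, dtype=float)
            if self.confidence.shape != self.coords.shape[:2]:
                raise ValueError("confidence must have shape (n_frames, 17)")
            if np.any(self.confidence < 0) or np.any(self.confidence > 1):
                raise ValueError("confidences must lie in [0, 1]")
        if self.frame_ids is not None:
            self.frame_ids = np.asarray(self.frame_ids)
            if len(self.frame_ids) != len(self.coords):
                raise ValueError("frame_ids length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def dims(self) -> int:
        return self.coords.shape[2]

    def keypoint(self, name: str) -> np.ndarray:
        """Coordinates of one named keypoint across frames, ``(n_frames, dims)``."""
        return self.coords[:, KP_INDEX[name], :]


@dataclass
class AngleTrace:
    """Uniformly sampled knee-angle time series in degrees.

    The angle convention is 0° at full extension (thigh and shank
    collinear), increasing with flexion — the convention the hip–knee–
    ankle dot-product formula yields directly.  Goniometer exports using
    the 180°-at-extension clinical convention are converted on read.
    """

    angles: np.ndarray
    fps: float
    side: str = ""
    device: str = ""
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1:
            raise ValueError("angles must be one-dimensional")
        if len(self.angles) < 10:
            raise ValueError(
                f"trace too short to analyze: {len(self.angles)} samples (< 10)"
            )
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("angles must be finite")
        if self.angles.min() < -1e-9 or self.angles.max() > 180 + 1e-9:
            raise ValueError("angles must lie within [0, 180] degrees")
        self.angles = np.clip(self.angles, 0.0, 180.0)
        if not (self.fps > 0):
            raise ValueError("fps must be positive")

    def __len__(self) -> int:
        return len(self.angles)

    @property
    def duration_s(self) -> float:
        return len(self.angles) / self.fps

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.angles)) / self.fps

    def replace_angles(self, angles: np.ndarray, smoothed: bool | None = None) -> "AngleTrace":
        return AngleTrace(
            angles=angles,
            fps=self.fps,
            side=self.side,
            device=self.device,
            smoothed=self.smoothed if smoothed is None else smoothed,
        )


@dataclass(frozen=True)
class TrialMetadata:
    """One pendulum-test trial's identity and clinical context.

    ``mas_flexor`` / ``mas_extensor`` are Modified Ashworth Scale levels
    on the ordinal scale {0, 1, 1.5, 2, 3, 4} where 1.5 encodes the
    clinical "1+" rating.
    """

    subject_id: str
    limb: str
    affected: bool
    mas_flexor: float
    mas_extensor: float
    device: str
    camera_view: str
    trial_index: int
    path: str | None = None

    def __post_init__(self) -> None:
        if self.limb not in SIDES:
            raise ValueError(f"limb must be left|right, got {self.limb!r}")
        if self.device not in DEVICES:
            raise ValueError(f"unknown device {self.device!r}")
        if str(self.camera_view) not in CAMERA_VIEWS:
            raise ValueError(f"camera_view must be one of {CAMERA_VIEWS}")
        for mas in (self.mas_flexor, self.mas_extensor):
            if mas not in MAS_LEVELS:
                raise ValueError(f"MAS level {mas!r} not on the ordinal scale")
        if not (1 <= self.trial_index <= 5):
            raise ValueError("trial_index must lie in 1..5")

    @property
    def key(self) -> tuple:
        return (self.subject_id, self.limb, self.device, self.trial_index)
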