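"""Readers and writers for the file dialects the pipeline touches.

Supported dialects:

* AlphaPose-style 2D JSON: an array of per-detection objects
  ``{"image_id": ..., "keypoints": [x1, y1, s1, ..., x17, y17, s17],
  "score": ..., "idx": ...}`` in COCO-17 order.
* 3D keypoints: a JSON array of shape frames × 17 × 3, or a long CSV
  with ``frame, kp, x, y, z`` columns.
* Angle CSV: ``time_s, angle_deg`` columns, standing in for electronic
  goniometer exports.
* Trial table CSV: one row per recorded trial with subject, limb,
  MAS scores, device, camera view and the trial file path.

All dialects are plain text (comma separator, "." decimal, UTF-8,
header required for CSV).  Readers never silently drop frames: the
output frame count equals the input frame count or an error is raised.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    MAS_TOKEN_MAP,
    N_KEYPOINTS,
    AngleTrace,
    KeypointTrajectory,
    TrialMetadata,
)
from .errors import (
    DialectError,
    KeypointParseError,
    MultiPersonError,
    TrialTableError,
)

logger = logging.getLogger(__name__)

#: Relative jitter in the time column above which an angle CSV is
#: resampled onto a uniform grid.
JITTER_TOLERANCE = 0.01


def _frame_sort_key(image_id):
    """Sort frames numerically when identifiers look like '000012.jpg'."""
    s = str(image_id)
    digits = "".join(ch for ch in s if ch.isdigit())
    return (int(digits), s) if digits else (0, s)


def read_keypoints_2d(path: str | Path, fps: float = 30.0) -> KeypointTrajectory:
    """Read an AlphaPose-dialect 2D keypoint JSON file.

    Raises
    ------
    KeypointParseError
        Malformed JSON, naming the offending record where possible.
    DialectError
        Keypoint array length differs from 51 (x, y, score × 17).
    MultiPersonError
        A frame holds more than one person id; pre-filter to one
        tracked person (the pipeline is single-subject).
    """
    path = Path(path)
    try:
        records = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise KeypointParseError(f"{path}: malformed JSON ({exc})") from exc
    if not isinstance(records, list):
        raise KeypointParseError(f"{path}: expected a JSON array of detections")

    by_frame: dict = {}
    for i, rec in enumerate(records):
        if not isinstance(rec, dict) or "keypoints" not in rec or "image_id" not in rec:
            raise KeypointParseError(
                f"{path}: record {i} lacks 'image_id'/'keypoints' fields"
            )
        kps = rec["keypoints"]
        if len(kps) != 3 * N_KEYPOINTS:
            raise DialectError(
                f"{path}: record {i} (image_id={rec['image_id']!r}) has "
                f"{len(kps)} keypoint values, expected {3 * N_KEYPOINTS}"
            )
        fid = rec["image_id"]
        if fid in by_frame:
            raise MultiPersonError(
                f"{path}: frame {fid!r} holds multiple person detections; "
                "pre-filter the file to a single tracked person"
            )
        by_frame[fid] = np.asarray(kps, dtype=float).reshape(N_KEYPOINTS, 3)

    if not by_frame:
        raise KeypointParseError(f"{path}: no detections in file")
    order = sorted(by_frame, key=_frame_sort_key)
    arr = np.stack([by_frame[fid] for fid in order])
    conf = np.clip(arr[:, :, 2], 0.0, 1.0)
    return KeypointTrajectory(
        coords=arr[:, :, :2],
        confidence=conf,
        fps=fps,
        source_tag="2d-pose",
        frame_ids=np.arange(len(order)),
    )


def write_keypoints_2d(traj: KeypointTrajectory, path: str | Path) -> None:
    """Write a 2D trajectory in the AlphaPose JSON dialect."""
    if traj.dims != 2:
        raise ValueError("write_keypoints_2d requires a 2D trajectory")
    conf = traj.confidence
    if conf is None:
        conf = np.ones(traj.coords.shape[:2])
    # Round once up front so write -> read -> write is byte-stable.
    conf = np.round(conf, 6)
    coords = np.round(traj.coords, 6)
    records = []
    for f in range(traj.n_frames):
        flat = np.concatenate([coords[f], conf[f][:, None]], axis=1).ravel()
        records.append(
            {
                "image_id": f"{f:06d}.jpg",
                "keypoints": [float(v) for v in flat],
                "score": round(float(conf[f].mean()), 6),
                "idx": 0,
            }
        )
    Path(path).write_text(json.dumps(records))


def read_keypoints_3d(path: str | Path, fps: float = 30.0) -> KeypointTrajectory:
    """Read a 3D keypoint file (JSON frames×17×3 array, or long CSV).

    Raises an error listing the frame index if any frame misses a
    keypoint, and rejects non-finite coordinates.
    """
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        required = {"frame", "kp", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise DialectError(f"{path}: long CSV needs columns {sorted(required)}")
        frames = sorted(df["frame"].unique())
        arr = np.full((len(frames), N_KEYPOINTS, 3), np.nan)
        for fi, f in enumerate(frames):
            sub = df[df["frame"] == f]
            kps = set(sub["kp"])
            missing = set(range(N_KEYPOINTS)) - kps
            if missing:
                raise DialectError(
                    f"{path}: frame {f} missing keypoint(s) {sorted(missing)}"
                )
            for _, row in sub.iterrows():
                arr[fi, int(row["kp"])] = (row["x"], row["y"], row["z"])
    else:
        try:
            data = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise KeypointParseError(f"{path}: malformed JSON ({exc})") from exc
        try:
            arr = np.asarray(data, dtype=float)
        except (TypeError, ValueError) as exc:
            raise DialectError(
                f"{path}: not a frames x {N_KEYPOINTS} x 3 numeric array ({exc})"
            ) from exc
        if arr.ndim != 3 or arr.shape[1:] != (N_KEYPOINTS, 3):
            raise DialectError(
                f"{path}: expected frames x {N_KEYPOINTS} x 3 array, got {arr.shape}"
            )
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr).all(axis=(1, 2)))
        raise DialectError(
            f"{path}: non-finite coordinates in frame(s) {bad.ravel().tolist()}"
        )
    return KeypointTrajectory(coords=arr, fps=fps, source_tag="3d-pose")


def write_keypoints_3d(traj: KeypointTrajectory, path: str | Path) -> None:
    """Write a 3D trajectory as a JSON frames×17×3 array."""
    if traj.dims != 3:
        raise ValueError("write_keypoints_3d requires a 3D trajectory")
    data = [
        [[round(float(v), 6) for v in kp] for kp in frame]
        for frame in traj.coords
    ]
    Path(path).write_text(json.dumps(data))


def read_angle_csv(
    path: str | Path,
    convention: str = "extension_zero",
    device: str = "goniometer",
    side: str = "",
) -> AngleTrace:
    """Read a ``time_s, angle_deg`` CSV into an :class:`AngleTrace`.

    The sampling rate is inferred from the median time step.  Jitter in
    the time column beyond 1% of the median step triggers linear-
    interpolation resampling onto a uniform grid (with a logged notice).

    ``convention='extension_180'`` converts clinical 180°-at-extension
    angles to the internal extension-zero convention via 180° − angle.
    """
    df = pd.read_csv(path)
    for col in ("time_s", "angle_deg"):
        if col not in df.columns:
            raise DialectError(f"{path}: missing required column {col!r}")
    t = df["time_s"].to_numpy(dtype=float)
    angles = df["angle_deg"].to_numpy(dtype=float)
    if len(t) < 10:
        raise DialectError(f"{path}: trace too short to analyze ({len(t)} samples)")
    dt = np.diff(t)
    if np.any(dt <= 0):
        i = int(np.argmax(dt <= 0))
        raise DialectError(
            f"{path}: time column not strictly increasing at row {i + 1}"
        )
    med = float(np.median(dt))
    fps = 1.0 / med
    if np.max(np.abs(dt - med)) > JITTER_TOLERANCE * med:
        logger.info(
            "%s: non-uniform sampling (jitter > 1%%); resampling to uniform %.3f fps grid",
            path,
            fps,
        )
        grid = np.arange(t[0], t[-1] + med / 2, med)
        angles = np.interp(grid, t, angles)
    if convention == "extension_180":
        angles = 180.0 - angles
    elif convention != "extension_zero":
        raise ValueError(f"unknown angle convention {convention!r}")
    return AngleTrace(angles=angles, fps=fps, side=side, device=device)


def write_angle_csv(trace: AngleTrace, path: str | Path) -> None:
    """Write an angle trace as a ``time_s, angle_deg`` CSV."""
    df = pd.DataFrame({"time_s": trace.times, "angle_deg": trace.angles})
    df.to_csv(path, index=False, float_format="%.6f")


def read_trial_table(path: str | Path) -> list[TrialMetadata]:
    """Read and validate a trial-metadata CSV.

    MAS columns accept the clinical token "1+", stored as the ordinal
    level 1.5.  Duplicate (subject, limb, device, trial) keys are a
    hard error.
    """
    df = pd.read_csv(path, dtype=str).fillna("")
    required = {
        "subject_id",
        "limb",
        "affected",
        "mas_flexor",
        "mas_extensor",
        "device",
        "camera_view",
        "trial_index",
    }
    missing = required - set(df.columns)
    if missing:
        raise TrialTableError(f"{path}: missing column(s) {sorted(missing)}")

    records: list[TrialMetadata] = []
    seen: set[tuple] = set()
    for i, row in df.iterrows():
        mas = {}
        for col in ("mas_flexor", "mas_extensor"):
            token = str(row[col]).strip()
            if token not in MAS_TOKEN_MAP:
                raise TrialTableError(
                    f"{path}: row {i + 1}: unknown MAS token {token!r} in {col}"
                )
            mas[col] = MAS_TOKEN_MAP[token]
        try:
            rec = TrialMetadata(
                subject_id=str(row["subject_id"]),
                limb=str(row["limb"]),
                affected=str(row["affected"]).strip().lower() in ("true", "1", "yes"),
                mas_flexor=mas["mas_flexor"],
                mas_extensor=mas["mas_extensor"],
                device=str(row["device"]),
                camera_view=str(row["camera_view"]),
                trial_index=int(row["trial_index"]),
                path=str(row["path"]) if "path" in df.columns else None,
            )
        except ValueError as exc:
            raise TrialTableError(f"{path}: row {i + 1}: {exc}") from exc
        if rec.key in seen:
            raise TrialTableError(
                f"{path}: duplicate trial key {rec.key} at row {i + 1}"
            )
        seen.add(rec.key)
        records.append(rec)
    return records


def write_trial_table(records: Sequence[TrialMetadata], path: str | Path) -> None:
    """Write trial metadata as CSV (inverse of :func:`read_trial_table`)."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "limb": r.limb,
                "affected": r.affected,
                "mas_flexor": "1+" if r.mas_flexor == 1.5 else f"{r.mas_flexor:g}",
                "mas_extensor": "1+" if r.mas_extensor == 1.5 else f"{r.mas_extensor:g}",
                "device": r.device,
                "camera_view": r.camera_view,
                "trial_index": r.trial_index,
                "path": r.path or "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
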