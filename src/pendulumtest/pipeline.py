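"""End-to-end wiring: trial file → angle trace → parameters → study tables.

These functions are the single code path behind both the CLI and the
study-level analysis, so command-line results always equal library-API
results on identical inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import keypoint_io, kinematics, swing_analysis
from .agreement import StudyTables, study_report
from .config import RunConfig
from .core import AngleTrace, TrialMetadata
from .errors import OverdampedTraceError, PendulumTestError


def load_trace(
    path: str | Path,
    device: str,
    side: str = "right",
    cfg: RunConfig | None = None,
) -> AngleTrace:
    """Read a per-trial input file and return the raw angle trace."""
    cfg = cfg or RunConfig()
    if device == "goniometer":
        return keypoint_io.read_angle_csv(
            path, convention=cfg.angle.convention, side=side
        )
    if device == "pose2d":
        traj = keypoint_io.read_keypoints_2d(path)
        return kinematics.knee_angle_2d(
            traj, side, min_confidence=cfg.angle.min_confidence
        )
    if device == "pose3d":
        traj = keypoint_io.read_keypoints_3d(path)
        return kinematics.knee_angle_3d(traj, side, plane_mode=cfg.plane.mode)
    raise ValueError(f"unknown device {device!r}")


def trace_to_parameters(trace: AngleTrace, cfg: RunConfig | None = None) -> dict:
    """Smooth a trace and extract landmarks + pendulum parameters.

    Returns a flat record (A0, A1, A3, A4, rest_angle, P1, P2, P3,
    flags).  Overdamped traces yield a partial record with an
    ``overdamped`` flag instead of raising, so batch callers can count
    exclusions; :func:`swing_analysis.landmarks` still raises when
    called directly.
    """
    cfg = cfg or RunConfig()
    sm = kinematics.smooth(
        trace, cfg.smoothing.window_frames, cfg.smoothing.polyorder
    )
    record: dict = {
        "A0": np.nan, "A1": np.nan, "A3": np.nan, "A4": np.nan,
        "rest_angle": np.nan,
        "P1": np.nan, "P2": np.nan, "P3": np.nan,
        "flags": "",
    }
    extra_flags: list[str] = []
    try:
        # The settling warning becomes a per-trial quality flag here so
        # batch runs are not flooded; direct API calls still warn.
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            lm, params = swing_analysis.analyze_trace(
                sm,
                min_prominence_deg=cfg.extrema.min_prominence_deg,
                tail_seconds=cfg.rest.tail_seconds,
            )
        if any("settled" in str(w.message) for w in caught):
            extra_flags.append("unsettled_rest")
    except OverdampedTraceError as exc:
        lm = exc.partial
        if lm is not None:
            record.update(
                {k: v for k, v in asdict(lm).items()
                 if k in ("A0", "A1", "A3", "A4", "rest_angle") and v is not None}
            )
            record["flags"] = ";".join((*lm.flags,)) or "overdamped"
        else:
            record["flags"] = "overdamped"
        return record
    record.update(A0=lm.A0, A1=lm.A1, A3=lm.A3, A4=lm.A4, rest_angle=lm.rest_angle)
    record.update(
        P1=params.P1, P2=params.P2,
        P3=params.P3 if params.P3 is not None else np.nan,
    )
    record["flags"] = ";".join((*params.flags, *extra_flags))
    return record


def process_trial(meta: TrialMetadata, base_dir: Path, cfg: RunConfig | None = None) -> dict:
    """Full record for one trial-table row (metadata + parameters)."""
    if not meta.path:
        raise PendulumTestError(f"trial {meta.key} has no input path")
    path = base_dir / meta.path
    if not path.exists():
        raise PendulumTestError(f"trial {meta.key}: input file {path} not found")
    trace = load_trace(path, meta.device, meta.limb, cfg)
    record = {
        "subject_id": meta.subject_id,
        "limb": meta.limb,
        "affected": meta.affected,
        "mas_flexor": meta.mas_flexor,
        "mas_extensor": meta.mas_extensor,
        "device": meta.device,
        "camera_view": meta.camera_view,
        "trial_index": meta.trial_index,
    }
    record.update(trace_to_parameters(trace, cfg))
    return record


def run_study(
    trial_table: str | Path,
    cfg: RunConfig | None = None,
) -> tuple[pd.DataFrame, StudyTables]:
    """Process every trial in a table and build the study report.

    Returns the per-trial parameter records and the three result
    tables.  Trials whose swing never oscillates stay in the record
    table with NaN parameters and an ``overdamped`` flag; the reporting
    layer drops them cell-wise (complete-case), never silently.
    """
    cfg = cfg or RunConfig()
    trial_table = Path(trial_table)
    metas = keypoint_io.read_trial_table(trial_table)
    base = trial_table.parent
    records = pd.DataFrame([process_trial(m, base, cfg) for m in metas])
    tables = study_report(
        records,
        icc_form=cfg.agreement.icc_form,
        iqr_scope=cfg.agreement.iqr_scope,
    )
    return records, tables
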