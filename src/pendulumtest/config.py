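"""Validated run configuration (YAML file and/or keyword overrides)."""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SmoothingConfig(_Strict):
    window_frames: int = Field(default=11, ge=5)
    polyorder: int = Field(default=3, ge=1)


class ExtremaConfig(_Strict):
    min_prominence_deg: float = Field(default=1.0, gt=0)


class RestConfig(_Strict):
    tail_seconds: float = Field(default=1.0, gt=0)


class PlaneConfig(_Strict):
    mode: Literal["per_frame", "averaged"] = "per_frame"


class AngleConfig(_Strict):
    convention: Literal["extension_zero", "extension_180"] = "extension_zero"
    min_confidence: float = Field(default=0.3, ge=0.0, le=1.0)


class AgreementConfig(_Strict):
    icc_form: Literal["consistency", "absolute"] = "consistency"
    iqr_scope: Literal["per_stratum", "global"] = "per_stratum"


class RunConfig(_Strict):
    """All pipeline knobs; unknown keys are rejected at load time."""

    smoothing: SmoothingConfig = Field(default_factory=SmoothingConfig)
    extrema: ExtremaConfig = Field(default_factory=ExtremaConfig)
    rest: RestConfig = Field(default_factory=RestConfig)
    plane: PlaneConfig = Field(default_factory=PlaneConfig)
    angle: AngleConfig = Field(default_factory=AngleConfig)
    agreement: AgreementConfig = Field(default_factory=AgreementConfig)
    log_level: str = "INFO"


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config file; ``overrides`` are dotted-section dicts."""
    data: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ValueError(f"{path}: config must be a YAML mapping")
            data = loaded
    for key, value in overrides.items():
        if isinstance(value, dict) and isinstance(data.get(key), dict):
            data[key] = {**data[key], **value}
        else:
            data[key] = value
    return RunConfig.model_validate(data)
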