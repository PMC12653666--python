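"""Typed exceptions shared across the pipeline.

The CLI maps these onto its exit-code contract: dialect/parse problems
exit 2, analyzable-but-degenerate traces exit 3.
"""

from __future__ import annotations


class PendulumTestError(Exception):
    """Base class for all package errors."""


class DialectError(PendulumTestError):
    """An input file does not follow the expected dialect."""


class KeypointParseError(DialectError):
    """Malformed JSON/CSV content; message names the offending record."""


class MultiPersonError(DialectError):
    """More than one tracked person in a frame.

    The pendulum-test protocol guarantees a single subject in frame, so
    multi-person files must be pre-filtered to one tracked person id.
    """


class TrialTableError(PendulumTestError):
    """Invalid trial-metadata table (unknown MAS token, duplicate key, ...)."""


class DegenerateGeometryError(PendulumTestError):
    """Zero-length segment or degenerate plane; carries the frame index."""

    def __init__(self, message: str, frame_index: int | None = None):
        super().__init__(message)
        self.frame_index = frame_index


class ParameterError(PendulumTestError, ValueError):
    """Invalid analysis parameter (e.g. even smoothing window)."""


class OverdampedTraceError(PendulumTestError):
    """The trace never oscillates, so swing landmarks are undefined.

    Severe spasticity can damp the swing completely; study-level code
    counts such exclusions explicitly.  ``partial`` carries whatever
    landmarks were computable (possibly none).
    """

    def __init__(self, message: str, partial=None):
        super().__init__(message)
        self.partial = partial


class UndefinedOracleError(PendulumTestError):
    """Closed-form oscillation oracle requested for a non-oscillating model."""
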