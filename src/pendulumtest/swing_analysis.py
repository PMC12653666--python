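"""Swing landmarks and pendulum parameters from an angle–time curve.

In the pendulum test the relaxed lower leg is released from full knee
extension and swings freely; the knee angle traces a decaying
oscillation around the natural resting angle.  On the flexion-positive,
extension-zero angle axis the leg's physical *lowest* point is maximal
knee flexion, i.e. a local *maximum* of θ, and the swing's highest
points are local minima.

Landmarks (all in degrees, referenced as stated):

* A0 — angular distance between the raised release position and the
  natural resting position (the baseline range of movement).
* A1 — maximum angular change of the first swing, from the starting
  position to the first swing's lowest pendular point (first flexion
  peak).
* A3 — offset of the second swing's peak from the resting position
  (energy retained after one full swing).
* A4 — excursion of the second swing cycle, from its highest to its
  lowest point.

Pendulum parameters:

* P1 = A1/A0 — normalized relaxation index; lower with greater
  spasticity.
* P2 = A3 — first maximum of oscillation, in degrees.
* P3 = A4/A3 — relaxation index at half swing, an energy-retention
  ratio.

For a noise-free linear damped oscillator with half-cycle decay ratio
r = exp(−πζ/√(1−ζ²)) these evaluate to P1 = P3 = 1 + r and
P2 = A0·r², which the simulator's closed-form oracle exploits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .core import AngleTrace
from .errors import OverdampedTraceError, ParameterError

#: Default prominence (degrees) an extremum must have to be accepted:
#: below typical pose-estimation jitter after smoothing, above
#: numerical ripple.
DEFAULT_MIN_PROMINENCE_DEG = 1.0

#: Default settling window (seconds) for the resting-angle estimate.
DEFAULT_TAIL_SECONDS = 1.0

#: Tail-window variance (deg²) above which the trace may not have
#: settled; a warning is emitted, the estimate is still returned.
REST_VARIANCE_WARN = 5.0


@dataclass(frozen=True)
class Extremum:
    """One accepted local extremum of the smoothed angle curve."""

    frame_index: int
    angle: float
    kind: str  # "peak" (maximal flexion) | "trough" (maximal extension)


@dataclass
class SwingLandmarks:
    """Angular landmarks of one pendulum trial with their provenance."""

    A0: float
    A1: float | None = None
    A3: float | None = None
    A4: float | None = None
    rest_angle: float = float("nan")
    extrema_used: tuple[Extremum, ...] = field(default_factory=tuple)
    flags: tuple[str, ...] = field(default_factory=tuple)


@dataclass
class PendulumParameters:
    """P1, P2, P3 for one trial (P3 may be undefined when A3 = 0)."""

    P1: float
    P2: float
    P3: float | None
    flags: tuple[str, ...] = field(default_factory=tuple)


def find_extrema(
    trace: AngleTrace,
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
) -> list[Extremum]:
    """Locate alternating local maxima and minima of the angle curve.

    Peaks (maximal flexion) and troughs (maximal extension) with
    prominence >= ``min_prominence_deg`` are merged in temporal order;
    where prominence filtering leaves two like extrema in a row, the
    more extreme one is kept.  The release sample — the global start,
    maximal extension, i.e. minimum θ — is prepended as the initial
    extremum.  Ties on a plateau resolve to the plateau's first frame.

    Raises
    ------
    OverdampedTraceError
        No interior extremum beyond the start: the trace is monotone
        (no oscillation) and swing landmarks are undefined.
    """
    x = trace.angles
    # plateau_size=1 makes scipy report plateau edges; the left edge is
    # the plateau's first frame (deterministic tie-break).
    _, pprops = find_peaks(x, prominence=min_prominence_deg, plateau_size=1)
    peaks = pprops["left_edges"]
    _, tprops = find_peaks(-x, prominence=min_prominence_deg, plateau_size=1)
    troughs = tprops["left_edges"]
    merged = sorted(
        [(int(i), "peak") for i in peaks] + [(int(i), "trough") for i in troughs]
    )
    # Enforce alternation: among consecutive like-kind extrema keep the
    # most extreme (highest peak / lowest trough).
    cleaned: list[tuple[int, str]] = []
    for idx, kind in merged:
        if cleaned and cleaned[-1][1] == kind:
            prev_idx, _ = cleaned[-1]
            better = (x[idx] > x[prev_idx]) if kind == "peak" else (x[idx] < x[prev_idx])
            if better:
                cleaned[-1] = (idx, kind)
        else:
            cleaned.append((idx, kind))
    if not cleaned:
        raise OverdampedTraceError(
            "no oscillation detected (monotone or overdamped trace); "
            "swing landmarks are undefined"
        )
    out = [Extremum(frame_index=0, angle=float(x[0]), kind="trough")]
    for idx, kind in cleaned:
        if idx == 0:
            continue
        out.append(Extremum(frame_index=idx, angle=float(x[idx]), kind=kind))
    if len(out) < 2:
        raise OverdampedTraceError(
            "no interior extrema beyond the release sample"
        )
    return out


def resting_angle(
    trace: AngleTrace,
    tail_seconds: float = DEFAULT_TAIL_SECONDS,
) -> float:
    """Natural resting angle: mean over the final settling window.

    By the end of the recording the oscillation has decayed and the
    limb hangs at its natural resting position.  If the tail window
    still varies by more than 5 deg² a warning is emitted (the trace
    may not have settled) but the mean is returned regardless.
    """
    n_tail = int(round(tail_seconds * trace.fps))
    if n_tail < 1 or n_tail > len(trace):
        raise ParameterError(
            f"tail window of {tail_seconds} s ({n_tail} samples) does not fit "
            f"a trace of {len(trace)} samples"
        )
    tail = trace.angles[-n_tail:]
    if float(np.var(tail)) > REST_VARIANCE_WARN:
        warnings.warn(
            "resting-angle tail window has not settled "
            f"(variance {np.var(tail):.1f} deg^2 > {REST_VARIANCE_WARN})",
            stacklevel=2,
        )
    return float(np.mean(tail))


def landmarks(
    trace: AngleTrace,
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    tail_seconds: float = DEFAULT_TAIL_SECONDS,
    rest_angle: float | None = None,
) -> SwingLandmarks:
    """Extract A0, A1, A3, A4 from a (smoothed) angle trace.

    The release-frame angle is taken as the starting position, and the
    resting angle comes from :func:`resting_angle` unless supplied.
    With e1 the first flexion peak, e2 the following extension trough
    and e3 the following flexion peak:

    * A0 = |release − rest|
    * A1 = |e1 − release|
    * A3 = |e2 − rest|
    * A4 = |e3 − e2|

    Raises
    ------
    OverdampedTraceError
        Fewer than three interior extrema.  The exception's ``partial``
        attribute carries whatever landmarks were computable (always
        A0; A1 if a first peak exists), so study-level code can count
        exclusions explicitly instead of receiving silent NaNs.
    """
    theta_start = float(trace.angles[0])
    theta_rest = (
        resting_angle(trace, tail_seconds) if rest_angle is None else float(rest_angle)
    )
    A0 = abs(theta_start - theta_rest)
    flags: list[str] = []

    try:
        extrema = find_extrema(trace, min_prominence_deg)
    except OverdampedTraceError as exc:
        raise OverdampedTraceError(
            str(exc),
            partial=SwingLandmarks(A0=A0, rest_angle=theta_rest, flags=("overdamped",)),
        ) from exc

    interior = extrema[1:]
    if interior and interior[0].kind != "peak":
        # The release is maximal extension, so the first genuine swing
        # extremum must be a flexion peak; anything else is a spurious
        # early trough.
        flags.append("leading_trough_dropped")
        interior = interior[1:]

    if len(interior) >= 1:
        e1 = interior[0]
        A1 = abs(e1.angle - theta_start)
    else:
        A1 = None
    if len(interior) < 3:
        raise OverdampedTraceError(
            f"only {len(interior)} interior extrema; second swing absent",
            partial=SwingLandmarks(
                A0=A0, A1=A1, rest_angle=theta_rest,
                extrema_used=tuple(extrema), flags=("overdamped", *flags),
            ),
        )
    e1, e2, e3 = interior[0], interior[1], interior[2]
    return SwingLandmarks(
        A0=A0,
        A1=abs(e1.angle - theta_start),
        A3=abs(e2.angle - theta_rest),
        A4=abs(e3.angle - e2.angle),
        rest_angle=theta_rest,
        extrema_used=(extrema[0], e1, e2, e3),
        flags=tuple(flags),
    )


def pendulum_parameters(lm: SwingLandmarks) -> PendulumParameters:
    """P1 = A1/A0, P2 = A3, P3 = A4/A3 from extracted landmarks.

    A0 = 0 makes every ratio undefined and is an error; A3 = 0 only
    undefines P3, which is returned as ``None`` with a flag while P1
    and P2 are still reported.
    """
    if lm.A0 is None or lm.A0 <= 0:
        raise ParameterError("A0 must be positive to normalize P1")
    if lm.A1 is None or lm.A3 is None or lm.A4 is None:
        raise ParameterError("incomplete landmarks; cannot form parameters")
    P1 = lm.A1 / lm.A0
    P2 = lm.A3
    flags: list[str] = list(lm.flags)
    if lm.A3 > 0:
        P3 = lm.A4 / lm.A3
    else:
        P3 = None
        flags.append("P3_undefined_A3_zero")
    return PendulumParameters(P1=P1, P2=P2, P3=P3, flags=tuple(flags))


def analyze_trace(
    trace: AngleTrace,
    min_prominence_deg: float = DEFAULT_MIN_PROMINENCE_DEG,
    tail_seconds: float = DEFAULT_TAIL_SECONDS,
) -> tuple[SwingLandmarks, PendulumParameters]:
    """Landmarks + parameters in one call (convenience for the CLI)."""
    lm = landmarks(trace, min_prominence_deg=min_prominence_deg, tail_seconds=tail_seconds)
    return lm, pendulum_parameters(lm)
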