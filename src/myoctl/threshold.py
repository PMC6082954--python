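"""Direct (amplitude-threshold) control.

One sensor's EMA envelope ``Y_t`` is compared against a threshold pair
``(theta_high, theta_low)``: muscle weakness (``Y < theta_low``) commands
the hand to open, tension (``Y > theta_high``) commands a grasp, and the
insensitive band between the thresholds issues no new command — the motion
active just before entering the band is held (latched).  An external
assistant nudges either threshold in fixed steps of 0.25/100 V; the pair
must always satisfy ``0.25 > theta_high > theta_low > 0`` strictly, and an
adjustment that would break the ordering is rejected outright.  The
assistant can also override the commanded motion manually.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import MotionLabel

__all__ = [
    "THETA_MAX",
    "ADJUST_STEP",
    "ThresholdPair",
    "AdjustCommand",
    "AdjustmentRejected",
    "ControllerState",
    "classify_amplitude",
    "latched_motion",
    "latched_motion_series",
    "adjust_thresholds",
    "fit_thresholds",
]

THETA_MAX = 0.25  # V, upper bound of the valid threshold range
ADJUST_STEP = THETA_MAX / 100.0  # 0.0025 V per assistant command


class AdjustmentRejected(ValueError):
    """A threshold adjustment would violate 0.25 > θ_high > θ_low > 0."""


@dataclass(frozen=True)
class ThresholdPair:
    theta_high: float
    theta_low: float

    def __post_init__(self) -> None:
        if not (THETA_MAX > self.theta_high > self.theta_low > 0.0):
            raise ValueError(
                f"thresholds must satisfy {THETA_MAX} > theta_high > theta_low > 0, "
                f"got ({self.theta_high}, {self.theta_low})"
            )


@dataclass(frozen=True)
class AdjustCommand:
    """Assistant's three-level nudge for each threshold: −1, 0 or +1."""

    delta_high: int = 0
    delta_low: int = 0

    def __post_init__(self) -> None:
        if self.delta_high not in (-1, 0, 1) or self.delta_low not in (-1, 0, 1):
            raise ValueError("deltas must be -1, 0 or +1")


@dataclass
class ControllerState:
    """Mutable latch state of the direct controller."""

    thresholds: ThresholdPair
    last_active_motion: MotionLabel = MotionLabel.REST
    manual_override: MotionLabel | None = None


def classify_amplitude(y: float, thresholds: ThresholdPair) -> MotionLabel:
    """Raw motion identifier from the envelope feature.

    Returns stop/rest inside the closed dead band
    ``theta_low <= Y <= theta_high``, open below it, grasp above it.
    """
    if y < 0:
        raise ValueError("envelope feature Y must be non-negative")
    if y < thresholds.theta_low:
        return MotionLabel.OPEN
    if y > thresholds.theta_high:
        return MotionLabel.GRASP
    return MotionLabel.REST


def latched_motion(y: float, state: ControllerState) -> MotionLabel:
    """Commanded motion with dead-band latching and manual override.

    An active raw decision (open/grasp) is output and remembered; inside the
    dead band the motion active just before entering it is re-issued.  A set
    ``manual_override`` wins over everything.  Mutates ``state``.
    """
    if state.manual_override is not None:
        return state.manual_override
    raw = classify_amplitude(y, state.thresholds)
    if raw is not MotionLabel.REST:
        state.last_active_motion = raw
        return raw
    return state.last_active_motion


def latched_motion_series(y_series, thresholds: ThresholdPair) -> np.ndarray:
    """Latched decisions for a whole envelope series (initial latch = rest)."""
    state = ControllerState(thresholds=thresholds)
    return np.array([int(latched_motion(float(y), state)) for y in y_series], dtype=np.int8)


def adjust_thresholds(thresholds: ThresholdPair, cmd: AdjustCommand) -> ThresholdPair:
    """Apply one assistant command: each threshold moves by ±0.0025 V or holds.

    Raises :class:`AdjustmentRejected` (leaving the pair unchanged) if the
    result would violate the strict ordering constraint.
    """
    new_high = thresholds.theta_high + ADJUST_STEP * cmd.delta_high
    new_low = thresholds.theta_low + ADJUST_STEP * cmd.delta_low
    if not (THETA_MAX > new_high > new_low > 0.0):
        raise AdjustmentRejected(
            f"adjustment to ({new_high:.4f}, {new_low:.4f}) violates the ordering constraint"
        )
    return ThresholdPair(theta_high=new_high, theta_low=new_low)


def fit_thresholds(open_y, rest_y, grasp_y) -> ThresholdPair:
    """Scripted auto-assistant: place thresholds between class envelopes.

    A deterministic surrogate for the human assistant used by the automated
    evaluation harness: given short calibration recordings of the envelope
    during open (weak), rest and grasp (tense) effort, each threshold is set
    at the midpoint between the medians of the adjacent classes, clamped to
    the valid range.
    """
    m_open = float(np.median(open_y))
    m_rest = float(np.median(rest_y))
    m_grasp = float(np.median(grasp_y))
    if not (m_open < m_rest < m_grasp):
        raise ValueError("calibration envelopes must be ordered open < rest < grasp")
    eps = 1e-6
    low = np.clip((m_open + m_rest) / 2, eps, THETA_MAX - 2 * eps)
    high = np.clip((m_rest + m_grasp) / 2, low + eps, THETA_MAX - eps)
    return ThresholdPair(theta_high=float(high), theta_low=float(low))
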