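"""Incremental position and force support controllers.

Every 25 ms the classifier emits a (class, PC) pair from the preceding 200 ms
of EMG.  The position controller converts abduction/adduction decisions into
a vertical velocity held over the decision interval (z changes by
gain · PC · Δt); the force controller makes a per-decision increment to the
robot's vertical support force (F changes by gain · PC).  No-movement leaves
the state untouched.  Gains differ between the up and down directions and
between the two modes — users typically need a faster lift than lower — and
all commands are clamped to the virtual-surface position limits or to
[0, F_max], with F_max defaulting to the limb weight (beyond it the robot
would lift the arm passively).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import classifier as clf
from .classifier import ClassifierModel, Decision, classify
from .features import extract_features
from .signal import EmgRecording, condition_signal, segment_windows

__all__ = [
    "Gains",
    "ControllerState",
    "position_step",
    "force_step",
    "run_decision_loop",
    "adapt_gains",
    "TrialSummary",
]

DECISION_PERIOD_MS = 25.0
WINDOW_MS = 200.0


@dataclass
class Gains:
    """Per-direction proportional-control gains.

    Position mode: m/s of commanded velocity per PC unit.
    Force mode: N of force increment per decision per PC unit.
    """

    up: float
    down: float
    g_min: float = 1e-4
    g_max: float = 10.0

    def __post_init__(self) -> None:
        if self.up < 0 or self.down < 0:
            raise ValueError("gains must be non-negative")


@dataclass
class ControllerState:
    mode: str                       # "position" | "force"
    gains: Gains
    z: float = 0.0
    F: float = 0.0
    z_limits: tuple[float, float] = (-0.15, 0.15)
    F_limits: tuple[float, float] = (0.0, 30.0)
    decision_period_ms: float = DECISION_PERIOD_MS
    rate_limit: float | None = None  # optional max |command| per decision
    log: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("position", "force"):
            raise ValueError(f"mode must be 'position' or 'force', got {self.mode!r}")
        lo, hi = self.z_limits
        if not lo <= self.z <= hi and self.mode == "position":
            raise ValueError("initial z outside z_limits")


def _command(decision: Decision, gain_up: float, gain_down: float) -> float:
    if decision.class_label == "abduction":
        return gain_up * decision.pc
    if decision.class_label == "adduction":
        return -gain_down * decision.pc
    return 0.0


def position_step(state: ControllerState, decision: Decision) -> ControllerState:
    """Apply one decision to the vertical position; z is held rigidly until
    the next decision."""
    if state.mode != "position":
        raise ValueError("position_step requires a position-mode state")
    dt = state.decision_period_ms / 1000.0
    cmd = _command(decision, state.gains.up, state.gains.down) * dt
    if state.rate_limit is not None:
        cmd = float(np.clip(cmd, -state.rate_limit, state.rate_limit))
    lo, hi = state.z_limits
    new_z = min(max(state.z + cmd, lo), hi)
    state.log.append((decision.time_ms, decision.class_label, decision.pc,
                      new_z - state.z))
    state.z = new_z
    return state


def force_step(state: ControllerState, decision: Decision) -> ControllerState:
    """Apply one decision as an increment to the vertical support force."""
    if state.mode != "force":
        raise ValueError("force_step requires a force-mode state")
    cmd = _command(decision, state.gains.up, state.gains.down)
    if state.rate_limit is not None:
        cmd = float(np.clip(cmd, -state.rate_limit, state.rate_limit))
    lo, hi = state.F_limits
    new_F = min(max(state.F + cmd, lo), hi)
    state.log.append((decision.time_ms, decision.class_label, decision.pc,
                      new_F - state.F))
    state.F = new_F
    return state


def controller_step(state: ControllerState, decision: Decision) -> ControllerState:
    return (position_step if state.mode == "position" else force_step)(state, decision)


def run_decision_loop(
    recording: EmgRecording,
    model: ClassifierModel,
    state: ControllerState,
    robot=None,
    *,
    window_ms: float = WINDOW_MS,
    precondition: bool = True,
) -> list[Decision]:
    """Replay a recorded EMG stream through the 25 ms decision loop.

    The stream is conditioned causally (as the real-time filter would),
    windowed at the decision cadence — first decision at t = window_ms — and
    each decision steps the controller and, when given, a robot simulator
    exposing ``command_position(z)`` or ``command_force(F)``.
    """
    if recording.duration_ms < window_ms:
        raise ValueError("stream shorter than one analysis window")
    cond = condition_signal(recording, mode="causal") if precondition else recording
    decisions: list[Decision] = []
    for win in segment_windows(cond, window_ms, state.decision_period_ms):
        fv = extract_features(win, model.thresholds)
        t_decision = win.start_time_ms + window_ms
        d = classify(fv, model, time_ms=t_decision)
        controller_step(state, d)
        if robot is not None:
            if state.mode == "position":
                robot.command_position(state.z)
            else:
                robot.command_force(state.F)
        decisions.append(d)
    return decisions


@dataclass
class TrialSummary:
    """Per-trial flags feeding the gain-adjustment heuristic."""

    ceiling_slam: bool = False   # arm driven straight into the ceiling limit
    arm_lagging: bool = False    # user waiting on the robot / elbow lifting off


def adapt_gains(summary: TrialSummary, gains: Gains) -> Gains:
    """Between-trial gain tuning: lower on ceiling slams (×0.8), raise when
    the user outruns the robot (×1.25), bounded to [g_min, g_max]."""
    factor = 1.0
    if summary.ceiling_slam:
        factor *= 0.8
    if summary.arm_lagging:
        factor *= 1.25
    clip = lambda g: min(max(g * factor, gains.g_min), gains.g_max)
    if factor == 1.0:
        return gains
    return replace(gains, up=clip(gains.up), down=clip(gains.down))
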