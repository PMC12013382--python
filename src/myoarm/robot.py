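"""Simulated admittance robot and arm kinematics for vertical arm support.

The real apparatus is an admittance-controlled haptic robot holding the
casted forearm of a seated user through a load cell.  Here the vertical
degree of freedom is a lumped 1-DOF mass under gravity with damping; virtual
rigid surfaces clamp motion between 70° and 100° shoulder abduction.
Horizontal motion (shoulder horizontal adduction, elbow flexion/extension) is
treated quasi-statically — the synthetic subject drives those joints
directly, and they do not feed back into the vertical dynamics.

Sign conventions: upward forces positive; the load-cell reading is negative
when the limb bears down on its support (an arm resting passively on the
tabletop reads about −W).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ArmModel",
    "ArmPose",
    "TrialRecord",
    "CONDITIONS",
    "abduction_to_height",
    "height_to_abduction",
    "reach_distance",
    "VerticalRobot",
    "make_condition",
]

GRAVITY = 9.81

#: the five support conditions
CONDITIONS = ("table", "position", "no_support", "force", "limb_weight")

#: virtual rigid surfaces protecting the shoulder, degrees of abduction
ABD_FLOOR_DEG = 70.0
ABD_CEILING_DEG = 100.0
#: vertical task window for the reach, degrees of abduction
TARGET_WINDOW_DEG = (80.0, 100.0)


@dataclass
class ArmModel:
    """Anthropometric and mechanical parameters of the supported limb."""

    L_u: float = 0.30      # upper-arm length, m
    L_f: float = 0.35      # forearm + hand length, m
    W: float = 30.0        # limb weight, N
    b: float = 25.0        # vertical damping at the end effector, N·s/m
    m_eff: float | None = None  # effective vertical mass, kg (default W/g)

    def __post_init__(self) -> None:
        if min(self.L_u, self.L_f, self.W) <= 0:
            raise ValueError("lengths and limb weight must be positive")
        if self.m_eff is None:
            self.m_eff = self.W / GRAVITY
        if self.m_eff <= 0:
            raise ValueError("effective mass must be positive")


@dataclass
class ArmPose:
    """Joint configuration: abduction and horizontal adduction of the
    shoulder (deg) and elbow flexion (deg, 0 = full extension)."""

    theta_abd: float = ABD_FLOOR_DEG
    theta_h: float = 30.0
    phi_e: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta_abd <= 180.0:
            raise ValueError(f"theta_abd {self.theta_abd} outside [0, 180]")
        if not 0.0 <= self.phi_e <= 160.0:
            raise ValueError(f"phi_e {self.phi_e} outside [0, 160]")


@dataclass
class TrialRecord:
    """Synchronized time series for one lift-reach-return-lower trial."""

    time_ms: np.ndarray
    theta_abd: np.ndarray
    theta_h: np.ndarray
    phi_e: np.ndarray
    z: np.ndarray
    F_applied: np.ndarray
    F_sensed: np.ndarray
    emg: np.ndarray               # raw synthetic EMG, (n, n_channels)
    fs: float
    condition: str
    trial_id: str = ""
    decisions: list = field(default_factory=list)
    truncated: bool = False

    def __post_init__(self) -> None:
        n = len(self.time_ms)
        for name in ("theta_abd", "theta_h", "phi_e", "z", "F_applied", "F_sensed"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"series {name} does not share the trial time base")
        if self.emg.shape[0] != n:
            raise ValueError("EMG does not share the trial time base")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


def abduction_to_height(theta_abd: float, arm: ArmModel) -> float:
    """End-effector height relative to the 90°-abduction plane:
    z = L_u · sin(θ_abd − 90°)."""
    return arm.L_u * math.sin(math.radians(theta_abd - 90.0))


def height_to_abduction(z: float, arm: ArmModel) -> float:
    """Inverse of :func:`abduction_to_height` on (0°, 180°)."""
    s = min(max(z / arm.L_u, -1.0), 1.0)
    return 90.0 + math.degrees(math.asin(s))


def reach_distance(theta_h: float, phi_e: float, arm: ArmModel) -> float:
    """Horizontal shoulder-to-endpoint distance by the law of cosines."""
    c = math.cos(math.radians(phi_e))
    return math.sqrt(arm.L_u**2 + arm.L_f**2 + 2.0 * arm.L_u * arm.L_f * c)


class VerticalRobot:
    """1-DOF vertical dynamics with virtual rigid surfaces.

    In force mode the arm is a damped mass driven by robot support, user
    muscle force and gravity, integrated with semi-implicit Euler and clamped
    at the virtual surfaces (plus the tabletop surface when present).  In
    position mode the controller imposes z directly and the robot holds it
    rigidly between decisions.
    """

    MAX_DT = 0.010  # s; explicit integration is unreliable beyond this

    def __init__(self, arm: ArmModel, *, tabletop: bool = False,
                 z0: float | None = None):
        self.arm = arm
        self.z_floor = abduction_to_height(ABD_FLOOR_DEG, arm)
        self.z_ceiling = abduction_to_height(ABD_CEILING_DEG, arm)
        self.z_table = 0.0 if tabletop else None
        self.z = self.z_floor if z0 is None else z0
        self.v = 0.0

    # -- force mode ---------------------------------------------------------
    def step(self, F_robot: float, F_user_lift: float, dt: float) -> float:
        """Advance the free vertical dynamics one step; returns F_sensed.

        m·z̈ = F_robot + F_user − W − b·ż.  On surface contact z is clamped
        and the constraint normal appears in the sensed force.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if dt > self.MAX_DT:
            raise ValueError(f"dt = {dt*1000:.1f} ms exceeds the {self.MAX_DT*1000:.0f} ms "
                             "stability limit")
        arm = self.arm
        F_net = F_robot + F_user_lift - arm.W - arm.b * self.v
        self.v += F_net / arm.m_eff * dt
        self.z += self.v * dt

        contact = False
        contact_normal = 0.0
        floor = self.z_floor if self.z_table is None else max(self.z_floor, self.z_table)
        if self.z <= floor:
            self.z = floor
            if self.v <= 0.0:
                self.v = 0.0
                contact = True
                # upward normal the surface supplies to hold the arm static
                contact_normal = max(arm.W - F_robot - F_user_lift, 0.0)
        if self.z >= self.z_ceiling:
            self.z = self.z_ceiling
            if self.v >= 0.0:
                self.v = 0.0
                contact = True
                # downward normal from the ceiling surface
                contact_normal = -max(F_robot + F_user_lift - arm.W, 0.0)
        if contact:
            # at rest against a surface the cell reads the reaction the limb
            # exerts on it: −W when resting passively with no support
            return -contact_normal
        # free flight: residual vertical load transmitted through the cast
        return F_user_lift + F_robot - arm.W - arm.b * self.v

    # -- position mode ------------------------------------------------------
    def impose_position(self, z: float, F_user_lift: float) -> float:
        """Rigidly place the end effector (position control); returns F_sensed.

        The robot supplies whatever force holds z, so the load cell reads the
        user's net loading against the rigid support: F_user_lift − W.
        """
        self.z = min(max(z, self.z_floor), self.z_ceiling)
        self.v = 0.0
        return F_user_lift - self.arm.W

    @property
    def theta_abd(self) -> float:
        return height_to_abduction(self.z, self.arm)


@dataclass
class ConditionEnv:
    """A configured robot environment for one support condition."""

    condition: str
    robot: VerticalRobot
    F_robot_static: float | None   # None → controller-driven
    controller_driven: bool


def make_condition(condition: str, arm: ArmModel) -> ConditionEnv:
    """Build the robot environment for one of the five support conditions."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of "
                         f"{CONDITIONS}")
    tabletop = condition == "table"
    robot = VerticalRobot(arm, tabletop=tabletop)
    if condition == "limb_weight":
        return ConditionEnv(condition, robot, F_robot_static=arm.W,
                            controller_driven=False)
    if condition in ("no_support", "table"):
        return ConditionEnv(condition, robot, F_robot_static=0.0,
                            controller_driven=False)
    return ConditionEnv(condition, robot, F_robot_static=None,
                        controller_driven=True)
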