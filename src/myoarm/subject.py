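"""Synthetic post-stroke subject: class-conditioned EMG and closed-loop behavior.

No public EMG corpus exists for this task, so every downstream module is
exercised against a generative stand-in.  Surface EMG is modeled the standard
way: a band-limited (20–350 Hz) zero-mean Gaussian carrier per channel,
amplitude-modulated by the intended activation, plus additive sensor noise.
Per movement class a 12-vector of mean channel activations mirrors the
electrode montage (abduction loads the deltoids, trapezius and supraspinatus;
adduction the pectoralis and infraspinatus; reaching the biceps and wrist
channels mildly).

The hallmark post-stroke impairment — the abnormal flexion synergy — enters
twice, both controlled by one scalar ``k_syn``:

* a non-negative 12×12 coupling matrix mixes intended drives into observed
  channel activations, bleeding shoulder-abduction effort into the elbow and
  wrist flexor channels;
* kinematically, the attainable elbow extension during reach shrinks with
  concurrent shoulder effort:  phi_min = phi_rest − phi_range·(1 − k_syn·effort).

Because supporting the arm lowers the shoulder effort needed to hold it up,
support directly buys elbow extension and reach distance — the phenomenon
the real study measures.

The closed-loop "user" follows a lift / reach / return / lower script.  Its
shoulder drive per phase is an explicit effort model: full effort when
carrying the unsupported limb, a fixed command-level contraction (default
0.75 of training intensity) when driving a real-time controller, a smaller
stabilization effort while supported in the window, and an eccentric fraction
while lowering.  These defaults were chosen once, analytically, so that the
time-integral of shoulder-channel drive under real-time control lands near
half of the no-support integral and the support conditions order as
limb-weight < real-time < no-support.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import signal as sps

from .robot import (ABD_FLOOR_DEG, ArmModel, ConditionEnv, TrialRecord,
                    VerticalRobot, abduction_to_height, make_condition)
from .signal import DEFAULT_CHANNELS, PASS_BAND, EmgRecording

__all__ = [
    "SubjectProfile",
    "PolicyParams",
    "default_patterns",
    "generate_class_emg",
    "build_training_protocol",
    "generate_unrelated_recordings",
    "user_policy",
    "simulate_session",
    "UNRELATED_TASKS",
]

MOVEMENT_CLASSES = ("no_movement", "abduction", "adduction")
UNRELATED_TASKS = (
    "horizontal_add_abd",
    "internal_external_rot",
    "elbow_flex_extend",
    "hand_open_close",
)
TRAINING_POSTURES = (0.0, 45.0, 90.0)

_CH = {name: i for i, name in enumerate(DEFAULT_CHANNELS)}


def default_patterns() -> dict[str, np.ndarray]:
    """Per-class/task mean channel activations (normalized units).

    Values are configuration, not physiological claims; they mirror which
    muscles of the montage a practitioner would expect each task to load.
    """
    def pat(**kw):
        v = np.full(12, 0.05)
        for name, a in kw.items():
            v[_CH[name]] = a
        return v

    return {
        "no_movement": np.full(12, 0.05),
        "abduction": pat(delt_ant=0.9, delt_mid=1.0, delt_post=0.7, trap_up=0.8,
                         supraspinatus=0.8, infraspinatus=0.3, pect_major=0.1,
                         biceps=0.2, wrist_ext_a=0.1, wrist_ext_b=0.1,
                         wrist_flex_a=0.1, wrist_flex_b=0.1),
        "adduction": pat(pect_major=0.9, infraspinatus=0.7, delt_ant=0.15,
                         delt_mid=0.15, delt_post=0.15, trap_up=0.2,
                         supraspinatus=0.2, biceps=0.2),
        "reach": pat(delt_ant=0.25, biceps=0.35, wrist_ext_a=0.3, wrist_ext_b=0.3,
                     wrist_flex_a=0.25, wrist_flex_b=0.25),
        # untrained tasks, emitted for the offline confusion analysis only
        "horizontal_add_abd": pat(pect_major=0.5, delt_post=0.5, delt_ant=0.35,
                                  infraspinatus=0.4, biceps=0.25),
        "internal_external_rot": pat(infraspinatus=0.6, supraspinatus=0.5,
                                     pect_major=0.35, delt_post=0.3),
        "elbow_flex_extend": pat(biceps=0.7, wrist_flex_a=0.3, wrist_flex_b=0.25,
                                 delt_ant=0.15),
        "hand_open_close": pat(wrist_ext_a=0.7, wrist_ext_b=0.6, wrist_flex_a=0.6,
                               wrist_flex_b=0.5, biceps=0.2),
    }


def _synergy_matrix(k_syn: float) -> np.ndarray:
    """Identity plus abnormal-synergy cross-talk: shoulder-abductor drive
    bleeds into elbow/wrist flexor channels in proportion to k_syn."""
    c = np.eye(12)
    sources = [_CH[n] for n in ("delt_ant", "delt_mid", "delt_post", "supraspinatus")]
    sinks = [_CH[n] for n in ("biceps", "wrist_flex_a", "wrist_flex_b")]
    for s in sources:
        for d in sinks:
            c[d, s] += 0.15 * k_syn
    return c


@dataclass
class SubjectProfile:
    """Generative parameters for one synthetic subject."""

    activation_patterns: dict[str, np.ndarray] = field(default_factory=default_patterns)
    k_syn: float = 0.6            # abnormal-synergy strength, ≥ 0
    noise_sd: float = 0.02        # additive sensor noise, signal units
    mvc_scale: float = 1.0        # carrier amplitude at activation 1.0
    posture_sensitivity: float = 0.05  # fractional pattern change per 45° posture
    seed: int = 0
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.k_syn < 0:
            raise ValueError("k_syn must be non-negative")
        for name, p in self.activation_patterns.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (len(self.channel_names),) or np.any(p < 0):
                raise ValueError(f"pattern {name!r} must be a non-negative "
                                 f"{len(self.channel_names)}-vector")
            self.activation_patterns[name] = p

    @property
    def synergy_coupling(self) -> np.ndarray:
        return _synergy_matrix(self.k_syn)

    def observed_activation(self, intents: Mapping[str, float],
                            posture: float = 45.0) -> np.ndarray:
        """Observed per-channel activation for a mixture of intended drives."""
        drive = np.zeros(len(self.channel_names))
        for name, intensity in intents.items():
            drive += intensity * self._posture_pattern(name, posture)
        return self.synergy_coupling @ drive

    def _posture_pattern(self, name: str, posture: float) -> np.ndarray:
        base = self.activation_patterns[name]
        j = np.arange(base.size)
        factor = 1.0 + self.posture_sensitivity * (posture - 45.0) / 45.0 \
            * np.sin(2.0 * np.pi * j / base.size)
        return base * factor


def _carrier(n: int, n_ch: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS band-limited Gaussian carrier, (n, n_ch)."""
    sos = sps.butter(2, PASS_BAND, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal((n, n_ch)), axis=0)
    rms = np.sqrt(np.mean(np.square(x), axis=0))
    return x / np.where(rms > 0, rms, 1.0)


def generate_class_emg(
    profile: SubjectProfile,
    klass: str,
    intensity: float = 1.0,
    duration_s: float = 10.0,
    posture: float = 45.0,
    seed: int | np.random.SeedSequence = 0,
    fs: float = 1000.0,
    label: str | None = None,
    trial_id: str | None = None,
) -> EmgRecording:
    """A steady contraction of one class at the given relative intensity.

    The per-channel amplitude is ``synergy_coupling @ (intensity · pattern)``
    scaled by ``mvc_scale``; the MAV of each channel is then amplitude ×
    √(2/π) in expectation (the folded-Gaussian mean).
    """
    if intensity < 0:
        raise ValueError("intensity must be non-negative")
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    n_ch = len(profile.channel_names)
    amp = profile.mvc_scale * profile.observed_activation({klass: intensity}, posture)
    samples = _carrier(n, n_ch, fs, rng) * amp \
        + profile.noise_sd * rng.standard_normal((n, n_ch))
    return EmgRecording(
        samples=samples, fs=fs, channel_names=profile.channel_names,
        label=klass if label is None else label, posture=posture,
        trial_id=trial_id,
    )


def build_training_protocol(
    profile: SubjectProfile,
    controller_mode: str = "both",
    seed: int = 0,
    fs: float = 1000.0,
    trial_duration_s: float = 10.0,
) -> list[EmgRecording]:
    """The calibration session: labeled 10-second training trials.

    Three horizontal-adduction postures (0°, 45°, 90°) × two repetitions ×
    three movement classes give 18 trials; five tabletop-supported and five
    limb-weight-supported reach trials — labeled no-movement so the decoder
    learns to hold still while the user reaches — complete the set.  Mode
    ``both`` emits all 28; ``position`` / ``force`` keep the 18 plus the five
    matching supported-reach trials (23).
    """
    if controller_mode not in ("position", "force", "both"):
        raise ValueError(f"controller_mode must be position|force|both, "
                         f"got {controller_mode!r}")
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(28))
    trials: list[EmgRecording] = []
    for posture in TRAINING_POSTURES:
        for rep in range(2):
            for klass in MOVEMENT_CLASSES:
                trials.append(generate_class_emg(
                    profile, klass, intensity=1.0, duration_s=trial_duration_s,
                    posture=posture, seed=next(streams), fs=fs,
                    trial_id=f"train_{klass}_p{posture:g}_r{rep}",
                ))
    for support, wanted in (("table", ("position", "both")),
                            ("limb_weight", ("force", "both"))):
        for rep in range(5):
            stream = next(streams)
            if controller_mode in wanted:
                trials.append(generate_class_emg(
                    profile, "reach", intensity=0.6,
                    duration_s=trial_duration_s, posture=90.0, seed=stream,
                    fs=fs, label="no_movement",
                    trial_id=f"train_reach_{support}_r{rep}",
                ))
    return trials


def generate_unrelated_recordings(
    profile: SubjectProfile,
    support: str = "limb_weight",
    seed: int = 0,
    n_trials: int = 3,
    trial_duration_s: float = 15.0,
    intensity: float = 0.7,
    fs: float = 1000.0,
) -> dict[str, list[EmgRecording]]:
    """Untrained-task recordings for the offline confusion analysis.

    Each of the four unrelated tasks is recorded in ``n_trials`` trials while
    the arm is fully supported (limb-weight or tabletop).  The tasks are
    alternating movement pairs (e.g. flex then extend), so their drive is
    cyclically amplitude-modulated — windows range from near-quiet through
    full task activation — and under limb-weight support a small stabilizing
    abduction drive is superimposed because the floating arm must be
    steadied, whereas on the tabletop it rests.
    """
    if support not in ("limb_weight", "table"):
        raise ValueError("support must be 'limb_weight' or 'table'")
    stabilize = 0.12 if support == "limb_weight" else 0.0
    ss = np.random.SeedSequence(seed)
    out: dict[str, list[EmgRecording]] = {}
    for task in UNRELATED_TASKS:
        out[task] = []
        for rep in range(n_trials):
            rng = np.random.default_rng(ss.spawn(1)[0])
            n = int(round(trial_duration_s * fs))
            t = np.arange(n) / fs
            # one movement of the pair every ~1.5 s, with per-cycle vigor jitter
            cycle = np.abs(np.sin(np.pi * t / 1.5))
            vigor = intensity * rng.uniform(0.6, 1.2)
            drive = vigor * (0.15 + 0.85 * cycle)
            amp_task = profile.mvc_scale * profile.observed_activation(
                {task: 1.0}, posture=45.0)
            amp_hold = profile.mvc_scale * profile.observed_activation(
                {"abduction": stabilize, "no_movement": 1.0}, posture=45.0)
            env = drive[:, None] * amp_task[None, :] + amp_hold[None, :]
            samples = _carrier(n, 12, fs, rng) * env \
                + profile.noise_sd * rng.standard_normal((n, 12))
            out[task].append(EmgRecording(
                samples=samples, fs=fs, channel_names=profile.channel_names,
                label=task, posture=45.0,
                trial_id=f"unrelated_{task}_{support}_r{rep}",
            ))
    return out


# ---------------------------------------------------------------------------
# closed-loop user policy and session simulation

PHASES = ("lift", "reach", "return", "lower", "done")


@dataclass
class PolicyParams:
    """Effort model of the synthetic user (fractions of training intensity)."""

    cmd_intensity: float = 0.75   # contraction used to drive a real-time controller
    rt_hold: float = 0.35         # stabilization effort in-window under real-time support
    ns_hold: float = 0.85         # effort holding the unsupported arm in-window
    eccentric_lower: float = 0.3  # eccentric abduction while lowering unsupported
    baseline: float = 0.05        # resting tone
    reach_drive: float = 0.5      # reach-pattern drive during the reach phase
    return_drive: float = 0.3
    phi_rest: float = 90.0        # elbow flexion at rest, deg
    phi_range: float = 70.0       # extension range available free of synergy, deg
    theta_h_rest: float = 30.0    # horizontal adduction at rest, deg
    theta_h_max: float = 90.0     # full forward reach, deg
    lift_s: float = 2.0
    reach_s: float = 3.0
    return_s: float = 2.0
    lower_s: float = 2.0
    rt_lift_timeout_s: float = 4.0
    rt_lower_timeout_s: float = 3.0
    servo_kp: float = 8.0         # user force PD, ×W per m of height error
    servo_kd: float = 2.0         # ×W per m/s


@dataclass
class PolicyOutput:
    intents: dict[str, float]     # per-class/task intended drive intensities
    F_user_lift: float            # N, upward muscular force on the limb
    phi_e_target: float           # deg, attainable elbow extension this instant
    theta_h_target: float         # deg


def attainable_elbow_extension(profile: SubjectProfile, shoulder_effort: float,
                               params: PolicyParams | None = None) -> float:
    """Minimum elbow flexion attainable under concurrent shoulder effort:
    phi_min = phi_rest − phi_range·(1 − k_syn·effort), clamped to ≥ 0."""
    p = params or PolicyParams()
    coupling = min(profile.k_syn * shoulder_effort, 1.0)
    return max(p.phi_rest - p.phi_range * (1.0 - coupling), 0.0)


def user_policy(
    task_phase: str,
    pose,
    F_robot: float,
    profile: SubjectProfile,
    *,
    realtime: bool = False,
    arm: ArmModel | None = None,
    params: PolicyParams | None = None,
) -> PolicyOutput:
    """The synthetic user's intent and muscular force for one instant.

    ``F_robot`` is the support currently provided (the rigid hold of position
    control and the tabletop count as full support).  Carrying effort scales
    with the unsupported fraction max(0, W − F_robot)/W; real-time phases add
    the fixed command-level contraction.  The elbow-extension target encodes
    the flexion synergy: more shoulder effort, less attainable extension.
    """
    if task_phase not in PHASES:
        raise ValueError(f"unknown phase {task_phase!r}")
    p = params or PolicyParams()
    arm = arm or ArmModel()
    unsupported = max(0.0, arm.W - F_robot) / arm.W

    intents = {"no_movement": 1.0}  # resting tone is always present
    abd = p.baseline
    add = 0.0
    if task_phase == "lift":
        abd = p.cmd_intensity if realtime else max(unsupported, p.baseline)
        if realtime:
            abd = max(abd, 0.3 * unsupported)  # partial carry while the robot catches up
    elif task_phase in ("reach", "return"):
        abd = p.rt_hold if realtime else max(unsupported * p.ns_hold, p.baseline)
        drive = p.reach_drive if task_phase == "reach" else p.return_drive
        intents["reach"] = drive
    elif task_phase == "lower":
        if realtime:
            add = p.cmd_intensity
        else:
            abd = max(unsupported * p.eccentric_lower, p.baseline)
            add = 0.1
    intents["abduction"] = abd
    if add:
        intents["adduction"] = add

    # shoulder effort that the flexion synergy couples into the elbow
    effort = max(abd, p.baseline)
    phi_target = attainable_elbow_extension(profile, effort, p)
    th_target = p.theta_h_rest + (p.theta_h_max - p.theta_h_rest) \
        * (1.0 - phi_target / p.phi_rest)

    F_user = unsupported * arm.W if task_phase in ("lift", "reach", "return") else 0.0
    return PolicyOutput(intents=intents, F_user_lift=F_user,
                        phi_e_target=phi_target, theta_h_target=th_target)


def _phase_schedule_static(t_s: float, p: PolicyParams) -> tuple[str, float]:
    """(phase, fraction-through-phase) for the scripted static conditions."""
    edges = [("lift", p.lift_s), ("reach", p.reach_s), ("return", p.return_s),
             ("lower", p.lower_s)]
    t0 = 0.0
    for name, dur in edges:
        if t_s < t0 + dur:
            return name, (t_s - t0) / dur
        t0 += dur
    return "done", 0.0


def simulate_session(
    profile: SubjectProfile,
    condition: str,
    n_trials: int = 10,
    seed: int = 0,
    *,
    model=None,
    gains=None,
    arm: ArmModel | None = None,
    params: PolicyParams | None = None,
    trial_duration_s: float = 12.0,
    fs: float = 1000.0,
    shrinkage: float = 0.1,
) -> list[TrialRecord]:
    """Run ``n_trials`` closed-loop lift-reach-return-lower trials.

    Static conditions (tabletop, limb-weight, no-support) play out the
    scripted task kinematics with the condition's constant support force.
    Real-time conditions close the full loop: synthetic EMG → causal
    conditioning → sliding-window features → minimum-Mahalanobis decision →
    proportional position/force command → robot dynamics.  When no trained
    ``model`` is supplied, one is fitted from the matching training protocol;
    gains default to the per-subject calibration.
    """
    from . import pipeline  # deferred: pipeline imports this module's protocol

    p = params or PolicyParams()
    arm = arm or ArmModel()
    env = make_condition(condition, arm)

    if env.controller_driven:
        if model is None:
            protocol = build_training_protocol(profile, condition, seed=seed + 1)
            model = pipeline.train_from_recordings(protocol, shrinkage=shrinkage)
        if gains is None:
            gains = pipeline.calibrate_gains(model, profile, arm, condition,
                                             cmd_intensity=p.cmd_intensity)

    ss = np.random.SeedSequence(seed)
    return [
        _simulate_trial(profile, condition, env, model, gains, arm, p,
                        trial_duration_s, fs, ss.spawn(1)[0],
                        trial_id=f"{condition}_{k:02d}")
        for k in range(n_trials)
    ]


def _simulate_trial(profile, condition, env: ConditionEnv, model, gains,
                    arm: ArmModel, p: PolicyParams, duration_s: float,
                    fs: float, seed, trial_id: str) -> TrialRecord:
    """One closed-loop trial, advanced in 25 ms control blocks.

    The user's intent only changes at phase transitions and the robot command
    only at decision instants, so EMG synthesis and causal conditioning are
    vectorized per block; only the force-mode vertical dynamics integrate at
    1 ms inside each block.
    """
    from .control import ControllerState, controller_step
    from .classifier import classify
    from .features import extract_features
    from .signal import AnalysisWindow, _design_sos

    rng = np.random.default_rng(seed)
    step = 25                      # samples per control block at 1 kHz
    window = 200                   # analysis-window samples
    n_blocks = int(round(duration_s * fs)) // step
    n = n_blocks * step
    dt = 1.0 / fs
    n_ch = len(profile.channel_names)
    carrier = _carrier(n, n_ch, fs, rng)
    wnoise = profile.noise_sd * rng.standard_normal((n, n_ch))

    realtime = env.controller_driven
    robot = VerticalRobot(arm, tabletop=(condition == "table"))  # fresh per trial
    state = None
    if realtime:
        state = ControllerState(
            mode=condition, gains=gains, z=robot.z_floor, F=0.0,
            z_limits=(robot.z_floor, robot.z_ceiling), F_limits=(0.0, arm.W),
        )

    sos = _design_sos(fs)
    zi = np.zeros((sos.shape[0], 2, n_ch))
    conditioned = np.empty((n, n_ch))

    emg = np.empty((n, n_ch))
    theta_abd = np.empty(n)
    theta_h = np.empty(n)
    phi_e = np.empty(n)
    z_arr = np.empty(n)
    F_app = np.empty(n)
    F_sns = np.empty(n)
    decisions = []

    phase, phase_t0, truncated = "lift", 0.0, False
    th, pe = p.theta_h_rest, p.phi_rest
    return_decay = 1.0 - (1.0 - 0.003) ** step  # per-block relaxation toward rest

    for k in range(n_blocks):
        i0, i1 = k * step, (k + 1) * step
        t = i0 * dt
        # -- phase machine ---------------------------------------------------
        if not realtime:
            phase, frac = _phase_schedule_static(t, p)
        else:
            el = t - phase_t0
            if phase == "lift":
                if robot.theta_abd >= 85.0:
                    phase, phase_t0 = "reach", t
                elif el > p.rt_lift_timeout_s:
                    truncated = True
                    phase, phase_t0 = "reach", t
            elif phase == "reach" and el >= p.reach_s:
                phase, phase_t0 = "return", t
            elif phase == "return" and el >= p.return_s:
                phase, phase_t0 = "lower", t
            elif phase == "lower" and (robot.theta_abd <= 78.0
                                       or el > p.rt_lower_timeout_s):
                phase, phase_t0 = "done", t
            frac = min((t - phase_t0) / p.reach_s, 1.0) if phase == "reach" \
                else 0.0

        # -- support the user currently feels ---------------------------------
        if condition == "limb_weight":
            F_support = arm.W
        elif condition == "table":
            # unsupported while lifting to the surface; resting on it in-window
            F_support = arm.W if phase in ("reach", "return", "done") else 0.0
        elif condition == "no_support":
            F_support = arm.W if phase == "done" else 0.0  # floor at rest
        elif condition == "position":
            F_support = arm.W                              # rigid hold
        else:  # force
            F_support = state.F

        pol = user_policy(phase, None, F_support, profile, realtime=realtime,
                          arm=arm, params=p)

        # -- EMG and causal conditioning for this block -----------------------
        amp = profile.mvc_scale * profile.observed_activation(pol.intents, 45.0)
        emg[i0:i1] = carrier[i0:i1] * amp + wnoise[i0:i1]
        conditioned[i0:i1], zi = sps.sosfilt(sos, emg[i0:i1], axis=0, zi=zi)

        # -- vertical motion over the block -----------------------------------
        if realtime and condition == "position":
            F_user = pol.F_user_lift if phase == "lift" else 0.0
            sns = robot.impose_position(state.z, F_user)
            F_sns[i0:i1] = sns
            F_app[i0:i1] = -sns          # holding force of the rigid robot
            z_arr[i0:i1] = robot.z
            theta_abd[i0:i1] = robot.theta_abd
        elif realtime:  # force mode: integrate at 1 ms
            z_des = abduction_to_height(90.0, arm) if phase in (
                "lift", "reach", "return") else robot.z_floor
            for i in range(i0, i1):
                if phase in ("lift", "reach", "return"):
                    F_pd = arm.W * (p.servo_kp * (z_des - robot.z)
                                    - p.servo_kd * robot.v)
                    F_user = float(np.clip(max(0.0, arm.W - state.F) + F_pd,
                                           0.0, 1.3 * arm.W))
                else:
                    F_user = 0.0
                F_sns[i] = robot.step(state.F, F_user, dt)
                F_app[i] = state.F
                z_arr[i] = robot.z
                theta_abd[i] = robot.theta_abd
        else:
            # scripted vertical kinematics for the static conditions
            if phase == "lift":
                abd_now = ABD_FLOOR_DEG + (90.0 - ABD_FLOOR_DEG) * frac
            elif phase in ("reach", "return"):
                abd_now = 90.0
            elif phase == "lower":
                abd_now = 90.0 - (90.0 - ABD_FLOOR_DEG) * frac
            else:
                abd_now = ABD_FLOOR_DEG
            robot.z = abduction_to_height(abd_now, arm)
            z_arr[i0:i1] = robot.z
            F_app[i0:i1] = env.F_robot_static
            if condition == "table" and phase in ("reach", "return"):
                F_sns[i0:i1] = -arm.W    # pressing into the rigid surface
            elif condition == "limb_weight":
                F_sns[i0:i1] = 0.0       # floating: the robot carries the limb
            elif phase == "done":
                F_sns[i0:i1] = -arm.W    # resting on the lower virtual surface
            else:
                F_sns[i0:i1] = pol.F_user_lift - arm.W
            theta_abd[i0:i1] = robot.theta_abd

        # -- decision at the block boundary (real-time conditions) ------------
        if realtime and i1 >= window:
            win = AnalysisWindow(conditioned[i1 - window : i1],
                                 start_time_ms=(i1 - window) * 1000.0 / fs, fs=fs)
            fv = extract_features(win, model.thresholds)
            d = classify(fv, model, time_ms=i1 * (1000.0 / fs))
            controller_step(state, d)
            decisions.append(d)

        # -- horizontal joints (quasi-static) ----------------------------------
        if phase == "reach":
            th = p.theta_h_rest + (pol.theta_h_target - p.theta_h_rest) * frac
            pe = p.phi_rest + (pol.phi_e_target - p.phi_rest) * frac
        elif phase in ("return", "lower", "done"):
            th += (p.theta_h_rest - th) * return_decay
            pe += (p.phi_rest - pe) * return_decay
        theta_h[i0:i1] = th
        phi_e[i0:i1] = pe

    return TrialRecord(
        time_ms=np.arange(n) * (1000.0 / fs), theta_abd=theta_abd, theta_h=theta_h,
        phi_e=phi_e, z=z_arr, F_applied=F_app, F_sensed=F_sns, emg=emg,
        fs=fs, condition=condition, trial_id=trial_id, decisions=decisions,
        truncated=truncated,
    )
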