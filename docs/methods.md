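# Methods

This note documents the models, numerical choices and limitations behind
`myoarm`. It states nothing that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal chain

EMG is sampled at 1 kHz (configurable; anything ≥ 700 Hz is accepted so the
350 Hz passband edge stays below Nyquist). Conditioning is a 4th-order
Butterworth band-pass 20–350 Hz cascaded with a 4th-order Butterworth
band-stop 50–70 Hz — the stop band brackets 50/60 Hz mains. Offline analyses
apply it forward–backward (zero phase); the real-time loop applies a single
causal pass and accepts the group delay. Analysis windows are 200 ms stepped
by 25 ms (175 ms overlap); each window covers exactly the 200 ms preceding
its decision instant, and a recording of N samples yields
`floor((N − W)/S) + 1` windows.

Per channel and window the features are Hudgins' four time-domain
descriptors plus a 6th-order autoregressive fit, channel-major
(MAV, ZC, SSC, WL, AR1..AR6 per channel; 120 values for 12 channels):

- **MAV** — mean absolute value.
- **ZC** — count of sign changes where *both* samples clear an amplitude
  gate. The gate uses the smaller of the two sample magnitudes so that a
  sub-threshold excursion through zero in a quiet channel does not register;
  the default gate is 0.01 × the channel's conditioned training-data RMS.
- **SSC** — count of interior samples whose adjacent slopes have product
  ≥ max(gate, 1e−12); the tiny floor excludes flat runs.
- **WL** — cumulative absolute first difference.
- **AR1..AR6** — Burg-method coefficients (sign convention
  x_t = Σ a_k x_{t−k} + e_t), chosen for stability on 200-sample windows.
  Degenerate (constant/zero) windows fall back to all-zero coefficients with
  a warning; the real-time loop must never raise on a quiet channel.

## Decoder and proportional control

The decoder is LDA-like: per-class feature means, one pooled within-class
covariance normalized by N − g, and a minimum-Mahalanobis decision. With
120-dimensional features from a few thousand windows the raw pooled
covariance is ill-conditioned, so it is shrunk convexly toward its diagonal,
Σ_λ = (1−λ)Σ + λ·diag(Σ), λ = 0.1 by default. Exact distance ties resolve
to no-movement when it participates (ambiguous intent must not move the
robot), otherwise to the lowest class index.

The proportional-control magnitude uses only the window's MAV sub-vector:
PC_i = (1/C_i) Σ_j S_ij·MAV_j², with the class/channel centers S_ij (mean
training MAV) and normalizers C_i = Σ_j S_ij². This literal squared form
makes PC scale quadratically with contraction intensity. An alternative
normalized dot-product form, PC_i = (1/C_i) Σ_j S_ij·MAV_j — which equals
1 when the window MAVs sit exactly on the class centers — is available as
`eq1_variant="dot"` but is not the default; the two readings differ only in
the PC scale the gains then absorb.

## Controllers

Every 25 ms the winning (class, PC) pair updates the support: position mode
applies a velocity held over the interval (Δz = g·PC·Δt, up for abduction,
down for adduction, nothing for no-movement), force mode an increment
ΔF = g·PC. Gains are separate per direction and mode. Position commands are
clamped to the virtual-surface limits (70°/100° abduction); force commands
to [0, W] — the limb weight, beyond which the robot would lift the arm
passively. An optional per-decision rate limiter exists but is off by
default. Between trials, a heuristic retunes gains: ×0.8 after a
ceiling-slam trial, ×1.25 when the user outruns the robot, bounded in
[g_min, g_max].

Reference gains are defined at PC = 1: crossing the full 70°→100° range in
≈ 3 s (position) or loading the full limb weight in ≈ 2 s (force). Because a
synthetic subject's command-level PC is far below 1 (quadratic intensity
scaling), `calibrate_gains` anchors those same timing targets to the PC the
subject actually produces at command-level contraction — the package's
analogue of the per-participant gain tuning a therapist would do.

## Robot simulation

The vertical degree of freedom is a lumped damped mass:
m·z̈ = F_robot + F_user − W − b·ż, integrated with semi-implicit Euler at
1 ms (steps above 10 ms are rejected). Virtual rigid surfaces clamp z at the
70° and 100° abduction heights; the tabletop condition adds a surface at
90°. Height maps to abduction by z = L_u·sin(θ − 90°). In position mode the
controller imposes z rigidly and the load cell reads the user's net loading
(F_user − W); on surface contact the constraint normal appears in the
sensed force, so an arm resting passively reads −W (negative = bearing
down). Horizontal joints (horizontal adduction, elbow) are quasi-static —
driven directly by the subject policy, with no feedback into the vertical
dynamics. Default anthropometry: L_u = 0.30 m, L_f = 0.35 m, W = 30 N,
b = 25 N·s/m, m = W/g; all configurable, none a claim about any person.

## Synthetic subject

Surface EMG is modeled as a unit-RMS Gaussian carrier band-limited to
20–350 Hz, amplitude-modulated per channel by the coupled activation, plus
additive white sensor noise (SD 0.02 in units where full activation ≈ 1).
The per-channel MAV of a steady contraction is then amplitude × √(2/π).
Class activation patterns mirror the 12-site montage (abduction loads
deltoids/trapezius/supraspinatus, adduction pectoralis/infraspinatus,
reaching the biceps and wrist channels mildly); posture perturbs patterns by
a small deterministic factor (±5% across the 0°–90° range). Four additional
untrained-task patterns (horizontal add/abd, isometric rotation, elbow
flex/extend, hand open/close) are emitted for the offline confusion analysis
only and never trained on; they are cyclically amplitude-modulated (~1.5 s
per movement of each pair, with per-cycle vigor jitter) because alternating
movements, unlike calibration contractions, are not steady.

The abnormal synergy enters through one scalar k_syn (default 0.6):

- a non-negative 12×12 coupling matrix adds 0.15·k_syn of each
  shoulder-abductor drive into the biceps and wrist-flexor channels;
- kinematically, the attainable elbow extension during reach shrinks with
  concurrent shoulder effort: φ_min = φ_rest − φ_range·(1 − k_syn·effort),
  with φ_rest = 90°, φ_range = 70°; the horizontal-reach target scales with
  the achieved extension. k_syn = 0 recovers independent joints.

The calibration protocol is 3 postures × 2 repetitions × 3 classes of
10-second trials (18), plus 5 tabletop-supported and 5 limb-weight-supported
reach trials labeled no-movement (so the decoder holds still while the user
reaches); 28 trials for both controllers, 23 per single mode.

The closed-loop policy follows lift → reach (3 s) → return (2 s) → lower,
with phase transitions driven by the simulated arm in the real-time
conditions (reach begins at 85° abduction; a 4 s lift timeout truncates and
flags the trial). Its shoulder drive is an explicit effort model, in
fractions of training intensity: 1.0 carrying the unsupported limb, 0.85
holding it in-window, 0.3 eccentric lowering, 0.75 command-level contraction
when driving a controller, 0.35 stabilization in-window under real-time
support, 0.05 resting tone. These constants were fixed once, analytically,
so that the time-integral of shoulder drive under real-time control lands
near half the no-support integral and the conditions order limb-weight <
real-time < no-support; they were not revisited afterwards. In force mode
the user additionally closes a PD position loop with muscle force
(kp = 8 W/m, kd = 2 W·s/m) around the window center, which produces the
characteristic oscillation of force-mode trials. All randomness flows from
one session seed through spawned per-trial sub-streams, so identical seeds
give bit-identical sessions.

## Evaluation

Reach outcomes are masked to the 80°–100° abduction target window: the
elbow metric is the in-window minimum flexion angle, the shoulder metric the
in-window maximum horizontal adduction — the operationalization under which
better support yields smaller elbow and larger shoulder values. Effort is
the rectified, 200 ms moving-averaged envelope, each channel normalized to
its session-wide maximum, summed over the shoulder channels, samples and
trials of a condition. The summed statistic defaults to the three deltoids +
supraspinatus; the heatmap view uses the three deltoids + upper trapezius
(both sets are configurable, reflecting the two channel lists in use for
these two views). Planned comparisons are classical paired one-sided
t-tests (n − 1 df); zero-variance differences degenerate to p ∈ {0, 0.5, 1}
with a warning. Confusion tables report the percentage of each untrained
task's windows per class, with an unweighted mean row over tasks; condition
tables report mean (sample SD) per cell and a group row across participant
means, rounded one decimal for degrees and to integers for percentages.

## Problem sizes

The test suite trains on the full 28-trial protocol at 3-second trial length
and simulates two closed-loop trials per condition; the acceptance script
uses full 10-second training trials and three 12-second trials per
condition. These sizes were chosen as the smallest at which the window
counts, accuracies and condition orderings are stable; the session count per
condition is a parameter (`n_trials`, 10 in the full design).

## What passing tests do and do not show

The generator produces stationary, Gaussian, class-conditioned EMG with a
fixed linear synergy. Real post-stroke EMG is nonstationary (fatigue,
electrode shift, varying tone), its synergy is neither linear nor constant,
and its classes are far less separable — the synthetic decoder accuracies
near 100% therefore validate the pipeline's mechanics, not clinical
performance. Likewise the condition orderings (reach improves and effort
halves under real-time support) are built into the effort model to the
extent that support reduces carrying effort; what the closed loop verifies
is that the decoder, controllers, robot and analyses interact correctly to
express that physiology, not that real participants would show these
magnitudes. Known limitations: no multi-DOF simultaneous classification, no
confidence rejection, no online adaptation, no horizontal assistance forces,
no servo dynamics of a real admittance robot, and no fatigue or
electrode-shift modeling.
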