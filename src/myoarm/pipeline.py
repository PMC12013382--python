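"""End-to-end helpers: featurize recordings, fit the decoder, set gains.

These glue the signal chain to the classifier exactly the way the real-time
loop does — causal conditioning, 200 ms windows stepped by 25 ms — so a model
trained here sees the same feature distribution the loop will produce.
"""

from __future__ import annotations

import numpy as np

from .classifier import CLASSES, ClassifierModel, proportional_control, train
from .control import Gains
from .features import FeatureVector, extract_features, feature_names
from .robot import ArmModel, abduction_to_height
from .signal import EmgRecording, condition_signal, segment_windows

__all__ = [
    "default_thresholds",
    "featurize_recording",
    "train_from_recordings",
    "typical_command_pc",
    "calibrate_gains",
    "default_gains",
]

WINDOW_MS = 200.0
STEP_MS = 25.0
THRESHOLD_RMS_FRACTION = 0.01


def default_thresholds(recordings: list[EmgRecording]) -> np.ndarray:
    """ZC/SSC amplitude gates: 0.01 × per-channel RMS of the conditioned
    training data."""
    sq_sum = None
    n_total = 0
    for rec in recordings:
        cond = condition_signal(rec, mode="causal")
        s = np.sum(np.square(cond.samples), axis=0)
        sq_sum = s if sq_sum is None else sq_sum + s
        n_total += cond.n_samples
    rms = np.sqrt(sq_sum / n_total)
    return THRESHOLD_RMS_FRACTION * rms


def featurize_recording(
    recording: EmgRecording,
    thresholds=0.0,
    window_ms: float = WINDOW_MS,
    step_ms: float = STEP_MS,
    mode: str = "causal",
) -> list[FeatureVector]:
    """Condition, window and featurize one trial."""
    cond = condition_signal(recording, mode=mode)
    return [extract_features(w, thresholds)
            for w in segment_windows(cond, window_ms, step_ms)]


def train_from_recordings(
    recordings: list[EmgRecording],
    shrinkage: float = 0.1,
    window_ms: float = WINDOW_MS,
    step_ms: float = STEP_MS,
    eq1_variant: str = "squared",
    thresholds: np.ndarray | None = None,
) -> ClassifierModel:
    """Fit the 3-class decoder from labeled training trials.

    Trials must carry a ``label`` in {no_movement, abduction, adduction};
    supported-reach trials enter as no-movement, as in the calibration
    protocol.
    """
    if thresholds is None:
        thresholds = default_thresholds(recordings)
    by_class: dict[str, list[FeatureVector]] = {c: [] for c in CLASSES}
    for rec in recordings:
        if rec.label not in by_class:
            raise ValueError(f"trial {rec.trial_id!r} has label {rec.label!r}; "
                             f"expected one of {CLASSES}")
        by_class[rec.label].extend(
            featurize_recording(rec, thresholds, window_ms, step_ms))
    order = tuple(feature_names(recordings[0].channel_names))
    return train(by_class, shrinkage=shrinkage, feature_order=order,
                 thresholds=thresholds, eq1_variant=eq1_variant)


def typical_command_pc(model: ClassifierModel, klass: str = "abduction",
                       intensity: float = 1.0) -> float:
    """Expected PC when the user contracts at ``intensity`` × the training
    level.

    At training intensity the window MAVs sit near the stored centers S, so
    PC ≈ Σ S³ / C for the literal squared form; MAV scales linearly with
    intensity and PC therefore quadratically (linearly for the dot variant).
    """
    i = model.classes.index(klass)
    pc_at_train = proportional_control(model.centers[i], model, i)
    power = 2.0 if model.eq1_variant == "squared" else 1.0
    return pc_at_train * intensity ** power


def default_gains(arm: ArmModel, mode: str, *,
                  lift_time_s: float = 3.0, load_time_s: float = 2.0,
                  decision_period_ms: float = 25.0) -> Gains:
    """Gains referenced to PC = 1: a sustained unit-PC abduction crosses the
    70°→100° range in ``lift_time_s`` (position) or loads the full limb
    weight in ``load_time_s`` (force)."""
    z_range = abduction_to_height(100.0, arm) - abduction_to_height(70.0, arm)
    if mode == "position":
        g = z_range / lift_time_s
    elif mode == "force":
        g = arm.W * decision_period_ms / 1000.0 / load_time_s
    else:
        raise ValueError(f"mode must be 'position' or 'force', got {mode!r}")
    return Gains(up=g, down=g)


def calibrate_gains(model: ClassifierModel, profile, arm: ArmModel, mode: str,
                    cmd_intensity: float = 0.75, **kwargs) -> Gains:
    """Per-subject gains: the PC = 1 timing targets of :func:`default_gains`,
    anchored to the PC this subject actually produces at command-level
    contraction (real users had their gains tuned individually)."""
    pc_cmd = typical_command_pc(model, "abduction", cmd_intensity)
    if pc_cmd <= 0:
        raise ValueError("subject produces no abduction PC; cannot calibrate")
    base = default_gains(arm, mode, **kwargs)
    return Gains(up=base.up / pc_cmd, down=base.down / pc_cmd,
                 g_min=base.g_min / pc_cmd, g_max=base.g_max / pc_cmd)
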