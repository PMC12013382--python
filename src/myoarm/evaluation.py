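"""Outcome analyses: reach excursion, EMG effort, paired tests, tables.

The primary outcomes of a lift-reach-return-lower trial are the maximal
joint excursions reached *while the arm is inside the vertical target window*
(80°–100° shoulder abduction): the minimum elbow flexion angle (smaller =
more extension = further reach) and the maximum horizontal shoulder
adduction.  Muscular effort is summarized by rectifying each EMG channel,
smoothing with a 200 ms moving average, normalizing to the channel's maximum
over the whole session, and summing over the shoulder channels and all trials
of a condition.  Planned comparisons use classical paired one-sided t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .classifier import CLASSES, ClassifierModel, classify
from .robot import TARGET_WINDOW_DEG, TrialRecord
from .signal import DEFAULT_CHANNELS, EmgRecording

__all__ = [
    "ExcursionResult",
    "excursion_metrics",
    "emg_envelope",
    "session_channel_max",
    "emg_effort",
    "paired_one_sided_t",
    "condition_summary",
    "unrelated_movement_confusion",
    "confusion_average_row",
    "SHOULDER_SUM_CHANNELS",
    "SHOULDER_HEATMAP_CHANNELS",
]

#: channels entering the summed shoulder-effort statistic (three deltoid
#: heads + supraspinatus); the heatmap view swaps supraspinatus for the
#: upper trapezius
SHOULDER_SUM_CHANNELS = ("delt_ant", "delt_mid", "delt_post", "supraspinatus")
SHOULDER_HEATMAP_CHANNELS = ("delt_ant", "delt_mid", "delt_post", "trap_up")

ENVELOPE_MS = 200.0


@dataclass
class ExcursionResult:
    trial_id: str
    elbow_deg: float       # min elbow flexion in-window; smaller = more extension
    shoulder_deg: float    # max horizontal adduction in-window; larger = further
    valid: bool


def excursion_metrics(trial: TrialRecord,
                      window_deg: tuple[float, float] = TARGET_WINDOW_DEG
                      ) -> ExcursionResult:
    """Joint-excursion outcome of one trial, masked to the target window."""
    lo, hi = window_deg
    mask = (trial.theta_abd >= lo) & (trial.theta_abd <= hi)
    if not mask.any():
        return ExcursionResult(trial.trial_id, np.nan, np.nan, valid=False)
    return ExcursionResult(
        trial.trial_id,
        elbow_deg=float(np.min(trial.phi_e[mask])),
        shoulder_deg=float(np.max(trial.theta_h[mask])),
        valid=True,
    )


def emg_envelope(emg: np.ndarray, fs: float,
                 window_ms: float = ENVELOPE_MS) -> np.ndarray:
    """Rectified, 200 ms moving-averaged EMG, per channel."""
    w = max(int(round(window_ms * fs / 1000.0)), 1)
    return ndimage.uniform_filter1d(np.abs(emg), size=w, axis=0, mode="nearest")


def session_channel_max(trials: Sequence[TrialRecord],
                        window_ms: float = ENVELOPE_MS) -> np.ndarray:
    """Per-channel maximum of the smoothed envelope across a whole session
    (all conditions); the normalization reference."""
    maxima = None
    for t in trials:
        m = emg_envelope(t.emg, t.fs, window_ms).max(axis=0)
        maxima = m if maxima is None else np.maximum(maxima, m)
    return maxima


def emg_effort(
    trials: Sequence[TrialRecord],
    session_max: np.ndarray,
    channels: Sequence[str] = SHOULDER_SUM_CHANNELS,
    channel_names: Sequence[str] = DEFAULT_CHANNELS,
    window_ms: float = ENVELOPE_MS,
    dt_scale: bool = False,
) -> float:
    """Summed normalized shoulder-channel envelope over a condition's trials.

    Each channel's envelope is divided by its session-wide maximum, then
    summed over the selected channels, all samples and all trials.  Channels
    whose session maximum is zero carry no information and are excluded with
    a warning.
    """
    idx = [list(channel_names).index(c) for c in channels]
    keep = []
    for j in idx:
        if session_max[j] <= 0:
            warnings.warn(f"channel {channel_names[j]!r} has zero session "
                          "maximum; excluded from the effort sum", stacklevel=2)
        else:
            keep.append(j)
    total = 0.0
    for t in trials:
        env = emg_envelope(t.emg[:, keep], t.fs, window_ms) / session_max[keep]
        total += float(env.sum()) * (1.0 / t.fs if dt_scale else 1.0)
    return total


def paired_one_sided_t(a: Sequence[float], b: Sequence[float],
                       direction: str = "less") -> tuple[float, float]:
    """Classical paired t-test (n−1 df), one-sided.

    ``direction="less"`` tests mean(a − b) < 0.  Zero variance of the paired
    differences degenerates: p = 0.5 for a zero mean difference, else 0 or 1
    by the sign of the mean difference, with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need two equal-length paired samples of size >= 2")
    if direction not in ("less", "greater"):
        raise ValueError("direction must be 'less' or 'greater'")
    d = a - b
    if np.ptp(d) == 0.0:
        warnings.warn("zero variance of paired differences; degenerate p",
                      stacklevel=2)
        md = d.mean()
        if md == 0.0:
            return 0.0, 0.5
        extreme = (md < 0) if direction == "less" else (md > 0)
        return (-np.inf if md < 0 else np.inf), (0.0 if extreme else 1.0)
    res = stats.ttest_rel(a, b, alternative=direction)
    return float(res.statistic), float(res.pvalue)


def condition_summary(values: Mapping[str, Mapping[str, Sequence[float]]],
                      round_to: int | None = 1) -> pd.DataFrame:
    """Per-participant mean (SD) per condition, plus a group row.

    ``values[condition][participant]`` is the per-trial metric sequence.
    Cell statistics are the mean and sample SD across trials; the group row
    is the mean and sample SD across participant means.  A single-trial cell
    or single participant leaves the SD as NaN (flagged by pandas' NaN).
    """
    rows = {}
    for cond, by_part in values.items():
        row = {}
        group_means = []
        for part, vals in by_part.items():
            v = np.asarray(list(vals), dtype=float)
            if v.size == 0:
                raise ValueError(f"empty cell: {cond!r}/{part!r}")
            m = v.mean()
            sd = v.std(ddof=1) if v.size > 1 else np.nan
            row[(part, "mean")] = m
            row[(part, "sd")] = sd
            group_means.append(m)
        g = np.asarray(group_means)
        row[("group", "mean")] = g.mean()
        row[("group", "sd")] = g.std(ddof=1) if g.size > 1 else np.nan
        rows[cond] = row
    df = pd.DataFrame(rows).T
    df.columns = pd.MultiIndex.from_tuples(df.columns)
    return df.round(round_to) if round_to is not None else df


def unrelated_movement_confusion(
    model: ClassifierModel,
    recordings_by_task: Mapping[str, Sequence[EmgRecording]],
    window_ms: float = 200.0,
    step_ms: float = 25.0,
    round_to: int | None = 0,
) -> pd.DataFrame:
    """Offline confusion of untrained tasks against the 3 trained classes.

    Every recording is conditioned, windowed and featurized exactly as in
    training; each row gives the percentage of a task's windows assigned to
    each class, and the final row is the unweighted mean over tasks.
    """
    from .pipeline import featurize_recording

    rows = {}
    for task, recs in recordings_by_task.items():
        counts = np.zeros(len(model.classes))
        for rec in recs:
            for fv in featurize_recording(rec, model.thresholds,
                                          window_ms, step_ms):
                counts[classify(fv, model).class_index] += 1
        if counts.sum() == 0:
            raise ValueError(f"task {task!r} produced no analysis windows")
        rows[task] = 100.0 * counts / counts.sum()
    df = pd.DataFrame(rows, index=list(model.classes)).T
    df.loc["average"] = confusion_average_row(df.values)
    return df.round(round_to) if round_to is not None else df


def confusion_average_row(task_rows: np.ndarray) -> np.ndarray:
    """Unweighted arithmetic mean over task rows — the published tables'
    'Average – all tasks' row."""
    rows = np.asarray(task_rows, dtype=float)
    if rows.ndim == 1:
        rows = rows[None, :]
    return rows.mean(axis=0)
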