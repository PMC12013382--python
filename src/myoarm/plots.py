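"""Optional figures: effort heatmap, excursion box plot, trial traces.

Matplotlib is imported lazily so the control pipeline has no plotting
dependency.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from .evaluation import SHOULDER_HEATMAP_CHANNELS, emg_envelope
from .robot import TrialRecord
from .signal import DEFAULT_CHANNELS

__all__ = ["effort_heatmap", "excursion_boxplot", "trial_traces"]


def _plt():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def effort_heatmap(sessions: Mapping[str, Sequence[TrialRecord]],
                   session_max: np.ndarray,
                   channels: Sequence[str] = SHOULDER_HEATMAP_CHANNELS,
                   path: str | None = None):
    """Per-condition time-series heat map of trial-averaged normalized EMG
    for the lifting channels (darker = more activity)."""
    plt = _plt()
    idx = [DEFAULT_CHANNELS.index(c) for c in channels]
    conditions = list(sessions)
    fig, axes = plt.subplots(len(conditions), 1, figsize=(8, 1.6 * len(conditions)),
                             sharex=True, squeeze=False)
    for ax, cond in zip(axes[:, 0], conditions):
        trials = sessions[cond]
        n = min(t.emg.shape[0] for t in trials)
        mean_env = np.mean(
            [emg_envelope(t.emg[:n, idx], t.fs) / session_max[idx]
             for t in trials], axis=0)
        ax.imshow(mean_env.T, aspect="auto", cmap="Greys", vmin=0, vmax=1,
                  extent=(0, n / trials[0].fs, -0.5, len(idx) - 0.5))
        ax.set_yticks(range(len(idx)), labels=list(channels)[::-1], fontsize=7)
        ax.set_ylabel(cond, fontsize=8)
    axes[-1, 0].set_xlabel("time (s)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def excursion_boxplot(values_by_condition: Mapping[str, Sequence[float]],
                      ylabel: str, path: str | None = None):
    """Box plot of a per-trial metric (excursion or summed effort) across
    support conditions."""
    plt = _plt()
    fig, ax = plt.subplots(figsize=(6, 4))
    conds = list(values_by_condition)
    ax.boxplot([values_by_condition[c] for c in conds], tick_labels=conds)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def trial_traces(trial: TrialRecord, path: str | None = None):
    """Kinematics (top) and forces (bottom) of one trial, the standard
    single-trial view."""
    plt = _plt()
    t = trial.time_ms / 1000.0
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 6), sharex=True)
    ax1.plot(t, trial.theta_abd, label="abduction (deg)")
    ax1.plot(t, trial.theta_h, label="horiz. adduction (deg)")
    ax1.plot(t, trial.phi_e, label="elbow flexion (deg)")
    ax1.axhspan(80, 100, color="0.9", zorder=0)
    ax1.set_ylabel("joint angle (deg)")
    ax1.legend(fontsize=8)
    ax2.plot(t, trial.F_applied, label="applied (N)", color="tab:red")
    ax2.plot(t, trial.F_sensed, label="sensed (N)", color="tab:green")
    ax2.axhline(0, color="0.7", lw=0.5)
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("vertical force (N)")
    ax2.legend(fontsize=8)
    fig.suptitle(f"{trial.condition} trial {trial.trial_id}")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
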