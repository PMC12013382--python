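"""EMG conditioning and sliding-window segmentation.

Surface EMG for upper-limb myocontrol is sampled at 1 kHz from 12 bipolar
sites.  Conditioning restricts the signal to the 20–350 Hz band where surface
EMG carries power, with a 50–70 Hz stop band straddling mains interference.
Decisions are made from 200 ms analysis windows advanced every 25 ms, so each
window covers exactly the 200 ms preceding its decision instant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EmgRecording",
    "AnalysisWindow",
    "condition_signal",
    "segment_windows",
    "n_windows",
]

DEFAULT_CHANNELS: tuple[str, ...] = (
    "delt_ant",
    "delt_mid",
    "delt_post",
    "trap_up",
    "pect_major",
    "supraspinatus",
    "infraspinatus",
    "biceps",
    "wrist_ext_a",
    "wrist_ext_b",
    "wrist_flex_a",
    "wrist_flex_b",
)

#: conditioning bands, Hz: overall pass band and mains stop band
PASS_BAND = (20.0, 350.0)
STOP_BAND = (50.0, 70.0)


@dataclass
class EmgRecording:
    """A multi-channel surface-EMG trial.

    ``samples`` is (n_samples, n_channels); channel order is fixed for a
    session.  ``label`` tags the movement class or support condition,
    ``posture`` the horizontal-adduction angle (degrees) at which the trial
    was recorded.
    """

    samples: np.ndarray
    fs: float
    channel_names: tuple[str, ...] = DEFAULT_CHANNELS
    label: str | None = None
    posture: float | None = None
    trial_id: str | None = None
    session_id: str | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) array")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain NaN or infinite values")
        self.channel_names = tuple(self.channel_names)
        if len(self.channel_names) != self.samples.shape[1]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.samples.shape[1]} channels"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_ms(self) -> float:
        return 1000.0 * self.n_samples / self.fs


@dataclass
class AnalysisWindow:
    """One 200 ms slice of a conditioned recording.

    ``start_time_ms`` is the time of the first sample; the decision instant
    the window informs is ``start_time_ms + window length``.
    """

    samples: np.ndarray
    start_time_ms: float
    fs: float

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]


def _design_sos(fs: float) -> np.ndarray:
    """4th-order Butterworth band-pass 20–350 Hz cascaded with a 4th-order
    band-stop 50–70 Hz."""
    bp = sps.butter(2, PASS_BAND, btype="bandpass", fs=fs, output="sos")
    bs = sps.butter(2, STOP_BAND, btype="bandstop", fs=fs, output="sos")
    return np.vstack([bp, bs])


def condition_signal(recording: EmgRecording, mode: str = "offline") -> EmgRecording:
    """Band-limit a recording to 20–350 Hz with a 50–70 Hz stop band.

    ``mode="offline"`` applies the filter forward-backward (zero phase);
    ``mode="causal"`` runs a single forward pass, as in the real-time loop,
    introducing only the filter's group delay.
    """
    if mode not in ("offline", "causal"):
        raise ValueError(f"mode must be 'offline' or 'causal', got {mode!r}")
    if recording.fs < 700.0:
        raise ValueError(
            f"sampling rate {recording.fs} Hz too low: the 350 Hz passband edge "
            "must lie below Nyquist (need fs >= 700 Hz)"
        )
    sos = _design_sos(recording.fs)
    if mode == "offline":
        out = sps.sosfiltfilt(sos, recording.samples, axis=0)
    else:
        out = sps.sosfilt(sos, recording.samples, axis=0)
    return replace(recording, samples=np.ascontiguousarray(out))


def n_windows(n_samples: int, window_samples: int, step_samples: int) -> int:
    """Closed-form sliding-window count: floor((N − W)/S) + 1, or 0 if short."""
    if n_samples < window_samples:
        return 0
    return (n_samples - window_samples) // step_samples + 1


def segment_windows(
    recording: EmgRecording, window_ms: float = 200.0, step_ms: float = 25.0
) -> list[AnalysisWindow]:
    """Slice a recording into overlapping analysis windows.

    Windows are causal: the window ending at decision time t covers
    [t − window_ms, t).  A recording shorter than one window yields an empty
    list with a warning rather than an error, so batch pipelines skip runt
    trials gracefully.
    """
    if window_ms <= 0 or step_ms <= 0:
        raise ValueError("window_ms and step_ms must be positive")
    if step_ms > window_ms:
        raise ValueError("step_ms must not exceed window_ms")
    w = int(round(window_ms * recording.fs / 1000.0))
    s = int(round(step_ms * recording.fs / 1000.0))
    count = n_windows(recording.n_samples, w, s)
    if count == 0:
        warnings.warn(
            f"recording {recording.trial_id or '<unnamed>'} shorter than one "
            f"{window_ms:g} ms window; no windows produced",
            stacklevel=2,
        )
        return []
    dt_ms = 1000.0 / recording.fs
    return [
        AnalysisWindow(
            samples=recording.samples[k * s : k * s + w],
            start_time_ms=k * s * dt_ms,
            fs=recording.fs,
        )
        for k in range(count)
    ]
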