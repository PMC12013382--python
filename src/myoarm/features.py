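"""Time-domain and autoregressive EMG features.

Per channel and window the feature set is Hudgins' four time-domain
descriptors — mean absolute value (MAV), zero crossings (ZC), slope sign
changes (SSC), waveform length (WL) — plus six Burg autoregressive
coefficients, giving 10 features per channel and 120 for a 12-channel
montage.  ZC and SSC carry a small amplitude threshold so sensor noise around
zero does not register as activity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from statsmodels.regression.linear_model import burg

__all__ = [
    "FeatureVector",
    "mav",
    "zero_crossings",
    "slope_sign_changes",
    "waveform_length",
    "ar_coefficients",
    "extract_features",
    "FEATURES_PER_CHANNEL",
    "feature_names",
]

AR_ORDER = 6
FEATURES_PER_CHANNEL = 4 + AR_ORDER
_TINY = 1e-12

_PER_CHANNEL_NAMES = ("mav", "zc", "ssc", "wl") + tuple(
    f"ar{k}" for k in range(1, AR_ORDER + 1)
)


def feature_names(channel_names) -> list[str]:
    """Channel-major feature labels, e.g. ``delt_ant:mav ... delt_ant:ar6, ...``."""
    return [f"{ch}:{f}" for ch in channel_names for f in _PER_CHANNEL_NAMES]


@dataclass
class FeatureVector:
    """One window's 10 × n_channels descriptor, channel-major.

    ``mav`` holds the per-channel MAV sub-vector separately because the
    proportional-control magnitude is defined on MAVs alone.
    """

    values: np.ndarray
    mav: np.ndarray
    start_time_ms: float = 0.0

    @property
    def n_channels(self) -> int:
        return self.mav.shape[0]


def mav(channel_window: np.ndarray) -> float:
    """Mean absolute value of one channel's window."""
    x = np.asarray(channel_window, dtype=float)
    if x.size == 0:
        raise ValueError("mav of an empty window is undefined")
    return float(np.mean(np.abs(x)))


def zero_crossings(channel_window: np.ndarray, amplitude_threshold: float = 0.0) -> int:
    """Count sign changes between consecutive samples.

    A crossing is counted only when both samples clear the amplitude
    threshold, so chatter around zero in a quiet channel is ignored.
    """
    if amplitude_threshold < 0:
        raise ValueError("amplitude_threshold must be non-negative")
    x = np.asarray(channel_window, dtype=float)
    if x.size < 2:
        return 0
    a, b = x[:-1], x[1:]
    gate = np.minimum(np.abs(a), np.abs(b)) >= amplitude_threshold
    return int(np.count_nonzero((a * b < 0) & gate))


def slope_sign_changes(
    channel_window: np.ndarray, amplitude_threshold: float = 0.0
) -> int:
    """Count local extrema: interior samples where the slope changes sign.

    Sample i counts when (x_i − x_{i−1})(x_i − x_{i+1}) ≥ max(threshold, tiny);
    the tiny floor excludes flat runs.
    """
    if amplitude_threshold < 0:
        raise ValueError("amplitude_threshold must be non-negative")
    x = np.asarray(channel_window, dtype=float)
    if x.size < 3:
        warnings.warn("slope_sign_changes needs at least 3 samples; returning 0",
                      stacklevel=2)
        return 0
    d1 = x[1:-1] - x[:-2]
    d2 = x[1:-1] - x[2:]
    return int(np.count_nonzero(d1 * d2 >= max(amplitude_threshold, _TINY)))


def waveform_length(channel_window: np.ndarray) -> float:
    """Cumulative absolute first difference — the path length of the trace."""
    x = np.asarray(channel_window, dtype=float)
    if x.size < 2:
        warnings.warn("waveform_length needs at least 2 samples; returning 0.0",
                      stacklevel=2)
        return 0.0
    return float(np.sum(np.abs(np.diff(x))))


def ar_coefficients(channel_window: np.ndarray, order: int = AR_ORDER) -> np.ndarray:
    """Burg AR coefficients of one channel's window.

    Sign convention: x_t = a1·x_{t−1} + … + a_order·x_{t−order} + e_t, so an
    AR(1) process with coefficient 0.5 yields a1 ≈ 0.5.  Degenerate windows
    (constant or all-zero) fall back to all-zero coefficients with a warning —
    the real-time loop must never see an exception from a quiet channel.
    """
    x = np.asarray(channel_window, dtype=float)
    if x.size <= order:
        raise ValueError(f"window of {x.size} samples cannot fit AR({order})")
    if np.ptp(x) < _TINY:
        warnings.warn("degenerate (constant) window: AR coefficients set to zero",
                      stacklevel=2)
        return np.zeros(order)
    try:
        rho, _ = burg(x, order=order, demean=True)
        if not np.all(np.isfinite(rho)):
            raise FloatingPointError("non-finite AR estimate")
        return np.asarray(rho, dtype=float)
    except Exception as exc:  # pragma: no cover - defensive real-time fallback
        warnings.warn(f"AR estimation failed ({exc}); coefficients set to zero",
                      stacklevel=2)
        return np.zeros(order)


def extract_features(window, thresholds=0.0) -> FeatureVector:
    """Featurize one analysis window into the channel-major 10×NCH vector.

    ``thresholds`` is the ZC/SSC amplitude gate: a scalar applied to every
    channel or a per-channel array (typically 0.01 × that channel's
    training-data RMS).
    """
    samples = np.asarray(window.samples, dtype=float)
    n_ch = samples.shape[1]
    thr = np.broadcast_to(np.asarray(thresholds, dtype=float), (n_ch,))
    values = np.empty(FEATURES_PER_CHANNEL * n_ch)
    mavs = np.empty(n_ch)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate-channel fallbacks are fine here
        for j in range(n_ch):
            x = samples[:, j]
            m = mav(x)
            mavs[j] = m
            base = j * FEATURES_PER_CHANNEL
            values[base] = m
            values[base + 1] = zero_crossings(x, thr[j])
            values[base + 2] = slope_sign_changes(x, thr[j])
            values[base + 3] = waveform_length(x)
            values[base + 4 : base + 4 + AR_ORDER] = ar_coefficients(x)
    return FeatureVector(values=values, mav=mavs,
                         start_time_ms=getattr(window, "start_time_ms", 0.0))
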