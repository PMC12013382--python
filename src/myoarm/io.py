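"""Plain-text file formats: EMG trial CSVs, trial records, run configuration.

Trials are tiny (≤ 10 s × 1 kHz × 12 channels), so everything is inspectable
CSV with a JSON sidecar carrying metadata; configuration is YAML or JSON.
Every output directory gets a manifest with the configuration hash and seeds
so an experiment can be re-run exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import emg_envelope
from .robot import TrialRecord
from .signal import DEFAULT_CHANNELS, EmgRecording

__all__ = [
    "read_emg_csv",
    "write_emg_csv",
    "write_trial_csv",
    "read_trial_csv",
    "RunConfig",
    "write_manifest",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_emg_csv(recording: EmgRecording, path: str | Path) -> None:
    """Write a trial as ``time_ms,ch01..chNN`` CSV plus a JSON sidecar."""
    path = Path(path)
    n = recording.n_samples
    cols = {"time_ms": np.arange(n) * 1000.0 / recording.fs}
    for j in range(recording.n_channels):
        cols[f"ch{j + 1:02d}"] = recording.samples[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")
    meta = {
        "fs": recording.fs,
        "channel_names": list(recording.channel_names),
        "label": recording.label,
        "posture": recording.posture,
        "trial_id": recording.trial_id,
        "session_id": recording.session_id,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_emg_csv(path: str | Path, expect_channels: int | None = None
                 ) -> EmgRecording:
    """Read a trial CSV, validating header, monotonic time and finiteness."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.columns[0] != "time_ms":
        raise ValueError(f"{path}: first column must be 'time_ms', "
                         f"got {df.columns[0]!r}")
    ch_cols = [c for c in df.columns[1:] if c.startswith("ch")]
    if list(df.columns[1:]) != ch_cols or not ch_cols:
        raise ValueError(f"{path}: expected channel columns ch01..chNN after "
                         "time_ms")
    if expect_channels is not None and len(ch_cols) != expect_channels:
        raise ValueError(f"{path}: found {len(ch_cols)} channel columns, "
                         f"configuration demands {expect_channels}")
    t = df["time_ms"].to_numpy()
    if np.any(np.diff(t) <= 0):
        raise ValueError(f"{path}: time_ms column is not strictly increasing")
    samples = df[ch_cols].to_numpy(dtype=float)
    if not np.all(np.isfinite(samples)):
        raise ValueError(f"{path}: samples contain NaN or infinite values")

    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    fs = meta.get("fs")
    if fs is None:
        fs = 1000.0 / float(np.median(np.diff(t)))
    names = meta.get("channel_names") or (
        DEFAULT_CHANNELS if len(ch_cols) == 12 else tuple(ch_cols))
    return EmgRecording(
        samples=samples, fs=float(fs), channel_names=tuple(names),
        label=meta.get("label"), posture=meta.get("posture"),
        trial_id=meta.get("trial_id"), session_id=meta.get("session_id"),
    )


def write_trial_csv(trial: TrialRecord, path: str | Path) -> None:
    """Write a closed-loop trial record: kinematics, forces and the smoothed
    per-channel EMG envelope (env01..envNN)."""
    path = Path(path)
    env = emg_envelope(trial.emg, trial.fs)
    cols = {
        "time_ms": trial.time_ms,
        "theta_abd": trial.theta_abd,
        "theta_h": trial.theta_h,
        "phi_e": trial.phi_e,
        "z": trial.z,
        "F_applied": trial.F_applied,
        "F_sensed": trial.F_sensed,
    }
    for j in range(env.shape[1]):
        cols[f"env{j + 1:02d}"] = env[:, j]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.6g")
    _sidecar(path).write_text(json.dumps({
        "fs": trial.fs, "condition": trial.condition,
        "trial_id": trial.trial_id, "truncated": trial.truncated,
        "n_decisions": len(trial.decisions),
    }, indent=1))


def read_trial_csv(path: str | Path) -> TrialRecord:
    """Read back a trial record CSV (the env columns stand in for raw EMG)."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(_sidecar(path).read_text()) if _sidecar(path).exists() else {}
    env_cols = [c for c in df.columns if c.startswith("env")]
    return TrialRecord(
        time_ms=df["time_ms"].to_numpy(),
        theta_abd=df["theta_abd"].to_numpy(),
        theta_h=df["theta_h"].to_numpy(),
        phi_e=df["phi_e"].to_numpy(),
        z=df["z"].to_numpy(),
        F_applied=df["F_applied"].to_numpy(),
        F_sensed=df["F_sensed"].to_numpy(),
        emg=df[env_cols].to_numpy(dtype=float),
        fs=float(meta.get("fs", 1000.0)),
        condition=meta.get("condition", "no_support"),
        trial_id=meta.get("trial_id", path.stem),
        truncated=bool(meta.get("truncated", False)),
    )


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, loadable from YAML/JSON."""

    fs: float = 1000.0
    n_channels: int = 12
    window_ms: float = 200.0
    step_ms: float = 25.0
    shrinkage: float = 0.1
    eq1_variant: str = "squared"
    controller_mode: str = "position"
    seed: int = 0
    n_trials: int = 10
    k_syn: float = 0.6
    noise_sd: float = 0.02
    arm: dict = field(default_factory=lambda: {"L_u": 0.30, "L_f": 0.35, "W": 30.0})
    out_dir: str = "runs"

    def __post_init__(self) -> None:
        if not self.window_ms > self.step_ms > 0:
            raise ValueError("require window_ms > step_ms > 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") \
            else json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def write_manifest(out_dir: str | Path, config: RunConfig, **extra) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": asdict(config), "config_hash": config.hash(),
                "seed": config.seed, **extra}
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=1))
    return p
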