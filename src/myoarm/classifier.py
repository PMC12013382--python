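"""Three-class minimum-Mahalanobis EMG classifier with proportional control.

The intent decoder is LDA-style: each movement class (no-movement, abduction,
adduction) is summarized by its mean feature vector, all classes share one
pooled within-class covariance, and a window is assigned to the class whose
mean is nearest in Mahalanobis distance.  Alongside the class label the
decoder emits a proportional-control magnitude

    PC_i = (1 / C_i) Σ_j S_ij · MAV_j²

where S_ij is the class/channel center — the mean training MAV of class i on
channel j — and C_i = Σ_j S_ij² normalizes per class.  PC scales the commanded
change per decision, so stronger contractions move the support faster.

With 120-dimensional features estimated from a few thousand windows the raw
pooled covariance is ill-conditioned; a convex shrinkage toward its diagonal,
Σ_λ = (1−λ)Σ + λ·diag(Σ), keeps it positive definite.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .features import FEATURES_PER_CHANNEL, FeatureVector

__all__ = [
    "CLASSES",
    "ClassifierModel",
    "Decision",
    "compute_centers",
    "compute_normalization",
    "proportional_control",
    "train",
    "classify",
    "save_model",
    "load_model",
]

#: fixed class order; index 0 is the safe "do nothing" class
CLASSES: tuple[str, ...] = ("no_movement", "abduction", "adduction")
NO_MOVEMENT = 0


@dataclass
class Decision:
    """One 25 ms classifier output: class, PC magnitude, and all distances."""

    time_ms: float
    class_index: int
    class_label: str
    pc: float
    distances: np.ndarray


@dataclass
class ClassifierModel:
    classes: tuple[str, ...]
    class_means: np.ndarray        # (n_classes, n_features)
    pooled_covariance: np.ndarray  # shrunk, (n_features, n_features)
    shrinkage: float
    centers: np.ndarray            # S[i, j], (n_classes, n_channels)
    normalization: np.ndarray      # C[i]
    n_channels: int
    feature_order: tuple[str, ...]
    thresholds: np.ndarray         # per-channel ZC/SSC gates used at training
    eq1_variant: str = "squared"   # "squared": Σ S·MAV²; "dot": Σ S·MAV
    _chol: tuple | None = field(default=None, repr=False, compare=False)

    @property
    def n_features(self) -> int:
        return self.class_means.shape[1]

    def _factor(self):
        if self._chol is None:
            self._chol = cho_factor(self.pooled_covariance, lower=True)
        return self._chol


def compute_centers(training_mavs_by_class: Sequence[np.ndarray]) -> np.ndarray:
    """Class/channel centers S[i, j]: mean training-window MAV.

    ``training_mavs_by_class[i]`` is (n_windows_i, n_channels).  Every
    class/channel cell needs at least one window.
    """
    rows = []
    for i, m in enumerate(training_mavs_by_class):
        m = np.asarray(m, dtype=float)
        if m.ndim != 2 or m.shape[0] == 0:
            raise ValueError(f"class {i}: need a (n_windows, n_channels) MAV "
                             "array with at least one window")
        row = m.mean(axis=0)
        silent = np.flatnonzero(row == 0.0)
        if silent.size:
            warnings.warn(f"class {i}: silent channel(s) {silent.tolist()} "
                          "(zero training MAV)", stacklevel=2)
        rows.append(row)
    return np.vstack(rows)


def compute_normalization(centers_row: np.ndarray) -> float:
    """C_i = Σ_j S_ij² for one class; zero flags the class unusable for PC."""
    c = float(np.sum(np.square(np.asarray(centers_row, dtype=float))))
    if c == 0.0:
        warnings.warn("normalization factor is zero: class unusable for "
                      "proportional control", stacklevel=2)
    return c


def proportional_control(
    mav_vector: np.ndarray, model: ClassifierModel, class_index: int
) -> float:
    """PC_i for a window's per-channel MAVs against class i's stored centers."""
    m = np.asarray(mav_vector, dtype=float)
    if m.shape[0] != model.n_channels:
        raise ValueError(f"MAV vector has {m.shape[0]} entries for "
                         f"{model.n_channels} channels")
    c = model.normalization[class_index]
    if c == 0.0:
        warnings.warn(f"C[{class_index}] = 0; PC forced to 0", stacklevel=2)
        return 0.0
    s = model.centers[class_index]
    if model.eq1_variant == "dot":
        return float(np.dot(s, m) / c)
    return float(np.dot(s, np.square(m)) / c)


def _pooled_covariance(features_by_class: Sequence[np.ndarray],
                       means: np.ndarray) -> np.ndarray:
    """Within-class scatter pooled across classes, normalized by N − g."""
    n_total = sum(f.shape[0] for f in features_by_class)
    g = len(features_by_class)
    p = means.shape[1]
    scatter = np.zeros((p, p))
    for i, f in enumerate(features_by_class):
        d = f - means[i]
        scatter += d.T @ d
    return scatter / max(n_total - g, 1)


def train(
    features_by_class: Mapping[str, Sequence[FeatureVector]] | Sequence[np.ndarray],
    shrinkage: float = 0.1,
    *,
    classes: tuple[str, ...] = CLASSES,
    feature_order: tuple[str, ...] | None = None,
    thresholds: np.ndarray | float = 0.0,
    eq1_variant: str = "squared",
) -> ClassifierModel:
    """Fit the 3-class model from labeled training windows.

    ``features_by_class`` maps class label → windows (FeatureVector sequence),
    or is a list of (n_windows, n_features) arrays in class order.  Requires
    at least two windows per class.
    """
    if eq1_variant not in ("squared", "dot"):
        raise ValueError("eq1_variant must be 'squared' or 'dot'")
    if not 0.0 <= shrinkage <= 1.0:
        raise ValueError("shrinkage must lie in [0, 1]")

    if isinstance(features_by_class, Mapping):
        missing = [c for c in classes if c not in features_by_class]
        if missing:
            raise ValueError(f"missing training data for class(es) {missing}")
        arrays, mav_arrays = [], []
        for c in classes:
            fvs = list(features_by_class[c])
            arrays.append(np.vstack([fv.values for fv in fvs]))
            mav_arrays.append(np.vstack([fv.mav for fv in fvs]))
    else:
        arrays = [np.asarray(a, dtype=float) for a in features_by_class]
        n_ch = arrays[0].shape[1] // FEATURES_PER_CHANNEL
        mav_arrays = [a[:, 0 : n_ch * FEATURES_PER_CHANNEL : FEATURES_PER_CHANNEL]
                      for a in arrays]

    p = arrays[0].shape[1]
    for i, a in enumerate(arrays):
        if a.shape[1] != p:
            raise ValueError("inconsistent feature length across classes")
        if a.shape[0] < 2:
            raise ValueError(f"class {classes[i]!r} has {a.shape[0]} window(s); "
                             "need at least 2")
    n_channels = mav_arrays[0].shape[1]

    means = np.vstack([a.mean(axis=0) for a in arrays])
    cov = _pooled_covariance(arrays, means)
    cov_shrunk = (1.0 - shrinkage) * cov + shrinkage * np.diag(np.diag(cov))
    cov_shrunk = 0.5 * (cov_shrunk + cov_shrunk.T)
    evals = np.linalg.eigvalsh(cov_shrunk)
    if evals[0] <= 1e-10 * max(evals[-1], 1e-300):
        raise ValueError(
            "pooled covariance is singular even after shrinkage "
            f"(λ = {shrinkage}); increase the shrinkage parameter"
        )

    centers = compute_centers(mav_arrays)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        normalization = np.array([compute_normalization(r) for r in centers])

    if feature_order is None:
        feature_order = tuple(f"f{k}" for k in range(p))
    return ClassifierModel(
        classes=tuple(classes),
        class_means=means,
        pooled_covariance=cov_shrunk,
        shrinkage=shrinkage,
        centers=centers,
        normalization=normalization,
        n_channels=n_channels,
        feature_order=tuple(feature_order),
        thresholds=np.broadcast_to(np.asarray(thresholds, dtype=float),
                                   (n_channels,)).copy(),
        eq1_variant=eq1_variant,
    )


def mahalanobis_distances(x: np.ndarray, model: ClassifierModel) -> np.ndarray:
    """d_i = sqrt((x − μ_i)ᵀ Σ⁻¹ (x − μ_i)) for every class, pooled Σ."""
    x = np.asarray(x, dtype=float)
    if x.shape[0] != model.n_features:
        raise ValueError(f"feature vector length {x.shape[0]} != model "
                         f"{model.n_features}")
    diffs = x - model.class_means          # (n_classes, p)
    sol = cho_solve(model._factor(), diffs.T)  # Σ⁻¹ diffsᵀ
    return np.sqrt(np.maximum(np.einsum("ip,pi->i", diffs, sol), 0.0))


def classify(feature_vector: FeatureVector | np.ndarray,
             model: ClassifierModel, time_ms: float | None = None) -> Decision:
    """Assign a window to the nearest class mean and compute its PC.

    Exact distance ties resolve to no-movement when it participates (an
    ambiguous window must not move the robot), else to the lowest class index.
    """
    if isinstance(feature_vector, FeatureVector):
        x = feature_vector.values
        mav_vec = feature_vector.mav
        t = feature_vector.start_time_ms if time_ms is None else time_ms
    else:
        x = np.asarray(feature_vector, dtype=float)
        if x.shape[0] == model.n_channels * FEATURES_PER_CHANNEL:
            # channel-major layout: MAV leads each per-channel block
            mav_vec = x[0 :: FEATURES_PER_CHANNEL]
        else:
            # feature space without the standard layout: treat the leading
            # entries as per-channel amplitudes
            mav_vec = np.abs(x[: model.n_channels])
        t = 0.0 if time_ms is None else time_ms

    d = mahalanobis_distances(x, model)
    tied = np.flatnonzero(d == d.min())
    idx = NO_MOVEMENT if NO_MOVEMENT in tied else int(tied[0])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pc = proportional_control(mav_vec, model, idx)
    return Decision(time_ms=float(t), class_index=idx,
                    class_label=model.classes[idx], pc=pc, distances=d)


# ---------------------------------------------------------------------------
# serialization — portable JSON container

def save_model(model: ClassifierModel, path: str | Path) -> None:
    payload = {
        "format": "myoarm-classifier-v1",
        "classes": list(model.classes),
        "shrinkage": model.shrinkage,
        "eq1_variant": model.eq1_variant,
        "n_channels": model.n_channels,
        "feature_order": list(model.feature_order),
        "class_means": model.class_means.tolist(),
        "pooled_covariance": model.pooled_covariance.tolist(),
        "centers": model.centers.tolist(),
        "normalization": model.normalization.tolist(),
        "thresholds": model.thresholds.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> ClassifierModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "myoarm-classifier-v1":
        raise ValueError(f"{path}: not a myoarm classifier model file")
    return ClassifierModel(
        classes=tuple(payload["classes"]),
        class_means=np.asarray(payload["class_means"]),
        pooled_covariance=np.asarray(payload["pooled_covariance"]),
        shrinkage=float(payload["shrinkage"]),
        centers=np.asarray(payload["centers"]),
        normalization=np.asarray(payload["normalization"]),
        n_channels=int(payload["n_channels"]),
        feature_order=tuple(payload["feature_order"]),
        thresholds=np.asarray(payload["thresholds"]),
        eq1_variant=payload["eq1_variant"],
    )
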