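"""One-class detector: Z-score standardisation, one-class SVM, track voting.

The reference class (swarming males) defines "normal": a one-class SVM is
trained on male segments only and everything outside its decision boundary
is called anomalous (non-male).  The nu parameter upper-bounds the fraction
of training errors and lower-bounds the fraction of support vectors.
Standardisation statistics are fitted on the male training rows exclusively
and applied unchanged to all test rows.

Per-segment calls are combined per track by majority vote; an exact tie is
resolved to the anomaly class.  The signed distance to the hyperplane acts
as a confidence proxy and is mapped to a pseudo-probability through the
logistic function for ranking-based metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field

import numpy as np
import pandas as pd
from sklearn.preprocessing import StandardScaler
from sklearn.svm import OneClassSVM

#: Tuned operating point: nu = 0.20 with the radial-basis kernel.
DEFAULT_NU = 0.20
DEFAULT_KERNEL = "rbf"

KERNELS = ("linear", "rbf", "poly", "sigmoid")
#: Long-form aliases accepted in configs.
KERNEL_ALIASES = {
    "radial_basis": "rbf",
    "radial_basis_function": "rbf",
    "polynomial": "poly",
}


@dataclass
class DetectorConfig:
    nu: float = DEFAULT_NU
    kernel: str = DEFAULT_KERNEL
    gamma: str | float = "scale"
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        self.kernel = KERNEL_ALIASES.get(self.kernel, self.kernel)
        if not 0.0 < self.nu <= 1.0:
            raise ValueError(f"nu must be in (0, 1], got {self.nu}")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class SegmentPredictions:
    """Per-segment outputs with track lineage preserved."""

    frame: pd.DataFrame  # columns: segment_id, track_id, trial_id, label,
    #                               decision, is_male, probability


@dataclass
class TrackPredictions:
    frame: pd.DataFrame  # columns: track_id, trial_id, label, n_segments,
    #                               n_male_segments, decision, is_male, probability


@dataclass
class TrainedDetector:
    config: DetectorConfig
    feature_names: list[str]
    scaler: StandardScaler
    model: OneClassSVM
    imputation_medians: dict[str, float] = dataclass_field(default_factory=dict)

    def standardise(self, matrix: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in matrix.columns]
        if missing:
            raise ValueError(f"feature matrix lacks columns {missing}")
        X = matrix[self.feature_names].to_numpy(dtype=float)
        if self.imputation_medians:
            med = np.array(
                [self.imputation_medians.get(f, 0.0) for f in self.feature_names]
            )
            X = np.where(np.isfinite(X), X, med)
        return self.scaler.transform(X)


def save(det: TrainedDetector, path) -> None:
    """Persist a trained detector (scaler, SVM, schema, imputation)."""
    import joblib

    joblib.dump(det, path)


def load(path) -> TrainedDetector:
    """Load a detector previously written by `save`."""
    import joblib

    det = joblib.load(path)
    if not isinstance(det, TrainedDetector):
        raise ValueError(f"{path} does not contain a trained detector")
    return det


def fit(
    matrix: pd.DataFrame,
    feature_names: list[str],
    config: DetectorConfig | None = None,
    imputation_medians: dict[str, float] | None = None,
) -> TrainedDetector:
    """Fit scaler + one-class SVM on male training segments.

    `matrix` must contain only male-labelled rows (lineage `label` column,
    if present, is checked) — anything else is a contract violation, since
    the one-class design must never see anomalies during training.
    """
    config = config or DetectorConfig()
    if "label" in matrix.columns:
        labels = set(matrix["label"].unique())
        if not labels <= {"male"}:
            raise ValueError(
                f"fit() requires male-only training rows, got labels {sorted(labels)}"
            )
    if len(matrix) < 10:
        raise ValueError("need >= 10 training segments")
    X = matrix[list(feature_names)].to_numpy(dtype=float)
    if imputation_medians:
        med = np.array([imputation_medians.get(f, 0.0) for f in feature_names])
        X = np.where(np.isfinite(X), X, med)
    scaler = StandardScaler().fit(X)
    model = OneClassSVM(
        nu=config.nu,
        kernel=config.kernel,
        gamma=config.gamma,
        degree=config.degree,
        coef0=config.coef0,
    )
    model.fit(scaler.transform(X))
    return TrainedDetector(
        config=config,
        feature_names=list(feature_names),
        scaler=scaler,
        model=model,
        imputation_medians=dict(imputation_medians or {}),
    )


def logistic(x: np.ndarray) -> np.ndarray:
    """Map a signed hyperplane distance to (0, 1)."""
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def predict_segments(det: TrainedDetector, matrix: pd.DataFrame) -> SegmentPredictions:
    """Signed decision value, binary call and pseudo-probability per row."""
    Xs = det.standardise(matrix)
    decision = det.model.decision_function(Xs)
    is_male = decision >= 0
    frame = pd.DataFrame(
        {
            "segment_id": matrix.get("segment_id", pd.RangeIndex(len(matrix)).astype(str)),
            "track_id": matrix.get("track_id", ""),
            "trial_id": matrix.get("trial_id", ""),
            "label": matrix.get("label", "unknown"),
            "decision": decision,
            "is_male": is_male,
            "probability": logistic(decision),
        }
    ).reset_index(drop=True)
    return SegmentPredictions(frame)


def vote_tracks(preds: SegmentPredictions) -> TrackPredictions:
    """Majority vote over a track's segment calls; exact tie -> anomalous.

    The track-level decision value — used for ROC/PR ranking — is the mean
    of the segment decision values (configurable alternative: the male vote
    fraction; the mean is smoother).
    """
    rows = []
    for track_id, group in preds.frame.groupby("track_id", sort=True):
        n = len(group)
        n_male = int(group["is_male"].sum())
        is_male = n_male * 2 > n  # strict majority; tie -> non-male
        decision = float(group["decision"].mean())
        rows.append(
            {
                "track_id": track_id,
                "trial_id": group["trial_id"].iloc[0],
                "label": group["label"].iloc[0],
                "n_segments": n,
                "n_male_segments": n_male,
                "decision": decision,
                "is_male": is_male,
                "probability": float(logistic(np.array([decision]))[0]),
            }
        )
    return TrackPredictions(pd.DataFrame(rows))
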