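"""Trial-wise cross-validation, the metric suite, and trial-level QC.

Evaluation follows a leave-2-trials-out scheme over the reference-class
(male) trials: each fold holds out one unordered pair of male trials for
testing and trains on the segments of the remaining male trials.  Non-male
tracks can never enter training (the detector is one-class), but the feature
screen needs anomalous examples, so a fixed subset of non-male trials is
reserved for screening and excluded from testing; the remaining non-male
trials (plus any female / focal-male trials) are tested in every fold.

Expected outcomes per class: male and focal-male tracks should be called
male; couple and female tracks should be called non-male.  Reported metrics
are computed at track level against those expectations, averaged over folds
with percentile 95% confidence intervals, alongside a pooled confusion
matrix summed over folds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2
from sklearn.metrics import (
    accuracy_score,
    average_precision_score,
    balanced_accuracy_score,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)

from . import detector as det_mod
from . import features as feat_mod
from . import selection as sel_mod
from .detector import DetectorConfig, TrainedDetector
from .tracks import MALE_LIKE, NON_MALE, Dataset

logger = logging.getLogger(__name__)

#: Expected binary outcome ("male" inlier / "non_male" outlier) per class.
EXPECTED_MAP = {
    "male": True,
    "focal_male": True,
    "couple": False,
    "female": False,
}

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "precision_male",
    "recall_male",
    "f1_male",
    "precision_nonmale",
    "recall_nonmale",
    "f1_nonmale",
    "precision",
    "recall",
    "f1",
    "roc_auc",
    "pr_auc_male",
    "pr_auc_nonmale",
    "pr_auc",
)


@dataclass
class FoldSpec:
    fold_id: str
    male_test: tuple[str, str]
    male_train: list[str]
    screen_trials: list[str]
    other_test: list[str]

    def __post_init__(self) -> None:
        overlap = set(self.male_test) & set(self.male_train)
        if overlap:
            raise ValueError(f"male trials in both train and test: {overlap}")


@dataclass
class FoldResult:
    fold: FoldSpec
    selection: sel_mod.SelectionResult
    detector: TrainedDetector
    segment_frame: pd.DataFrame
    track_frame: pd.DataFrame  # adds expected_male column


@dataclass
class MetricsReport:
    per_fold: pd.DataFrame
    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    confusion: dict[str, int]  # pooled over folds: tp/fp/fn/tn, male positive
    subclass_accuracy: dict[str, float]
    n_folds: int = 0


def make_folds(
    male_trials: list[str],
    screen_trials: list[str] | None = None,
    other_test: list[str] | None = None,
) -> list[FoldSpec]:
    """One fold per unordered pair of male trials, in sorted order.

    8 male trials therefore yield C(8,2) = 28 folds.
    """
    male_trials = sorted(set(male_trials))
    if len(male_trials) < 3:
        raise ValueError("need >= 3 male trials for leave-2-out folds")
    folds = []
    for a, b in itertools.combinations(male_trials, 2):
        folds.append(
            FoldSpec(
                fold_id=f"{a}+{b}",
                male_test=(a, b),
                male_train=[t for t in male_trials if t not in (a, b)],
                screen_trials=sorted(screen_trials or []),
                other_test=sorted(other_test or []),
            )
        )
    return folds


def plan_folds(
    dataset: Dataset,
    n_screen_trials: int = 2,
    validation_trials: list[str] | None = None,
) -> list[FoldSpec]:
    """Derive the fold plan from a labelled dataset.

    Male trials rotate through test pairs; the first `n_screen_trials`
    (sorted) non-male trials are reserved for the feature screen; remaining
    non-male / focal-male trials are tested in every fold.  Validation
    trials (used for hyperparameter tuning) are excluded everywhere.
    """
    excluded = set(validation_trials or [])
    male_trials = [t for t in dataset.trials_with_label("male") if t not in excluded]
    nonmale_trials = sorted(
        {
            trial.trial_id
            for trial in dataset.trials
            if any(lbl in NON_MALE for lbl in trial.labels())
        }
        - set(male_trials)
        - excluded
    )
    screen = nonmale_trials[:n_screen_trials]
    other = [
        t.trial_id
        for t in dataset.trials
        if t.trial_id not in set(male_trials) | set(screen) | excluded
    ]
    return make_folds(male_trials, screen, other)


def train_and_predict(
    matrix: pd.DataFrame,
    male_train: list[str],
    screen_trials: list[str],
    test_mask: pd.Series,
    config: DetectorConfig | None = None,
    alpha: float = sel_mod.DEFAULT_ALPHA,
    corr_threshold: float = sel_mod.DEFAULT_CORR_THRESHOLD,
    tag: str = "",
) -> tuple[sel_mod.SelectionResult, TrainedDetector, pd.DataFrame, pd.DataFrame]:
    """Select, fit and predict for one train/test split of the matrix.

    Training rows are the male segments of `male_train` trials; screening
    rows are the non-male segments of `screen_trials`; imputation medians,
    the feature screen, the scaler and the detector all see training and
    screening rows only, so no test trial can leak into any fitted state.
    Returns (selection, detector, segment frame, track frame); the track
    frame carries an `expected_male` column from the per-class expectation.
    """
    config = config or DetectorConfig()
    trial = matrix["trial_id"]
    label = matrix["label"]
    train_rows = matrix[(label == "male") & trial.isin(male_train)]
    screen_rows = matrix[label.isin(NON_MALE) & trial.isin(screen_trials)]
    test_rows = matrix[test_mask]
    if test_rows.empty:
        raise ValueError(f"split {tag}: empty test set")
    if screen_rows.empty:
        raise ValueError(
            f"split {tag}: no non-male screening segments "
            f"(screen trials {screen_trials})"
        )

    medians = feat_mod.fit_imputer(
        pd.concat([train_rows, screen_rows], ignore_index=True)
    )
    train_imp = feat_mod.impute(train_rows, medians)
    screen_imp = feat_mod.impute(screen_rows, medians)

    schema = feat_mod.feature_columns(matrix)
    selection = sel_mod.select_features(
        train_imp[schema], screen_imp[schema], schema, alpha, corr_threshold
    )
    selected = selection.selected
    if not selected:
        # fall back to the full schema rather than abort the split
        logger.warning("split %s: no feature passed the screen", tag)
        selected = schema

    trained = det_mod.fit(train_imp, selected, config, imputation_medians=medians)
    seg_preds = det_mod.predict_segments(trained, test_rows)
    track_frame = det_mod.vote_tracks(seg_preds).frame.copy()
    track_frame["expected_male"] = track_frame["label"].map(EXPECTED_MAP)
    track_frame = track_frame[track_frame["expected_male"].notna()]
    track_frame["expected_male"] = track_frame["expected_male"].astype(bool)
    return selection, trained, seg_preds.frame, track_frame


def run_fold(
    fold: FoldSpec,
    matrix: pd.DataFrame,
    config: DetectorConfig | None = None,
    alpha: float = sel_mod.DEFAULT_ALPHA,
    corr_threshold: float = sel_mod.DEFAULT_CORR_THRESHOLD,
) -> FoldResult:
    """Select features, fit and predict for one leave-2-trials-out fold."""
    trial = matrix["trial_id"]
    label = matrix["label"]
    test_mask = trial.isin(fold.male_test) | (
        label.isin(set(EXPECTED_MAP)) & trial.isin(fold.other_test)
    )
    selection, trained, seg_frame, track_frame = train_and_predict(
        matrix,
        fold.male_train,
        fold.screen_trials,
        test_mask,
        config,
        alpha,
        corr_threshold,
        tag=fold.fold_id,
    )
    track_frame.insert(0, "fold_id", fold.fold_id)
    return FoldResult(fold, selection, trained, seg_frame, track_frame)


def _fold_metrics(track_frame: pd.DataFrame) -> dict[str, float]:
    y_true = track_frame["expected_male"].to_numpy(dtype=bool)
    y_pred = track_frame["is_male"].to_numpy(dtype=bool)
    score = track_frame["decision"].to_numpy(dtype=float)
    out = {
        "accuracy": accuracy_score(y_true, y_pred),
        "balanced_accuracy": balanced_accuracy_score(y_true, y_pred),
        "precision_male": precision_score(y_true, y_pred, zero_division=0),
        "recall_male": recall_score(y_true, y_pred, zero_division=0),
        "f1_male": f1_score(y_true, y_pred, zero_division=0),
        "precision_nonmale": precision_score(~y_true, ~y_pred, zero_division=0),
        "recall_nonmale": recall_score(~y_true, ~y_pred, zero_division=0),
        "f1_nonmale": f1_score(~y_true, ~y_pred, zero_division=0),
    }
    out["precision"] = (out["precision_male"] + out["precision_nonmale"]) / 2
    out["recall"] = (out["recall_male"] + out["recall_nonmale"]) / 2
    out["f1"] = (out["f1_male"] + out["f1_nonmale"]) / 2
    if len(np.unique(y_true)) == 2:
        out["roc_auc"] = roc_auc_score(y_true, score)
        out["pr_auc_male"] = average_precision_score(y_true, score)
        out["pr_auc_nonmale"] = average_precision_score(~y_true, -score)
        out["pr_auc"] = (out["pr_auc_male"] + out["pr_auc_nonmale"]) / 2
    else:
        logger.info("single-class fold: ranking metrics undefined, excluded")
        for k in ("roc_auc", "pr_auc_male", "pr_auc_nonmale", "pr_auc"):
            out[k] = float("nan")
    return {k: float(v) for k, v in out.items()}


def compute_metrics(results: list[FoldResult]) -> MetricsReport:
    """Fold-averaged metric suite with percentile 95% CIs over folds."""
    if not results:
        raise ValueError("need at least one fold")
    rows = []
    confusion = {"tp": 0, "fp": 0, "fn": 0, "tn": 0}
    sub_hits: dict[str, list[int]] = {}
    for res in results:
        m = _fold_metrics(res.track_frame)
        m["fold_id"] = res.fold.fold_id
        rows.append(m)
        yt = res.track_frame["expected_male"].to_numpy(dtype=bool)
        yp = res.track_frame["is_male"].to_numpy(dtype=bool)
        confusion["tp"] += int(np.sum(yt & yp))
        confusion["fp"] += int(np.sum(~yt & yp))
        confusion["fn"] += int(np.sum(yt & ~yp))
        confusion["tn"] += int(np.sum(~yt & ~yp))
        for lbl, grp in res.track_frame.groupby("label"):
            hits = (grp["is_male"] == grp["expected_male"]).astype(int).tolist()
            sub_hits.setdefault(str(lbl), []).extend(hits)
    per_fold = pd.DataFrame(rows)
    mean, lo, hi = {}, {}, {}
    for name in METRIC_NAMES:
        vals = per_fold[name].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            mean[name] = lo[name] = hi[name] = float("nan")
        else:
            mean[name] = float(np.mean(vals))
            lo[name] = float(np.percentile(vals, 2.5))
            hi[name] = float(np.percentile(vals, 97.5))
    subclass = {
        lbl: float(np.mean(hits)) for lbl, hits in sorted(sub_hits.items())
    }
    return MetricsReport(
        per_fold=per_fold,
        mean=mean,
        ci_low=lo,
        ci_high=hi,
        confusion=confusion,
        subclass_accuracy=subclass,
        n_folds=len(results),
    )


def cross_validate(
    dataset: Dataset,
    window_s: float = 1.6,
    overlap_s: float = 0.8,
    config: DetectorConfig | None = None,
    alpha: float = sel_mod.DEFAULT_ALPHA,
    corr_threshold: float = sel_mod.DEFAULT_CORR_THRESHOLD,
    n_screen_trials: int = 2,
    validation_trials: list[str] | None = None,
) -> tuple[MetricsReport, list[FoldResult], pd.DataFrame]:
    """End-to-end leave-2-trials-out evaluation of a labelled dataset.

    Filters short tracks, windows, extracts features once, then runs every
    fold of the plan and aggregates the metric suite.  Returns the report,
    the per-fold results and the shared feature matrix.
    """
    from .segmentation import window_dataset
    from .tracks import filter_short_tracks

    filtered = filter_short_tracks(dataset, window_s)
    segments = window_dataset(filtered, window_s, overlap_s)
    matrix = feat_mod.build_feature_matrix(segments)
    folds = plan_folds(filtered, n_screen_trials, validation_trials)
    results = [
        run_fold(fold, matrix, config, alpha, corr_threshold) for fold in folds
    ]
    return compute_metrics(results), results, matrix


def detect_outlier_trials(dataset: Dataset, level: float = 0.95) -> list[str]:
    """Flag trials whose tracks sit outside the joint duration/displacement
    confidence ellipse.

    A 2D normal is fitted to (duration, displacement) over all tracks of
    all trials; a trial is flagged when its centroid's squared Mahalanobis
    distance exceeds the chi-square quantile at `level`.  Catches e.g. a
    high-wind session in which the whole swarm rolls downwind at unusually
    high speed.  Advisory only — exclusion is the caller's decision.
    """
    if len(dataset.trials) < 3:
        logger.info("fewer than 3 trials: outlier QC skipped")
        return []
    points = np.array([(tr.duration, tr.displacement()) for tr in dataset])
    mu = points.mean(axis=0)
    cov = np.cov(points, rowvar=False)
    try:
        prec = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        prec = np.linalg.pinv(cov)
    cutoff = chi2.ppf(level, df=2)
    flagged = []
    for trial in dataset.trials:
        pts = np.array([(tr.duration, tr.displacement()) for tr in trial.tracks])
        centroid = pts.mean(axis=0) - mu
        d2 = float(centroid @ prec @ centroid)
        if d2 > cutoff:
            flagged.append(trial.trial_id)
    return flagged
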