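"""Cross-validated grid search over nu, kernel, window size and overlap.

Every feasible grid point is evaluated end to end — changing the window or
overlap changes the segments, so re-segmentation and re-extraction are part
of the evaluated pipeline (extraction is cached per (window, overlap) since
nu/kernel changes reuse the same features).  Configurations are scored by
track-level balanced accuracy on a held-out validation set of trials, kept
disjoint from the trials used for training and testing, and ranked best
first (ties: smaller nu, then smaller window, then kernel order).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import balanced_accuracy_score

from . import features as feat_mod
from .detector import KERNELS, DetectorConfig
from .evaluation import EXPECTED_MAP, train_and_predict
from .segmentation import window_dataset
from .selection import DEFAULT_ALPHA, DEFAULT_CORR_THRESHOLD
from .tracks import NON_MALE, Dataset, filter_short_tracks

logger = logging.getLogger(__name__)


def _frange(start: float, stop: float, step: float) -> list[float]:
    n = int(round((stop - start) / step))
    return [round(start + k * step, 10) for k in range(n + 1)]


@dataclass
class GridSpec:
    """Hyperparameter ranges.

    Defaults are the published search ranges: nu from 0 to 1 in steps of
    0.01 (nu must exceed 0, so the feasible values start at 0.01), the four
    kernels, windows from 1 to 10 s in 0.2 s steps, overlaps from 0.2 to
    5 s in 0.2 s steps.  Points with overlap >= window are infeasible and
    skipped (with a logged count).
    """

    nus: list[float] = field(default_factory=lambda: _frange(0.01, 1.0, 0.01))
    kernels: list[str] = field(default_factory=lambda: list(KERNELS))
    windows_s: list[float] = field(default_factory=lambda: _frange(1.0, 10.0, 0.2))
    overlaps_s: list[float] = field(default_factory=lambda: _frange(0.2, 5.0, 0.2))

    def points(self) -> list[tuple[float, str, float, float]]:
        """Feasible (nu, kernel, window, overlap) combinations."""
        feasible, skipped = [], 0
        for window, overlap in itertools.product(self.windows_s, self.overlaps_s):
            if overlap >= window:
                skipped += len(self.nus) * len(self.kernels)
                continue
            for nu, kernel in itertools.product(self.nus, self.kernels):
                feasible.append((nu, kernel, window, overlap))
        if skipped:
            logger.info("grid: skipped %d infeasible combinations", skipped)
        if not feasible:
            raise ValueError("empty feasible grid")
        return feasible


def grid_search(
    dataset: Dataset,
    validation_trials: list[str],
    grid: GridSpec | None = None,
    alpha: float = DEFAULT_ALPHA,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
    n_screen_trials: int = 2,
) -> pd.DataFrame:
    """Exhaustive, deterministic search over the feasible grid.

    The detector trains on male trials outside `validation_trials`; the
    feature screen uses non-male trials outside `validation_trials`; scoring
    uses the validation trials' tracks only.  Returns one row per evaluated
    configuration, ranked by validation balanced accuracy (best first).
    """
    grid = grid or GridSpec()
    validation = set(validation_trials)
    if not validation:
        raise ValueError("validation_trials must be non-empty")
    male_train = [
        t for t in dataset.trials_with_label("male") if t not in validation
    ]
    screen_all = sorted(
        {
            trial.trial_id
            for trial in dataset.trials
            if any(lbl in NON_MALE for lbl in trial.labels())
        }
        - set(male_train)
        - validation
    )
    screen = screen_all[:n_screen_trials]

    kernel_order = {k: i for i, k in enumerate(KERNELS)}
    cache: dict[tuple[float, float], pd.DataFrame] = {}
    rows = []
    for nu, kernel, window, overlap in grid.points():
        key = (window, overlap)
        if key not in cache:
            filtered = filter_short_tracks(dataset, window)
            segments = window_dataset(filtered, window, overlap)
            cache[key] = feat_mod.build_feature_matrix(segments)
        matrix = cache[key]
        test_mask = matrix["trial_id"].isin(validation) & matrix["label"].isin(
            set(EXPECTED_MAP)
        )
        try:
            _, _, _, track_frame = train_and_predict(
                matrix,
                male_train,
                screen,
                test_mask,
                DetectorConfig(nu=nu, kernel=kernel),
                alpha,
                corr_threshold,
                tag=f"nu={nu},kernel={kernel},w={window},o={overlap}",
            )
            score = float(
                balanced_accuracy_score(
                    track_frame["expected_male"], track_frame["is_male"]
                )
            )
        except ValueError as exc:
            logger.warning("grid point failed (%s); scored 0: %s", kernel, exc)
            score = float("nan")
        rows.append(
            {
                "nu": nu,
                "kernel": kernel,
                "window_s": window,
                "overlap_s": overlap,
                "balanced_accuracy": score,
            }
        )
    table = pd.DataFrame(rows)
    table["_kernel_order"] = table["kernel"].map(kernel_order)
    table = table.sort_values(
        ["balanced_accuracy", "nu", "window_s", "_kernel_order"],
        ascending=[False, True, True, True],
        kind="stable",
        na_position="last",
    ).drop(columns="_kernel_order")
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table.reset_index(drop=True)
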