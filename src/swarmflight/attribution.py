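"""Shapley-value attribution of detector decisions to features.

Explains the *signed decision value* (distance to the one-class boundary,
positive = male-like) as a sum of per-feature contributions.  The estimator
is the classic permutation-sampling Monte Carlo scheme: for each explained
row, random feature orderings are walked from a random background row to the
explained row, and the marginal change in the decision value when a feature
is switched in is credited to that feature.  Each sampled permutation
telescopes exactly, so local accuracy

    baseline + sum_j attribution_j == decision(row)

holds to floating-point precision for any number of samples, while the
attributions themselves converge to the Shapley values (efficiency,
symmetry and dummy axioms) as the sample count grows.  Fixed seed implies
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd


@dataclass
class AttributionMatrix:
    values: np.ndarray  # (n_rows, n_features)
    baseline: float  # expected decision value over the background
    decisions: np.ndarray  # (n_rows,) decision value of each explained row
    feature_names: list[str]
    n_samples: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def attribute(
    predict: Callable[[np.ndarray], np.ndarray],
    X: np.ndarray,
    background: np.ndarray,
    n_samples: int = 128,
    seed: int = 0,
    feature_names: Sequence[str] | None = None,
) -> AttributionMatrix:
    """Sampling Shapley attributions of `predict` for the rows of `X`.

    `predict` maps an (m, n_features) array to m scalar outputs (for a
    trained detector: the signed decision values on standardised inputs).
    `background` supplies the reference distribution (training rows).
    `n_samples` is the number of sampled permutations per row; the spread of
    the estimate shrinks as 1/sqrt(n_samples).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.size == 0:
        raise ValueError("background must be non-empty")
    n_rows, n_feat = X.shape
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if feature_names is None:
        feature_names = [f"f{j}" for j in range(n_feat)]
    rng = np.random.default_rng(seed)

    phi = np.zeros((n_rows, n_feat))
    baseline_acc = 0.0
    for s in range(n_samples):
        order = rng.permutation(n_feat)
        # one background row shared by all explained rows per draw, so the
        # scalar baseline reconstructs every row's decision value exactly
        b_idx = int(rng.integers(0, len(background)))
        b = np.tile(background[b_idx], (n_rows, 1))
        # walk from background to x along `order`, keeping every waypoint
        states = np.empty((n_feat + 1, n_rows, n_feat))
        states[0] = b
        current = b.copy()
        for k, j in enumerate(order):
            current[:, j] = X[:, j]
            states[k + 1] = current
        outputs = np.asarray(
            predict(states.reshape(-1, n_feat)), dtype=float
        ).reshape(n_feat + 1, n_rows)
        deltas = np.diff(outputs, axis=0)  # (n_feat, n_rows)
        phi[:, order] += deltas.T
        baseline_acc += outputs[0].mean() if n_rows else 0.0
    phi /= n_samples
    baseline = baseline_acc / n_samples
    decisions = np.asarray(predict(X), dtype=float)
    return AttributionMatrix(
        values=phi,
        baseline=float(baseline),
        decisions=decisions,
        feature_names=list(feature_names),
        n_samples=n_samples,
        seed=seed,
    )


def attribute_detector(
    det,
    matrix: pd.DataFrame,
    background: pd.DataFrame,
    n_samples: int = 128,
    seed: int = 0,
) -> AttributionMatrix:
    """Attribute a TrainedDetector's decision values on feature-matrix rows.

    `background` should be drawn from the training rows; standardisation
    (with the detector's training-fitted scaler and imputation) is applied
    inside, so attributions are expressed per original feature.
    """
    Xs = det.standardise(matrix)
    Bs = det.standardise(background)
    return attribute(
        det.model.decision_function,
        Xs,
        Bs,
        n_samples=n_samples,
        seed=seed,
        feature_names=det.feature_names,
    )


def summarise_attributions(attr: AttributionMatrix) -> pd.DataFrame:
    """Rank features by mean absolute attribution (ties: stable by name)."""
    if attr.values.size == 0:
        raise ValueError("empty attribution matrix")
    mean_abs = np.mean(np.abs(attr.values), axis=0)
    table = pd.DataFrame(
        {"feature": attr.feature_names, "mean_abs_attribution": mean_abs}
    )
    table = table.sort_values(
        ["mean_abs_attribution", "feature"],
        ascending=[False, True],
        kind="stable",
    ).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def scatter_table(
    attr: AttributionMatrix, matrix: pd.DataFrame, feature: str
) -> pd.DataFrame:
    """(feature value, attribution) pairs for dependence scatter plots."""
    j = attr.feature_names.index(feature)
    return pd.DataFrame(
        {
            "value": matrix[feature].to_numpy(dtype=float),
            "attribution": attr.values[:, j],
        }
    )
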