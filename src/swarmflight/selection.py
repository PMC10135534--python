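"""Statistical feature selection on the training split.

Two stages:

1. **Mann-Whitney screen** — a two-sided rank-sum test per feature comparing
   the reference (male) segments against the anomalous (non-male) segments,
   Bonferroni-corrected at family-wise error rate alpha = 0.01: a feature is
   kept iff p < alpha / n_features.  The test is non-parametric, matching the
   heavy-tailed distributions of kinematic features.
2. **Correlation pruning** — among the significant features, groups are
   formed by the transitive closure of |Pearson r| >= 0.85 and a single
   representative is retained per group (smallest screening p-value, ties
   broken by schema order).

Both stages see training rows only; test trials never reach this module.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.01
DEFAULT_CORR_THRESHOLD = 0.85


@dataclass
class SelectionResult:
    """Outcome of the screen + prune pipeline."""

    features: list[str]
    u_statistics: dict[str, float]
    p_values: dict[str, float]
    alpha: float
    bonferroni_threshold: float
    significant: list[str] = field(default_factory=list)
    correlation_groups: list[list[str]] = field(default_factory=list)
    selected: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "alpha": self.alpha,
                    "bonferroni_threshold": self.bonferroni_threshold,
                    "u_statistics": self.u_statistics,
                    "p_values": self.p_values,
                    "significant": self.significant,
                    "correlation_groups": self.correlation_groups,
                    "selected": self.selected,
                },
                indent=2,
            )
        )


def mann_whitney_screen(
    reference: pd.DataFrame,
    anomalous: pd.DataFrame,
    feature_names: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
) -> SelectionResult:
    """Bonferroni-corrected Mann-Whitney U screen.

    `reference` and `anomalous` hold feature columns for the two classes
    (male vs non-male segment values).  Uses the normal approximation with
    tie correction — segment counts run into the thousands.  A feature
    constant in both classes yields p = 1 and is never selected.
    """
    if feature_names is None:
        feature_names = list(reference.columns)
    if reference.empty or anomalous.empty:
        raise ValueError("both classes must be non-empty")
    n = len(feature_names)
    threshold = alpha / n
    u_stats: dict[str, float] = {}
    p_values: dict[str, float] = {}
    significant: list[str] = []
    for name in feature_names:
        a = reference[name].to_numpy(dtype=float)
        b = anomalous[name].to_numpy(dtype=float)
        a = a[np.isfinite(a)]
        b = b[np.isfinite(b)]
        if len(a) == 0 or len(b) == 0 or (np.ptp(a) == 0 and np.ptp(b) == 0 and a[0] == b[0]):
            u_stats[name] = float("nan")
            p_values[name] = 1.0
            continue
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        u_stats[name] = float(res.statistic)
        p_values[name] = float(res.pvalue)
        if p_values[name] < threshold:
            significant.append(name)
    return SelectionResult(
        features=list(feature_names),
        u_statistics=u_stats,
        p_values=p_values,
        alpha=alpha,
        bonferroni_threshold=threshold,
        significant=significant,
        selected=list(significant),
    )


def _connected_components(names: list[str], adjacency: np.ndarray) -> list[list[str]]:
    """Transitive closure of the |r| >= threshold relation (union-find)."""
    parent = list(range(len(names)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if adjacency[i, j]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    groups: dict[int, list[str]] = {}
    for i, name in enumerate(names):
        groups.setdefault(find(i), []).append(name)
    return list(groups.values())


def correlation_prune(
    matrix: pd.DataFrame,
    result: SelectionResult,
    threshold: float = DEFAULT_CORR_THRESHOLD,
) -> SelectionResult:
    """Keep one representative per group of highly correlated features.

    Groups are connected components under |Pearson r| >= `threshold`
    computed on the training rows in `matrix`; the representative is the
    group member with the smallest screening p-value (ties: schema order).
    """
    selected = [f for f in result.features if f in set(result.significant)]
    if not selected:
        result.correlation_groups = []
        result.selected = []
        return result
    values = matrix[selected].to_numpy(dtype=float)
    # constant columns produce NaN correlations; treat as uncorrelated
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(values, rowvar=False)
    corr = np.atleast_2d(np.nan_to_num(corr, nan=0.0))
    adjacency = np.abs(corr) >= threshold
    groups = _connected_components(selected, adjacency)
    order = {name: i for i, name in enumerate(result.features)}
    final = []
    for group in groups:
        best = min(group, key=lambda f: (result.p_values[f], order[f]))
        final.append(best)
    final.sort(key=lambda f: order[f])
    result.correlation_groups = [sorted(g, key=lambda f: order[f]) for g in groups]
    result.selected = final
    return result


def select_features(
    reference: pd.DataFrame,
    anomalous: pd.DataFrame,
    feature_names: list[str] | None = None,
    alpha: float = DEFAULT_ALPHA,
    corr_threshold: float = DEFAULT_CORR_THRESHOLD,
) -> SelectionResult:
    """Screen then prune; correlations are computed on the pooled training
    rows of both classes."""
    result = mann_whitney_screen(reference, anomalous, feature_names, alpha)
    pooled = pd.concat([reference, anomalous], ignore_index=True)
    return correlation_prune(pooled, result, corr_threshold)
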