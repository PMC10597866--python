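"""Wrapper feature selection by EFMO over a combined accuracy/Fisher cost.

The quality of a binary feature mask FS is

    cost(FS) = α · accuracy(FS) + β · Σ_{j selected} F(j) / Σ_k F(k)

with α = 0.65, β = 0.35 (α + β = 1).  accuracy(FS) is the stratified
cross-validated accuracy of an inner RBF-SVM restricted to the selected
features, and F(j) is the per-feature Fisher score — between-class squared
deviation of class means over summed within-class sample variances.  Larger
accuracy and larger selected-score share are both better, so the optimizer
*maximizes* the cost (equivalently minimizes its negative).

EFMO searches continuous vectors in [0, 1]^Nb thresholded at 0.5 into
masks; an empty candidate mask is repaired by activating the top-Fisher
feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import efmo


@dataclass
class SelectionConfig:
    alpha: float = 0.65
    beta: float = 0.35
    cv_folds: int = 5
    #: inner classifier used by the accuracy term during selection
    inner_c: float = 1.0
    inner_gamma: str | float = "scale"
    n_fish: int = 30
    max_iter: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0 or abs(self.alpha + self.beta - 1) > 1e-9:
            raise ValueError("need alpha, beta >= 0 with alpha + beta = 1")


def fisher_score(values: np.ndarray, labels: np.ndarray) -> float:
    """Binary-class Fisher score of one feature.

    ((x̄+ − x̄)² + (x̄− − x̄)²) / (s²+ + s²−) with unbiased within-class
    sample variances.  A zero denominator with separated means yields +inf
    (the feature trivially separates); 0/0 yields 0.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("fisher_score expects exactly two classes")
    grand = values.mean()
    between = 0.0
    within = 0.0
    for c in classes:
        v = values[labels == c]
        if len(v) < 2:
            raise ValueError("need >= 2 samples per class")
        between += (v.mean() - grand) ** 2
        within += v.var(ddof=1)
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return float(between / within)


def fisher_score_multiclass(values: np.ndarray, labels: np.ndarray) -> float:
    """Multiclass generalization: Σ_c (x̄_c − x̄)² / Σ_c s²_c / n_c-normalized."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    grand = values.mean()
    between = 0.0
    within = 0.0
    for c in np.unique(labels):
        v = values[labels == c]
        between += (v.mean() - grand) ** 2
        within += v.var(ddof=1) if len(v) > 1 else 0.0
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return float(between / within)


def fisher_scores(table: pd.DataFrame) -> np.ndarray:
    """Fisher score of every feature column (all but 'label')."""
    y = table["label"].to_numpy()
    feats = table.drop(columns="label")
    return np.array([fisher_score(feats[c].to_numpy(), y) for c in feats.columns])


def _inner_classifier(config: SelectionConfig):
    return make_pipeline(StandardScaler(),
                         SVC(C=config.inner_c, gamma=config.inner_gamma))


def mask_accuracy(table: pd.DataFrame, mask: np.ndarray,
                  config: SelectionConfig | None = None) -> float:
    """Stratified cross-validated accuracy using only the masked features."""
    config = config or SelectionConfig()
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty feature mask")
    y = table["label"].to_numpy()
    X = table.drop(columns="label").to_numpy()[:, mask]
    cv = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                         random_state=config.seed)
    scores = cross_val_score(_inner_classifier(config), X, y, cv=cv)
    return float(scores.mean())


def _score_ratio(scores: np.ndarray, mask: np.ndarray) -> float:
    """Selected-sum over total-sum of Fisher scores; infinite scores are
    capped at 10× the largest finite score so the ratio stays defined."""
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    cap = 10.0 * finite.max() if finite.size and finite.max() > 0 else 1.0
    capped = np.where(np.isfinite(scores), scores, cap)
    total = capped.sum()
    if total == 0:
        return 0.0
    return float(capped[np.asarray(mask, dtype=bool)].sum() / total)


def selection_cost(table: pd.DataFrame, mask: np.ndarray,
                   config: SelectionConfig | None = None,
                   scores: np.ndarray | None = None) -> float:
    """α·accuracy + β·(Fisher-score share of the selected features)."""
    config = config or SelectionConfig()
    if scores is None:
        scores = fisher_scores(table)
    acc = mask_accuracy(table, mask, config)
    return config.alpha * acc + config.beta * _score_ratio(scores, mask)


@dataclass
class SelectionResult:
    mask: np.ndarray
    cost: float
    feature_names: list[str]

    @property
    def selected_names(self) -> list[str]:
        return [n for n, m in zip(self.feature_names, self.mask) if m]

    def to_json(self) -> str:
        import json

        return json.dumps({"mask": self.mask.astype(int).tolist(),
                           "cost": self.cost,
                           "features": self.feature_names,
                           "selected": self.selected_names})


def _repair(mask: np.ndarray, scores: np.ndarray) -> np.ndarray:
    if mask.any():
        return mask
    fixed = mask.copy()
    capped = np.where(np.isfinite(scores), scores, np.inf)
    fixed[int(np.argmax(capped))] = True
    return fixed


def select_features(table: pd.DataFrame,
                    config: SelectionConfig | None = None) -> SelectionResult:
    """EFMO search over feature masks maximizing the selection cost.

    Deterministic given ``config.seed``; cost evaluations are memoized per
    mask since many continuous candidates threshold to the same mask.
    """
    config = config or SelectionConfig()
    y = table["label"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate single-class table")
    names = [c for c in table.columns if c != "label"]
    nb = len(names)
    if nb < 2:
        raise ValueError("need at least two features")
    scores = fisher_scores(table)
    cache: dict[tuple, float] = {}

    def cost_of(mask: np.ndarray) -> float:
        key = tuple(mask.tolist())
        if key not in cache:
            cache[key] = selection_cost(table, mask, config, scores)
        return cache[key]

    def objective(x: np.ndarray) -> float:
        mask = _repair(x >= 0.5, scores)
        return -cost_of(mask)

    space = efmo.SearchSpace(np.zeros(nb), np.ones(nb), objective)
    result = efmo.optimize(space, n_fish=config.n_fish, max_iter=config.max_iter,
                           seed=config.seed)
    best_mask = _repair(result.best_position >= 0.5, scores)
    return SelectionResult(best_mask, cost_of(best_mask), names)


def exhaustive_best_mask(table: pd.DataFrame,
                         config: SelectionConfig | None = None) -> SelectionResult:
    """Enumerate all nonempty masks (small Nb only) — the selection oracle."""
    config = config or SelectionConfig()
    names = [c for c in table.columns if c != "label"]
    nb = len(names)
    if nb > 16:
        raise ValueError("exhaustive enumeration limited to 16 features")
    scores = fisher_scores(table)
    best_mask, best_cost = None, -np.inf
    for bits in range(1, 2**nb):
        mask = np.array([(bits >> j) & 1 for j in range(nb)], dtype=bool)
        c = selection_cost(table, mask, config, scores)
        if c > best_cost:
            best_mask, best_cost = mask, c
    return SelectionResult(best_mask, best_cost, names)
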