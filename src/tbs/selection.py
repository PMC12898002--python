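"""Three-stage per-pair feature selection and rank aggregation.

Stage 1 scores each feature's univariate discrimination for the binary class
pair as |AUC - 0.5| from the rank-sum statistic and keeps the top block.
Stage 2 ranks the survivors by mean absolute Shapley attribution under a
bagged-tree ensemble.  Stage 3 recursively eliminates the lowest-attribution
fraction per iteration until the target subset size (35 by default) remains.
All stages must run strictly inside the training fold.

Rank aggregation follows the minimum-rank tie convention, and the overall
rank is the arithmetic mean of the correlation-based and SHAP-based ranks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from ._treeshap import ensemble_shap_values

__all__ = [
    "BaggedPairClassifier",
    "SelectionTrace",
    "univariate_filter",
    "shap_rank",
    "rfe_select",
    "aggregate_ranks",
    "three_stage_select",
    "rank_min",
]


class BaggedPairClassifier:
    """Bootstrap-aggregated decision trees for one 1-vs-1 severity contrast.

    Each of ``n_bags`` unlimited-depth CART trees is fit on a bootstrap
    resample of the training subjects; the ensemble score is the mean
    predicted probability of the positive (second) class.  Deterministic
    given ``seed``.
    """

    def __init__(self, n_bags: int = 100, seed: int = 0):
        self.n_bags = n_bags
        self.seed = seed
        self.trees_: list[DecisionTreeClassifier] = []
        self.classes_: np.ndarray | None = None
        self.feature_names_: list[str] | None = None

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size != 2:
            raise ValueError("need exactly two classes")
        rng = np.random.default_rng(self.seed)
        n = X.shape[0]
        self.trees_ = []
        for b in range(self.n_bags):
            idx = rng.integers(0, n, size=n)
            while np.unique(y[idx]).size < 2:  # keep both classes in the bag
                idx = rng.integers(0, n, size=n)
            tree = DecisionTreeClassifier(random_state=int(rng.integers(2 ** 31)))
            tree.fit(X[idx], (y[idx] == self.classes_[1]).astype(int))
            self.trees_.append(tree)
        return self

    def decision_scores(self, X) -> np.ndarray:
        """Mean predicted positive-class probability across bags."""
        X = np.asarray(X, dtype=float)
        probs = np.zeros(X.shape[0])
        for tree in self.trees_:
            p = tree.predict_proba(X)
            probs += p[:, 1] if p.shape[1] == 2 else p[:, 0] * float(tree.classes_[0])
        return probs / len(self.trees_)


def rankdata_auc(x: np.ndarray, y01: np.ndarray) -> float:
    """Mann-Whitney AUC of feature values for binary labels (ties -> 0.5)."""
    from scipy.stats import rankdata
    r = rankdata(x)
    n1 = int(y01.sum())
    n0 = y01.size - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required")
    return float((r[y01 == 1].sum() - n1 * (n1 + 1) / 2) / (n0 * n1))


def univariate_filter(table: pd.DataFrame, labels, keep: int = 200,
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Keep the ``keep`` features with largest |AUC - 0.5|; ties break by
    feature-name lexical order.  Returns (filtered table, scores)."""
    if keep < 1:
        raise ValueError("keep must be >= 1")
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("binary labels required")
    y01 = (y == classes[1]).astype(int)
    scores = {}
    for name in table.columns:
        scores[name] = abs(rankdata_auc(table[name].to_numpy(dtype=float), y01) - 0.5)
    s = pd.Series(scores)
    order = sorted(s.index, key=lambda n: (-s[n], n))
    kept = order[:min(keep, len(order))]
    if keep > len(order):
        import warnings
        warnings.warn("keep exceeds feature count; retaining all features")
    return table[kept], s


def shap_rank(model: BaggedPairClassifier, table: pd.DataFrame,
              ) -> tuple[pd.Series, np.ndarray, float]:
    """Mean |Shapley attribution| per feature over the table's subjects.

    Returns (mean-abs series indexed like the table's columns, the per-subject
    attribution matrix, and the ensemble base value).  Attribution additivity
    (sum + base == ensemble score) holds to float precision.
    """
    if model.feature_names_ is not None and \
            list(table.columns) != model.feature_names_:
        raise ValueError("model was trained on a different feature set")
    X = table.to_numpy(dtype=float)
    phi, base = ensemble_shap_values(model.trees_, X)
    mean_abs = pd.Series(np.mean(np.abs(phi), axis=0), index=table.columns)
    return mean_abs, phi, base


@dataclass
class SelectionTrace:
    """Bookkeeping of the recursive elimination: features dropped per step."""

    steps: list[list[str]] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)


def rfe_select(table: pd.DataFrame, labels, target_n: int = 35,
               step: float = 0.1, seed: int = 0, n_bags: int = 100,
               ) -> tuple[pd.DataFrame, SelectionTrace]:
    """Recursive feature elimination with mean-|SHAP| importance.

    Per iteration a fresh bagged ensemble is trained on the surviving
    features and the lowest-importance ``step`` fraction (at least one
    feature) is dropped, stopping at exactly ``target_n`` features.
    """
    if target_n > table.shape[1]:
        raise ValueError("target_n exceeds current feature count")
    y = np.asarray(labels)
    current = table
    trace = SelectionTrace()
    it = 0
    while current.shape[1] > target_n:
        model = BaggedPairClassifier(n_bags=n_bags, seed=seed + it).fit(
            current.to_numpy(dtype=float), y)
        model.feature_names_ = list(current.columns)
        importance, _, _ = shap_rank(model, current)
        n_drop = max(1, int(np.floor(step * current.shape[1])))
        n_drop = min(n_drop, current.shape[1] - target_n)
        # drop lowest importance; ties resolved lexically for determinism
        order = sorted(importance.index, key=lambda n: (importance[n], n))
        dropped = order[:n_drop]
        trace.steps.append(list(dropped))
        current = current.drop(columns=dropped)
        it += 1
    trace.kept = list(current.columns)
    return current, trace


def aggregate_ranks(corr_rank: float, shap_rank_: float) -> float:
    """Overall rank = arithmetic mean of correlation- and SHAP-based ranks."""
    if corr_rank < 1 or shap_rank_ < 1:
        raise ValueError("ranks must be >= 1")
    return (corr_rank + shap_rank_) / 2.0


def rank_min(values: pd.Series, ascending: bool = False) -> pd.Series:
    """Rank with ties sharing the minimum rank (competition ranking)."""
    return values.rank(method="min", ascending=ascending)


def three_stage_select(table: pd.DataFrame, labels, keep: int = 200,
                       target_n: int = 35, step: float = 0.1, seed: int = 0,
                       n_bags: int = 100) -> tuple[pd.DataFrame, dict]:
    """Univariate filter -> SHAP ranking -> RFE, returning the final table
    and a manifest recording what survived each stage."""
    y = np.asarray(labels)
    filtered, uni_scores = univariate_filter(table, y, keep=keep)
    model = BaggedPairClassifier(n_bags=n_bags, seed=seed).fit(
        filtered.to_numpy(dtype=float), y)
    model.feature_names_ = list(filtered.columns)
    importance, _, _ = shap_rank(model, filtered)
    target = min(target_n, filtered.shape[1])
    final, trace = rfe_select(filtered, y, target_n=target, step=step,
                              seed=seed, n_bags=n_bags)
    manifest = {
        "stage1_kept": list(filtered.columns),
        "stage1_scores": uni_scores.to_dict(),
        "stage2_importance": importance.to_dict(),
        "stage3_trace": trace.steps,
        "final": list(final.columns),
    }
    return final, manifest
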