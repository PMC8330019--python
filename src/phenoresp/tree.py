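"""From-scratch CART classifier with Gini impurity and feature importance.

The tree maps baseline phenotype features (demographics, labs, comorbidity
flags, sensitization, genotypes, baseline lung function and FENO,
medication-use indicators) onto the four response-cluster labels, exactly
as a descriptive discriminant analysis: it is fitted on the full cohort
with no held-out split, and its normalized Gini importance ranks the
baseline features that best separate the clusters.

Splits are binary on numeric thresholds (midpoints of sorted distinct
values); categorical features are one-hot expanded for splitting and their
indicator importances re-aggregated onto the parent feature.  A node stops
splitting when its Gini impurity is already below ``impurity_stop``
(default 0.2, a node-purity reading of the study's "Gini < 0.2"), at
``max_depth``, below the sample minima, or when no admissible split
decreases impurity.  Missing values are imputed by per-feature median
(continuous) or mode (categorical), with companion ``*_imputed`` indicator
columns.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeParams",
    "TreeNode",
    "gini_impurity",
    "best_split",
    "fit_cart",
    "feature_importance",
    "prepare_features",
    "tree_to_json",
    "tree_to_dot",
    "predict",
    "confusion_matrix",
]


@dataclass(frozen=True)
class TreeParams:
    """CART growth controls."""

    impurity_stop: float = 0.2
    max_depth: int = 6
    min_samples_split: int = 10
    min_samples_leaf: int = 5
    #: shuffle feature evaluation order (tie-break experiment only)
    shuffle_features: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.impurity_stop < 1:
            raise ValueError("impurity_stop must lie in [0, 1)")
        if min(self.max_depth, self.min_samples_split, self.min_samples_leaf) < 1:
            raise ValueError("depth and sample bounds must be positive")


@dataclass
class TreeNode:
    node_id: int
    class_counts: np.ndarray
    impurity: float
    depth: int
    feature: Optional[str] = None
    threshold: Optional[float] = None
    left: Optional["TreeNode"] = None
    right: Optional["TreeNode"] = None
    #: (n_node / n_total) * local impurity decrease, for importances
    weighted_decrease: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.class_counts))

    @property
    def n(self) -> int:
        return int(self.class_counts.sum())


def gini_impurity(class_counts) -> float:
    """Gini impurity 1 - sum(p_i^2) of a count vector."""
    counts = np.asarray(class_counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("class counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("class counts are all zero")
    p = counts / total
    return float(1.0 - (p ** 2).sum())


def best_split(column: np.ndarray, labels: np.ndarray, params: TreeParams,
               n_classes: Optional[int] = None
               ) -> Optional[tuple[float, float]]:
    """Best binary threshold for one numeric column.

    Candidates are midpoints of consecutive sorted distinct values; the
    winner maximizes the decrease from parent impurity to the size-weighted
    child impurity, subject to ``min_samples_leaf``.  Equal decreases keep
    the smaller threshold.  Returns ``(threshold, decrease)`` or ``None``
    for constant columns / no improving admissible split.
    """
    column = np.asarray(column, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n = len(column)
    k = n_classes or labels.max() + 1
    order = np.argsort(column, kind="stable")
    xs, ys = column[order], labels[order]
    distinct = np.nonzero(np.diff(xs) > 0)[0]  # split after position i
    if distinct.size == 0:
        return None
    parent = gini_impurity(np.bincount(ys, minlength=k))
    left_counts = np.zeros(k)
    best = None
    prev = 0
    for pos in distinct:
        left_counts += np.bincount(ys[prev: pos + 1], minlength=k)
        prev = pos + 1
        n_left = pos + 1
        n_right = n - n_left
        if n_left < params.min_samples_leaf or n_right < params.min_samples_leaf:
            continue
        total_counts = np.bincount(ys, minlength=k)
        right_counts = total_counts - left_counts
        decrease = parent - (n_left / n) * gini_impurity(left_counts) \
            - (n_right / n) * gini_impurity(right_counts)
        threshold = (xs[pos] + xs[pos + 1]) / 2.0
        if best is None or decrease > best[1] + 1e-12:
            best = (threshold, decrease)
    if best is None or best[1] <= 1e-12:
        return None
    return best


def _grow(X: np.ndarray, y: np.ndarray, feature_names: Sequence[str],
          params: TreeParams, n_total: int, n_classes: int, depth: int,
          counter: list, feature_order: Sequence[int]) -> TreeNode:
    counts = np.bincount(y, minlength=n_classes).astype(float)
    node = TreeNode(node_id=counter[0], class_counts=counts,
                    impurity=gini_impurity(counts), depth=depth)
    counter[0] += 1
    n = len(y)
    if (node.impurity < params.impurity_stop or depth >= params.max_depth
            or n < params.min_samples_split):
        return node
    chosen = None  # (decrease, order_rank, threshold, feature_idx)
    for rank, j in enumerate(feature_order):
        result = best_split(X[:, j], y, params, n_classes)
        if result is None:
            continue
        threshold, decrease = result
        if chosen is None or decrease > chosen[0] + 1e-12:
            chosen = (decrease, rank, threshold, j)
    if chosen is None:
        return node
    decrease, _, threshold, j = chosen
    mask = X[:, j] <= threshold
    node.feature = feature_names[j]
    node.threshold = float(threshold)
    node.weighted_decrease = (n / n_total) * decrease
    node.left = _grow(X[mask], y[mask], feature_names, params, n_total,
                      n_classes, depth + 1, counter, feature_order)
    node.right = _grow(X[~mask], y[~mask], feature_names, params, n_total,
                       n_classes, depth + 1, counter, feature_order)
    return node


def fit_cart(features: pd.DataFrame, labels: Sequence[int],
             params: TreeParams = TreeParams()) -> TreeNode:
    """Grow a CART on numeric features against integer class labels.

    ``features`` must already be numeric (see ``prepare_features`` for
    one-hot expansion and imputation); labels are 1-based cluster ids.
    The fit is descriptive — the full data, no held-out split.
    """
    X = features.to_numpy(dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(y) != len(X):
        raise ValueError("label / feature row mismatch")
    if np.isnan(X).any():
        raise ValueError("features contain missing values; impute first")
    classes = np.unique(y)
    y0 = np.searchsorted(classes, y)
    order = np.arange(X.shape[1])
    if params.shuffle_features:
        np.random.default_rng(params.seed).shuffle(order)
    root = _grow(X, y0, list(features.columns), params, len(y),
                 len(classes), 0, [0], order)
    root.classes_ = classes  # type: ignore[attr-defined]
    return root


def _iter_nodes(node: TreeNode):
    yield node
    if not node.is_leaf:
        yield from _iter_nodes(node.left)
        yield from _iter_nodes(node.right)


def feature_importance(root: TreeNode,
                       onehot_parent: Optional[dict] = None) -> pd.DataFrame:
    """Normalized Gini importance per feature, in percent, descending.

    Sums each feature's weighted impurity decreases over its split nodes
    and normalizes the total to 100 %.  One-hot indicator columns are
    aggregated back onto their parent categorical feature via
    ``onehot_parent`` (indicator name -> parent name).
    """
    onehot_parent = onehot_parent or {}
    raw: dict[str, float] = {}
    for node in _iter_nodes(root):
        if node.is_leaf:
            continue
        name = onehot_parent.get(node.feature, node.feature)
        raw[name] = raw.get(name, 0.0) + node.weighted_decrease
    total = sum(raw.values())
    if total <= 0:
        return pd.DataFrame(columns=["feature", "importance_pct"])
    rows = [{"feature": f, "importance_pct": 100.0 * v / total}
            for f, v in raw.items()]
    return (pd.DataFrame(rows)
            .sort_values("importance_pct", ascending=False, kind="stable")
            .reset_index(drop=True))


def prepare_features(baselines: pd.DataFrame,
                     exclude: Sequence[str] = ("patient_id",)
                     ) -> tuple[pd.DataFrame, dict]:
    """Numeric design matrix from a baseline table.

    Continuous columns: median-imputed with an ``*_imputed`` flag when any
    value is missing.  Object/categorical columns: mode-imputed then one-hot
    expanded.  Returns ``(matrix, onehot_parent)`` where the mapping sends
    indicator columns back to their source feature for importance reports.
    """
    df = baselines.drop(columns=[c for c in exclude if c in baselines.columns])
    out = {}
    onehot_parent: dict[str, str] = {}
    for col in df.columns:
        series = df[col]
        if series.dtype == object or isinstance(series.dtype, pd.CategoricalDtype):
            if series.isna().any():
                out[f"{col}_imputed"] = series.isna().astype(float)
                series = series.fillna(series.mode().iloc[0])
            for value in sorted(series.astype(str).unique()):
                name = f"{col}={value}"
                out[name] = (series.astype(str) == value).astype(float)
                onehot_parent[name] = col
        else:
            series = pd.to_numeric(series)
            if series.isna().any():
                out[f"{col}_imputed"] = series.isna().astype(float)
                series = series.fillna(series.median())
            out[col] = series.astype(float)
    return pd.DataFrame(out, index=baselines.index), onehot_parent


def predict(root: TreeNode, features: pd.DataFrame) -> np.ndarray:
    """Predicted class labels (original label values) for each row."""
    classes = getattr(root, "classes_", None)
    X = features.to_numpy(dtype=float)
    cols = {c: i for i, c in enumerate(features.columns)}
    out = np.empty(len(X), dtype=int)
    for i, row in enumerate(X):
        node = root
        while not node.is_leaf:
            node = node.left if row[cols[node.feature]] <= node.threshold else node.right
        pred = node.predicted_class
        out[i] = classes[pred] if classes is not None else pred
    return out


def confusion_matrix(labels: Sequence[int], predicted: Sequence[int]) -> pd.DataFrame:
    """Training confusion matrix (rows = true, columns = predicted)."""
    return pd.crosstab(pd.Series(labels, name="true"),
                       pd.Series(predicted, name="predicted"))


def tree_to_json(root: TreeNode) -> str:
    def encode(node: TreeNode) -> dict:
        payload = {
            "id": node.node_id,
            "counts": node.class_counts.astype(int).tolist(),
            "impurity": round(node.impurity, 6),
        }
        if node.is_leaf:
            payload["leaf_class"] = node.predicted_class
        else:
            payload.update({
                "feature": node.feature,
                "threshold": node.threshold,
                "decrease": round(node.weighted_decrease, 6),
                "left": encode(node.left),
                "right": encode(node.right),
            })
        return payload
    return json.dumps(encode(root), indent=1)


def tree_to_dot(root: TreeNode) -> str:
    lines = ["digraph cart {", "  node [shape=box];"]
    for node in _iter_nodes(root):
        if node.is_leaf:
            label = f"leaf class {node.predicted_class}\\nn={node.n} gini={node.impurity:.3f}"
        else:
            label = (f"{node.feature} <= {node.threshold:.4g}\\n"
                     f"n={node.n} gini={node.impurity:.3f}")
        lines.append(f'  n{node.node_id} [label="{label}"];')
        if not node.is_leaf:
            lines.append(f"  n{node.node_id} -> n{node.left.node_id};")
            lines.append(f"  n{node.node_id} -> n{node.right.node_id};")
    lines.append("}")
    return "\n".join(lines)
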