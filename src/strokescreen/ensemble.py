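"""Disagreement-set ensemble: threshold screening, meta-labels, CART arbiter.

The screening workflow labels an individual high-risk when predicted
9-year stroke risk exceeds a threshold (strictly greater than 10% by
default).  Where a Cox model and a gradient-boosted-tree model disagree
on that label, the model whose label matches the realized outcome
(stroke => high-risk is correct) is deterministically the "better"
model, and a CART decision tree is trained on the disagreement set to
predict which model to trust for a given individual.  The ensemble rule
keeps the Cox label wherever the two models agree and lets the tree
arbitrate otherwise.

The CART learner is implemented here rather than delegated to a library
backend: its node-level Gini bookkeeping, deterministic tie-breaking
(lowest feature index, then lowest threshold), and JSON-inspectable
structure are part of the method's contract.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ContractViolationError, FitError

#: Class labels of the arbiter, in tie-break order: the Cox model is the
#: workflow's default, so leaf-majority ties resolve to it.
MODEL_CLASSES = ("cox", "gbt")

DEFAULT_THRESHOLD = 0.10


def classify_high_risk(risks, tau: float = DEFAULT_THRESHOLD) -> np.ndarray:
    """High-risk label per individual: predicted risk strictly above tau."""
    risks = np.asarray(risks, dtype=float)
    if np.any((risks < 0) | (risks > 1)):
        raise ContractViolationError("risks must lie in [0, 1]")
    return risks > tau


def find_disagreements(cox_labels, gbt_labels) -> np.ndarray:
    """Indices where the two models' high-risk labels differ."""
    cox_labels = np.asarray(cox_labels, dtype=bool)
    gbt_labels = np.asarray(gbt_labels, dtype=bool)
    if cox_labels.shape != gbt_labels.shape:
        raise ContractViolationError("label vectors must have equal length")
    return np.flatnonzero(cox_labels != gbt_labels)


def make_meta_labels(cox_labels, gbt_labels, outcomes) -> np.ndarray:
    """Better-model label ("cox"/"gbt") per disagreement record.

    The correct high-risk label is the realized outcome (stroke within
    the horizon => high-risk); the better model is the one whose label
    matches it.  Every record must be a genuine disagreement, so exactly
    one model is better.
    """
    cox_labels = np.asarray(cox_labels, dtype=bool)
    gbt_labels = np.asarray(gbt_labels, dtype=bool)
    outcomes = np.asarray(outcomes, dtype=bool)
    if np.any(cox_labels == gbt_labels):
        raise ContractViolationError(
            "meta-labels are defined only on disagreement records"
        )
    return np.where(cox_labels == outcomes, "cox", "gbt")


@dataclass
class TreeNode:
    """One node of the CART arbiter (leaf iff ``feature`` is None)."""

    n: int
    counts: tuple[int, int]  # records per class, MODEL_CLASSES order
    impurity: float
    prediction: str
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def to_dict(self) -> dict:
        d = {
            "n": self.n,
            "counts": list(self.counts),
            "impurity": self.impurity,
            "prediction": self.prediction,
        }
        if not self.is_leaf:
            d.update(
                feature=self.feature,
                threshold=self.threshold,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TreeNode":
        node = cls(
            n=d["n"],
            counts=tuple(d["counts"]),
            impurity=d["impurity"],
            prediction=d["prediction"],
        )
        if "feature" in d:
            node.feature = d["feature"]
            node.threshold = d["threshold"]
            node.left = cls.from_dict(d["left"])
            node.right = cls.from_dict(d["right"])
        return node


def _gini(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    return float(1.0 - np.sum(p * p))


def _best_split(x: np.ndarray, y: np.ndarray, min_leaf: int):
    """Exhaustive axis-aligned split search minimizing weighted child Gini.

    Returns (feature_index, threshold, gain) or None.  Candidate
    thresholds are midpoints between consecutive distinct sorted values;
    ties in gain resolve to the lowest feature index, then the lowest
    threshold (strict improvement required to replace the incumbent).
    """
    n, p = x.shape
    total = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=float)
    parent_cost = n * _gini(total)
    best = None
    best_gain = 1e-12
    for j in range(p):
        order = np.argsort(x[:, j], kind="stable")
        xs = x[order, j]
        ys = y[order]
        left1 = np.cumsum(ys)  # class-1 count in left block after each row
        idx = np.arange(1, n)
        distinct = xs[1:] != xs[:-1]
        valid = distinct & (idx >= min_leaf) & (n - idx >= min_leaf)
        if not valid.any():
            continue
        for i in idx[valid]:
            l1 = left1[i - 1]
            left = np.array([i - l1, l1], dtype=float)
            right = total - left
            cost = i * _gini(left) + (n - i) * _gini(right)
            gain = (parent_cost - cost) / n
            if gain > best_gain:
                best_gain = gain
                best = (j, (xs[i - 1] + xs[i]) / 2.0, float(gain))
    return best


class MetaTree:
    """Greedy CART classifier predicting the better model per individual.

    Splits use Gini impurity G(p) = 1 - sum_c p_c^2 and stop at
    ``max_depth``, ``min_samples_leaf``, or zero impurity gain.  Leaf
    prediction is the majority class, ties resolving to "cox" (the
    workflow default).
    """

    def __init__(self, max_depth: int = 4, min_samples_leaf: int = 20):
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.root: TreeNode | None = None
        self.feature_names_: list[str] | None = None
        self.degenerate_single_class_: bool = False

    def fit(self, features: pd.DataFrame, labels) -> "MetaTree":
        labels = np.asarray(labels)
        if len(labels) == 0:
            raise FitError("meta-tree needs a nonempty disagreement set")
        if not set(np.unique(labels)) <= set(MODEL_CLASSES):
            raise ContractViolationError(f"labels must be in {MODEL_CLASSES}")
        y = np.searchsorted(np.array(MODEL_CLASSES), labels)  # cox=0, gbt=1
        self.feature_names_ = list(features.columns)
        x = features.to_numpy(dtype=float)
        self.degenerate_single_class_ = len(np.unique(y)) < 2
        self.root = self._grow(x, y, depth=0)
        return self

    def _grow(self, x: np.ndarray, y: np.ndarray, depth: int) -> TreeNode:
        counts = np.array([np.sum(y == 0), np.sum(y == 1)], dtype=int)
        node = TreeNode(
            n=len(y),
            counts=(int(counts[0]), int(counts[1])),
            impurity=_gini(counts.astype(float)),
            prediction=MODEL_CLASSES[int(np.argmax(counts))],  # tie -> cox
        )
        if depth >= self.max_depth or node.impurity == 0.0:
            return node
        split = _best_split(x, y, self.min_samples_leaf)
        if split is None:
            return node
        j, thr, _gain = split
        node.feature = self.feature_names_[j]
        node.threshold = thr
        mask = x[:, j] <= thr
        node.left = self._grow(x[mask], y[mask], depth + 1)
        node.right = self._grow(x[~mask], y[~mask], depth + 1)
        return node

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        """Better-model label ("cox"/"gbt") per row."""
        if self.root is None:
            raise FitError("meta-tree is not fitted")
        x = features[self.feature_names_].to_numpy(dtype=float)
        out = np.empty(len(x), dtype=object)
        col = {f: i for i, f in enumerate(self.feature_names_)}
        for i, row in enumerate(x):
            node = self.root
            while not node.is_leaf:
                node = node.left if row[col[node.feature]] <= node.threshold else node.right
            out[i] = node.prediction
        return out

    def training_accuracy(self) -> float:
        """Weighted fraction of training records in leaves matching their class."""
        if self.root is None:
            raise FitError("meta-tree is not fitted")
        correct = total = 0

        def walk(node: TreeNode) -> None:
            nonlocal correct, total
            if node.is_leaf:
                total += node.n
                correct += node.counts[MODEL_CLASSES.index(node.prediction)]
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return correct / total

    def to_json(self, path: str | Path | None = None) -> str:
        if self.root is None:
            raise FitError("meta-tree is not fitted")
        payload = json.dumps(
            {
                "max_depth": self.max_depth,
                "min_samples_leaf": self.min_samples_leaf,
                "feature_names": self.feature_names_,
                "degenerate_single_class": self.degenerate_single_class_,
                "root": self.root.to_dict(),
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "MetaTree":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        tree = cls(max_depth=d["max_depth"], min_samples_leaf=d["min_samples_leaf"])
        tree.feature_names_ = d["feature_names"]
        tree.degenerate_single_class_ = d["degenerate_single_class"]
        tree.root = TreeNode.from_dict(d["root"])
        return tree


def fit_meta_tree(
    features: pd.DataFrame,
    labels,
    max_depth: int = 4,
    min_samples_leaf: int = 20,
    seed: int = 0,
) -> MetaTree:
    """Fit the CART arbiter on disagreement records.

    ``seed`` is accepted for interface uniformity; the greedy search and
    its tie-breaks are fully deterministic.  If only one class is present
    the returned tree is a flagged single-leaf tree.
    """
    return MetaTree(max_depth=max_depth, min_samples_leaf=min_samples_leaf).fit(
        features, labels
    )


def gini_importance(tree: MetaTree) -> pd.Series:
    """Per-feature Gini importance, normalized to sum to 1.

    importance(f) = sum over internal nodes splitting on f of
    (n_node / n_total) * (G(node) - weighted child G); the zero vector if
    the tree has no splits.
    """
    if tree.root is None:
        raise FitError("meta-tree is not fitted")
    raw = pd.Series(0.0, index=tree.feature_names_)
    n_total = tree.root.n

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        child_g = (
            node.left.n * node.left.impurity + node.right.n * node.right.impurity
        ) / node.n
        raw[node.feature] += (node.n / n_total) * (node.impurity - child_g)
        walk(node.left)
        walk(node.right)

    walk(tree.root)
    total = raw.sum()
    return raw / total if total > 0 else raw


def ensemble_predict(cox_labels, gbt_labels, features: pd.DataFrame, tree: MetaTree) -> np.ndarray:
    """Final high-risk labels: Cox by default, tree-arbitrated on disagreement.

    Where the models agree the (Cox) label passes through unchanged; on
    disagreement the label of whichever model the tree selects is used.
    """
    cox_labels = np.asarray(cox_labels, dtype=bool)
    gbt_labels = np.asarray(gbt_labels, dtype=bool)
    out = cox_labels.copy()
    dis = find_disagreements(cox_labels, gbt_labels)
    if len(dis) == 0:
        return out
    choice = tree.predict(features.iloc[dis])
    use_gbt = choice == "gbt"
    out[dis[use_gbt]] = gbt_labels[dis[use_gbt]]
    return out
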