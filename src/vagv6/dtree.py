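"""C4.5-style decision trees over taxon relative-abundance features.

Binary numeric splits chosen by gain ratio, pessimistic (error-based)
pruning with the classic 25% confidence factor, and stratified 10-fold
cross-validation. Used to predict clinical categories (pH class, amine
odor) from community composition, and rendered as an indented flow chart.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm


@dataclass
class TreeNode:
    """Internal node (feature/threshold + low/high children) or leaf."""

    class_counts: Counter
    feature: str | None = None
    threshold: float | None = None
    low: "TreeNode | None" = None
    high: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    @property
    def n(self) -> int:
        return sum(self.class_counts.values())

    @property
    def label(self):
        # majority class, ties broken by label order for determinism
        return min(self.class_counts.items(), key=lambda kv: (-kv[1], str(kv[0])))[0]

    def predict_one(self, row) -> object:
        node = self
        while not node.is_leaf:
            node = node.low if row[node.feature] <= node.threshold else node.high
        return node.label

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.low.n_nodes() + self.high.n_nodes()

    def render(self, indent: str = "") -> str:
        if self.is_leaf:
            dist = dict(sorted(self.class_counts.items(), key=str))
            return f"{indent}-> predict {self.label} {dist}\n"
        out = f"{indent}{self.feature} <= {self.threshold:.4f}?\n"
        out += f"{indent}  yes:\n" + self.low.render(indent + "    ")
        out += f"{indent}  no:\n" + self.high.render(indent + "    ")
        return out


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def best_split(features: pd.DataFrame, labels: np.ndarray,
               min_leaf: int = 2):
    """Exhaustive search over features x candidate thresholds (midpoints of
    consecutive distinct values) maximising the gain ratio among splits with
    positive information gain. Returns (feature, threshold, gain_ratio) or
    None."""
    n = len(labels)
    base = _entropy(labels)
    best = None
    for feat in features.columns:
        x = features[feat].to_numpy(float)
        order = np.argsort(x, kind="stable")
        xs, ys = x[order], labels[order]
        distinct = np.nonzero(np.diff(xs) > 0)[0]
        if distinct.size == 0:
            continue
        # numeric-attribute MDL penalty: choosing among m candidate
        # thresholds costs log2(m)/n bits of gain
        penalty = math.log2(distinct.size) / n
        for i in distinct:
            k = i + 1
            if k < min_leaf or n - k < min_leaf:
                continue
            thr = (xs[i] + xs[i + 1]) / 2
            gain = base - (k / n) * _entropy(ys[:k]) \
                - ((n - k) / n) * _entropy(ys[k:]) - penalty
            if gain <= 1e-12:
                continue
            p = k / n
            split_info = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
            ratio = gain / split_info
            key = (ratio, gain)
            if best is None or key > best[0]:
                best = (key, feat, thr)
    if best is None:
        return None
    (_ratio, _gain), feat, thr = best
    return feat, thr, _ratio


def induce_tree(features: pd.DataFrame, labels, min_leaf: int = 2
                ) -> TreeNode:
    """Recursive binary induction; stops on purity, no positive gain, or
    nodes smaller than ``2 * min_leaf``."""
    if features.shape[1] == 0:
        raise ValueError("empty feature set")
    labels = np.asarray(labels)
    node = TreeNode(Counter(labels.tolist()))
    if len(node.class_counts) < 2 or len(labels) < 2 * min_leaf:
        return node
    found = best_split(features, labels, min_leaf)
    if found is None:
        return node
    feat, thr, _ = found
    mask = features[feat].to_numpy(float) <= thr
    node.feature, node.threshold = feat, thr
    node.low = induce_tree(features[mask], labels[mask], min_leaf)
    node.high = induce_tree(features[~mask], labels[~mask], min_leaf)
    return node


def _pessimistic_errors(n: int, e: int, confidence: float) -> float:
    """C4.5 upper confidence bound on the error count of a leaf covering
    ``n`` cases with ``e`` training errors (one-sided binomial bound via the
    normal approximation, as in the original implementation)."""
    if n == 0:
        return 0.0
    if e == 0:
        # exact binomial bound for error-free leaves
        return n * (1 - confidence ** (1 / n))
    z = float(norm.isf(confidence))
    f = (e + 0.5) / n          # continuity-corrected error frequency
    if f >= 1:
        return float(n)
    ub = (f + z * z / (2 * n)
          + z * math.sqrt(f / n - f * f / n + z * z / (4 * n * n))) \
        / (1 + z * z / n)
    return min(ub, 1.0) * n


def _subtree_error(node: TreeNode, confidence: float) -> float:
    if node.is_leaf:
        return _pessimistic_errors(node.n, node.n - node.class_counts[node.label],
                                   confidence)
    return _subtree_error(node.low, confidence) \
        + _subtree_error(node.high, confidence)


def prune_tree(node: TreeNode, confidence: float = 0.25) -> TreeNode:
    """Bottom-up pessimistic pruning: collapse a subtree to a leaf whenever
    the leaf's error bound does not exceed the subtree's summed bound."""
    if node.is_leaf:
        return node
    node.low = prune_tree(node.low, confidence)
    node.high = prune_tree(node.high, confidence)
    leaf_err = _pessimistic_errors(node.n, node.n - node.class_counts[node.label],
                                   confidence)
    if leaf_err <= _subtree_error(node, confidence) + 1e-12:
        return TreeNode(node.class_counts)
    return node


def predict(tree: TreeNode, features: pd.DataFrame) -> np.ndarray:
    return np.array([tree.predict_one(row) for _, row in features.iterrows()])


def accuracy(tree: TreeNode, features: pd.DataFrame, labels) -> float:
    return float((predict(tree, features) == np.asarray(labels)).mean())


@dataclass
class TreeReport:
    tree: TreeNode
    training_accuracy: float
    cv_accuracy: float
    k: int
    seed: int
    stratified: bool = True
    rendering: str = ""


def cross_validate(features: pd.DataFrame, labels, k: int = 10,
                   seed: int = 0, min_leaf: int = 2,
                   confidence: float = 0.25) -> TreeReport:
    """Induce + prune on the full data (reported tree) and score mean
    accuracy over (stratified when possible) k folds."""
    from sklearn.model_selection import KFold, StratifiedKFold

    labels = np.asarray(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"need at least k={k} samples")
    features = features.reset_index(drop=True)
    _, counts = np.unique(labels, return_counts=True)
    stratified = counts.min() >= k
    if stratified:
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(features, labels)
    else:
        import warnings
        warnings.warn("a class has fewer members than folds; "
                      "using unstratified folds", stacklevel=2)
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
        folds = splitter.split(features)
    accs = []
    for train, test in folds:
        t = prune_tree(induce_tree(features.iloc[train], labels[train],
                                   min_leaf), confidence)
        accs.append(accuracy(t, features.iloc[test], labels[test]))
    full = prune_tree(induce_tree(features, labels, min_leaf), confidence)
    return TreeReport(full, accuracy(full, features, labels),
                      float(np.mean(accs)), k, seed, stratified,
                      full.render())


def ph_odor_trees(cohort, seed: int = 0) -> dict[str, TreeReport]:
    """Two clinical trees from taxon proportions: pH class (<=4.5 vs >4.5)
    and amine odor (absent vs present). Samples with the target missing are
    dropped; a missing clinical column skips that tree with a warning."""
    import warnings

    props = cohort.proportions().reset_index(drop=True)
    out = {}
    targets = {
        "ph": (cohort.df["ph"] > 4.5).where(cohort.df["ph"].notna()).map(
            {True: "pH>4.5", False: "pH<=4.5"}),
        "odor": cohort.df["amsel_odor"].map({1.0: "odor", 0.0: "no odor"}),
    }
    for name, target in targets.items():
        ok = target.notna()
        if ok.sum() == 0 or target[ok].nunique() < 2:
            warnings.warn(f"target {name!r} unusable; skipped", stacklevel=2)
            continue
        out[name] = cross_validate(props[ok.to_numpy()],
                                   target[ok].to_numpy(), seed=seed)
    return out
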