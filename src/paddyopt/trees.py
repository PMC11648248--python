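"""Decision-path analysis: an information-gain threshold tree over benefits.

The classifier predicts a record's composite benefit code from its five
benefit values using greedy binary splits on continuous features that
maximize information gain, with candidate thresholds at the midpoints of
consecutive sorted unique values (the classical ID3 entropy criterion
extended to continuous features a la C4.5).  Reduced-error pruning against a
validation fold carved from the training set guards against overfitting.
Root-to-leaf paths ending in a target code — e.g. the suboptimal
``HY-HG-HB-HP-LE`` — are extracted as ordered threshold conditions with the
leaf's class probability (training-set leaf purity) and support, mirroring
how benefit-path probabilities are read off the fitted tree.  A bagging
ensemble (bootstrap trees, majority vote) serves as a cross-check.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class TreeNode:
    """Either an internal threshold split or a class leaf."""

    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    klass: str | None = None
    probability: float | None = None
    support: int = 0
    class_counts: dict = field(default_factory=dict)

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def n_nodes(self) -> int:
        if self.is_leaf:
            return 1
        return 1 + self.left.n_nodes() + self.right.n_nodes()

    def predict_one(self, row) -> str:
        node = self
        while not node.is_leaf:
            node = node.left if row[node.feature] < node.threshold else node.right
        return node.klass

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {"class": self.klass, "probability": self.probability,
                    "support": self.support}
        return {"feature": self.feature, "threshold": self.threshold,
                "support": self.support,
                "left": self.left.to_dict(), "right": self.right.to_dict()}


@dataclass
class DecisionPath:
    """Ordered condition chain ending in a target-class leaf."""

    conditions: list[tuple[str, str, float]]  # (feature, "<" or ">=", threshold)
    klass: str
    probability: float
    support: int

    def __str__(self) -> str:
        conds = " and ".join(f"{f} {d} {t:.6g}" for f, d, t in self.conditions)
        return f"[{conds}] -> {self.klass} (p={self.probability:.2f}, n={self.support})"

    def interval(self, feature: str) -> tuple[float, float]:
        """Consistency interval (lo, hi) implied for one feature."""
        lo, hi = -np.inf, np.inf
        for f, d, t in self.conditions:
            if f != feature:
                continue
            if d == ">=":
                lo = max(lo, t)
            else:
                hi = min(hi, t)
        return lo, hi


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(x: np.ndarray, y_codes: np.ndarray, threshold: float,
                     n_classes: int) -> float:
    """Gain of splitting continuous feature x at threshold (< vs >=)."""
    left = x < threshold
    parent = np.bincount(y_codes, minlength=n_classes)
    lc = np.bincount(y_codes[left], minlength=n_classes)
    rc = parent - lc
    n = len(y_codes)
    nl, nr = lc.sum(), rc.sum()
    return _entropy(parent) - (nl / n) * _entropy(lc) - (nr / n) * _entropy(rc)


def _entropy_batch(counts: np.ndarray) -> np.ndarray:
    """Entropy of each row of a counts matrix (rows may sum to zero)."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, counts / np.where(totals == 0, 1, totals), 0.0)
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return -plogp.sum(axis=1)


def best_split(X: pd.DataFrame, y_codes: np.ndarray, n_classes: int,
               min_leaf: int = 1) -> tuple[str, float, float] | None:
    """Best (feature, threshold, gain) over all midpoint candidates.

    The scan is exhaustive (every midpoint of consecutive sorted unique
    values of every feature) but computed with prefix class counts.  Ties
    break deterministically toward the lowest feature index then the
    smallest threshold.  Returns None when no admissible split exists.
    """
    n = len(y_codes)
    parent_counts = np.bincount(y_codes, minlength=n_classes)
    h_parent = _entropy(parent_counts)
    best = None
    for j, feat in enumerate(X.columns):
        x = X[feat].to_numpy(dtype=float)
        order = np.argsort(x, kind="mergesort")
        xs, ys = x[order], y_codes[order]
        # candidate split after position i wherever the value changes
        change = np.flatnonzero(xs[:-1] < xs[1:])
        if change.size == 0:
            continue
        onehot = np.zeros((n, n_classes))
        onehot[np.arange(n), ys] = 1.0
        prefix = np.cumsum(onehot, axis=0)
        left_counts = prefix[change]
        right_counts = parent_counts - left_counts
        nl = change + 1
        nr = n - nl
        ok = (nl >= min_leaf) & (nr >= min_leaf)
        if not ok.any():
            continue
        gains = h_parent - (nl / n) * _entropy_batch(left_counts) \
            - (nr / n) * _entropy_batch(right_counts)
        mids = (xs[change] + xs[change + 1]) / 2.0
        gains = np.where(ok, gains, -np.inf)
        i = int(np.lexsort((mids, -gains))[0])  # max gain, then smallest threshold
        key = (-float(gains[i]), j, float(mids[i]))
        if best is None or key < best[0]:
            best = (key, feat, float(mids[i]), float(gains[i]))
    if best is None:
        return None
    return best[1], best[2], best[3]


def _make_leaf(y: np.ndarray) -> TreeNode:
    counts = Counter(y)
    # deterministic tie-break on label
    klass, n_major = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    return TreeNode(klass=klass, probability=n_major / len(y), support=len(y),
                    class_counts=dict(sorted(counts.items())))


def _grow(X: pd.DataFrame, y: np.ndarray, classes: list[str], depth: int,
          max_depth: int | None, min_leaf: int, min_gain: float) -> TreeNode:
    if len(set(y)) == 1 or (max_depth is not None and depth >= max_depth):
        return _make_leaf(y)
    code_of = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([code_of[v] for v in y])
    found = best_split(X, y_codes, len(classes), min_leaf=min_leaf)
    if found is None or found[2] <= min_gain:
        return _make_leaf(y)
    feat, thr, _ = found
    mask = X[feat].to_numpy(dtype=float) < thr
    node = TreeNode(feature=feat, threshold=thr, support=len(y))
    node.left = _grow(X[mask], y[mask], classes, depth + 1, max_depth, min_leaf, min_gain)
    node.right = _grow(X[~mask], y[~mask], classes, depth + 1, max_depth, min_leaf, min_gain)
    return node


def _prune_reduced_error(node: TreeNode, Xv: pd.DataFrame, yv: np.ndarray) -> TreeNode:
    """Bottom-up reduced-error pruning against a validation fold."""
    if node.is_leaf or len(yv) == 0:
        return node
    mask = Xv[node.feature].to_numpy(dtype=float) < node.threshold
    node.left = _prune_reduced_error(node.left, Xv[mask], yv[mask])
    node.right = _prune_reduced_error(node.right, Xv[~mask], yv[~mask])
    preds = np.array([node.predict_one(row) for _, row in Xv.iterrows()])
    subtree_correct = int((preds == yv).sum())
    leaf = _merged_leaf(node)
    leaf_correct = int((yv == leaf.klass).sum())
    if leaf_correct >= subtree_correct:
        return leaf
    return node


def _merged_leaf(node: TreeNode) -> TreeNode:
    counts: Counter = Counter()

    def collect(n: TreeNode) -> None:
        if n.is_leaf:
            counts.update(n.class_counts)
        else:
            collect(n.left)
            collect(n.right)

    collect(node)
    klass, n_major = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    total = sum(counts.values())
    return TreeNode(klass=klass, probability=n_major / total, support=total,
                    class_counts=dict(sorted(counts.items())))


def extract_paths(tree: TreeNode, target: str) -> list[DecisionPath]:
    """All root-to-leaf paths whose leaf class equals the target code."""
    paths: list[DecisionPath] = []

    def walk(node: TreeNode, conds: list[tuple[str, str, float]]) -> None:
        if node.is_leaf:
            if node.klass == target:
                paths.append(DecisionPath(conditions=list(conds), klass=node.klass,
                                          probability=node.probability,
                                          support=node.support))
            return
        walk(node.left, conds + [(node.feature, "<", node.threshold)])
        walk(node.right, conds + [(node.feature, ">=", node.threshold)])

    walk(tree, [])
    return paths


@dataclass
class ClassifierEvaluation:
    """Confusion matrix (rows = truth), accuracy and detection prevalence."""

    confusion: pd.DataFrame
    accuracy: float
    detection_prevalence: pd.Series

    def summary(self) -> str:
        lines = [f"accuracy: {self.accuracy:.4f}", "confusion matrix (rows=truth):",
                 self.confusion.to_string(), "detection prevalence:",
                 self.detection_prevalence.to_string()]
        return "\n".join(lines)


def evaluate_classifier(y_true, y_pred) -> ClassifierEvaluation:
    """Confusion matrix, accuracy, and per-class (TP+FP)/total."""
    y_true = pd.Series(list(y_true))
    y_pred = pd.Series(list(y_pred))
    if len(y_true) == 0:
        raise ValueError("empty test set")
    labels = sorted(set(y_true) | set(y_pred))
    cm = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for t, p in zip(y_true, y_pred):
        cm.loc[t, p] += 1
    total = len(y_true)
    accuracy = float(np.trace(cm.to_numpy())) / total
    prevalence = cm.sum(axis=0) / total  # column sums: predicted counts = TP+FP
    return ClassifierEvaluation(confusion=cm, accuracy=accuracy,
                                detection_prevalence=prevalence.rename("detection_prevalence"))


class BenefitPathModel:
    """Threshold tree over the five benefit values predicting composite codes.

    Parameters
    ----------
    features : DataFrame of the five benefit values per record.
    labels : Series of composite benefit codes aligned with ``features``.
    train_frac : fraction held for training (default 0.70, the rest is test).
    min_leaf, max_depth, min_gain : growth controls.
    prune : apply reduced-error pruning against a 20% validation fold carved
        from the training split.
    """

    def __init__(self, features: pd.DataFrame, labels: pd.Series,
                 train_frac: float = 0.70, min_leaf: int = 1,
                 max_depth: int | None = None, min_gain: float = 1e-12,
                 prune: bool = True):
        self.features = features.reset_index(drop=True)
        self.labels = pd.Series(list(labels))
        if self.features.isna().any().any():
            raise ValueError("features contain missing values")
        self.train_frac = train_frac
        self.min_leaf = min_leaf
        self.max_depth = max_depth
        self.min_gain = min_gain
        self.prune = prune

    def fit(self, seed: int = 0) -> "BenefitPathResults":
        rng = np.random.default_rng(seed)
        n = len(self.features)
        perm = rng.permutation(n)
        n_train = max(int(round(self.train_frac * n)), 1)
        train_idx, test_idx = perm[:n_train], perm[n_train:]
        Xtr, ytr = self.features.iloc[train_idx], self.labels.iloc[train_idx].to_numpy()
        if len(set(ytr)) < 2 and len(set(self.labels)) >= 2:
            import warnings

            warnings.warn("single class in training data; degenerate tree")
        if self.prune and len(train_idx) >= 5:
            n_val = max(int(round(0.2 * len(train_idx))), 1)
            val_idx, sub_idx = train_idx[:n_val], train_idx[n_val:]
            Xs, ys = self.features.iloc[sub_idx], self.labels.iloc[sub_idx].to_numpy()
            classes = sorted(set(ys))
            tree = _grow(Xs, ys, classes, 0, self.max_depth, self.min_leaf, self.min_gain)
            Xv, yv = self.features.iloc[val_idx], self.labels.iloc[val_idx].to_numpy()
            tree = _prune_reduced_error(tree, Xv, yv)
        else:
            classes = sorted(set(ytr))
            tree = _grow(Xtr, ytr, classes, 0, self.max_depth, self.min_leaf, self.min_gain)
        return BenefitPathResults(model=self, tree=tree,
                                  train_idx=train_idx, test_idx=test_idx, seed=seed)


@dataclass
class BenefitPathResults:
    """Fitted tree plus the train/test split it was grown on."""

    model: BenefitPathModel
    tree: TreeNode
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.array([self.tree.predict_one(row) for _, row in X.iterrows()])

    def paths(self, target: str) -> list[DecisionPath]:
        return extract_paths(self.tree, target)

    def evaluate(self, on: str = "test") -> ClassifierEvaluation:
        idx = self.test_idx if on == "test" else self.train_idx
        if len(idx) == 0:
            raise ValueError(f"empty {on} set")
        X = self.model.features.iloc[idx]
        y = self.model.labels.iloc[idx]
        return evaluate_classifier(y, self.predict(X))

    def summary(self) -> str:
        ev = self.evaluate("test") if len(self.test_idx) else self.evaluate("train")
        return (f"BenefitPathModel: {self.tree.n_nodes()} nodes, "
                f"train n={len(self.train_idx)}, test n={len(self.test_idx)}\n"
                + ev.summary())


def stratified_split(labels: pd.Series, train_frac: float, rng: np.random.Generator):
    """Per-class random split preserving class proportions within one record."""
    train, test = [], []
    for klass in sorted(set(labels)):
        idx = np.flatnonzero((labels == klass).to_numpy())
        idx = rng.permutation(idx)
        if len(idx) == 1:
            train.extend(idx)  # singleton classes stay in training
            continue
        n_train = max(int(round(train_frac * len(idx))), 1)
        n_train = min(n_train, len(idx) - 1) if len(idx) > 1 else n_train
        train.extend(idx[:n_train])
        test.extend(idx[n_train:])
    return np.array(sorted(train)), np.array(sorted(test))


class BaggingPathModel:
    """Bootstrap ensemble of benefit-path trees with majority voting."""

    def __init__(self, features: pd.DataFrame, labels: pd.Series,
                 train_frac: float = 0.75, n_bags: int = 25,
                 bootstrap: bool = True, min_leaf: int = 1,
                 max_depth: int | None = None):
        self.features = features.reset_index(drop=True)
        self.labels = pd.Series(list(labels))
        self.train_frac = train_frac
        self.n_bags = n_bags
        self.bootstrap = bootstrap
        self.min_leaf = min_leaf
        self.max_depth = max_depth

    def fit(self, seed: int = 0) -> "BaggingPathResults":
        rng = np.random.default_rng(seed)
        singletons = [k for k, v in Counter(self.labels).items() if v == 1]
        if singletons:
            import warnings

            warnings.warn(f"classes with a single record kept whole in training: {singletons}")
        train_idx, test_idx = stratified_split(self.labels, self.train_frac, rng)
        Xtr = self.features.iloc[train_idx].reset_index(drop=True)
        ytr = self.labels.iloc[train_idx].reset_index(drop=True)
        trees = []
        for _ in range(self.n_bags):
            if self.bootstrap:
                bag = rng.integers(0, len(Xtr), size=len(Xtr))
            else:
                bag = np.arange(len(Xtr))
            Xb, yb = Xtr.iloc[bag], ytr.iloc[bag].to_numpy()
            classes = sorted(set(yb))
            trees.append(_grow(Xb, yb, classes, 0, self.max_depth, self.min_leaf, 1e-12))
        return BaggingPathResults(model=self, trees=trees,
                                  train_idx=train_idx, test_idx=test_idx, seed=seed)


@dataclass
class BaggingPathResults:
    model: BaggingPathModel
    trees: list[TreeNode]
    train_idx: np.ndarray
    test_idx: np.ndarray
    seed: int

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        votes = np.array([[t.predict_one(row) for t in self.trees]
                          for _, row in X.iterrows()], dtype=object)
        out = []
        for row_votes in votes:
            counts = Counter(row_votes)
            out.append(sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[0][0])
        return np.array(out)

    def evaluate(self, on: str = "test") -> ClassifierEvaluation:
        idx = self.test_idx if on == "test" else self.train_idx
        if len(idx) == 0:
            raise ValueError(f"empty {on} set")
        X = self.model.features.iloc[idx]
        y = self.model.labels.iloc[idx]
        return evaluate_classifier(y, self.predict(X))
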