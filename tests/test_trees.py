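import math

import numpy as np
import pandas as pd
import pytest

import paddyopt as po
from paddyopt.trees import (
    BaggingPathModel,
    BenefitPathModel,
    _grow,
    best_split,
    evaluate_classifier,
    extract_paths,
    stratified_split,
)


# -- independent oracle: exhaustive information-gain enumeration --------------

def _oracle_entropy(labels):
    n = len(labels)
    h = 0.0
    for lab in set(labels):
        p = sum(1 for v in labels if v == lab) / n
        h -= p * math.log2(p)
    return h


def oracle_best_split(X: pd.DataFrame, y: list):
    """Plain-loop enumeration of every feature/midpoint candidate."""
    best = None
    for j, feat in enumerate(X.columns):
        xs = sorted(set(X[feat]))
        for lo, hi in zip(xs[:-1], xs[1:]):
            t = (lo + hi) / 2
            left = [lab for v, lab in zip(X[feat], y) if v < t]
            right = [lab for v, lab in zip(X[feat], y) if v >= t]
            gain = _oracle_entropy(y) - len(left) / len(y) * _oracle_entropy(left) \
                - len(right) / len(y) * _oracle_entropy(right)
            key = (-gain, j, t)
            if best is None or key < best[0]:
                best = (key, feat, t, gain)
    return None if best is None else best[1:]


@pytest.mark.parametrize("seed", range(8))
def test_root_split_matches_exhaustive_oracle(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 13))
    k = int(rng.integers(1, 4))
    X = pd.DataFrame(rng.integers(0, 6, size=(n, k)).astype(float),
                     columns=[f"f{i}" for i in range(k)])
    y = rng.choice(["a", "b", "c"], size=n)
    classes = sorted(set(y))
    codes = np.array([classes.index(v) for v in y])
    got = best_split(X, codes, len(classes))
    want = oracle_best_split(X, list(y))
    if want is None or want[2] <= 0:
        assert got is None or got[2] == pytest.approx(0.0, abs=1e-12) or got[2] == pytest.approx(want[2])
    else:
        assert got is not None
        assert got[0] == want[0]
        assert got[1] == pytest.approx(want[1])
        assert got[2] == pytest.approx(want[2], abs=1e-12)


def test_perfectly_separable_toy_set():
    X = pd.DataFrame({"yield": [8000, 8200, 9000, 9500, 10500, 11000, 11500, 12000],
                      "ghg": [400.0] * 8})
    y = pd.Series(["low"] * 4 + ["high"] * 4)
    model = BenefitPathModel(X, y, train_frac=1.0, prune=False)
    res = model.fit(seed=0)
    assert res.tree.feature == "yield"
    assert res.tree.threshold == pytest.approx((9500 + 10500) / 2)
    assert res.tree.left.is_leaf and res.tree.right.is_leaf
    assert res.tree.left.probability == 1.0 and res.tree.right.probability == 1.0


def test_single_class_gives_single_leaf():
    X = pd.DataFrame({"yield": [1.0, 2.0, 3.0]})
    y = pd.Series(["only"] * 3)
    res = BenefitPathModel(X, y, train_frac=1.0, prune=False).fit(seed=0)
    assert res.tree.is_leaf
    assert res.tree.klass == "only" and res.tree.probability == 1.0


def test_fit_is_deterministic(calibrated_benefits):
    mt = calibrated_benefits[calibrated_benefits["method"] == "MT"]
    bands = po.derive_bands(calibrated_benefits)
    labels = po.classify_table(mt, bands)
    X = mt[list(po.BENEFIT_COLUMNS)]
    r1 = BenefitPathModel(X, labels).fit(seed=11)
    r2 = BenefitPathModel(X, labels).fit(seed=11)
    assert r1.tree.to_dict() == r2.tree.to_dict()
    assert (r1.train_idx == r2.train_idx).all()


def _check_support_conservation(node):
    if node.is_leaf:
        return
    assert node.left.support + node.right.support == node.support
    _check_support_conservation(node.left)
    _check_support_conservation(node.right)


def test_leaf_support_conservation(calibrated_benefits):
    mt = calibrated_benefits[calibrated_benefits["method"] == "MT"]
    bands = po.derive_bands(calibrated_benefits)
    labels = po.classify_table(mt, bands)
    res = BenefitPathModel(mt[list(po.BENEFIT_COLUMNS)], labels, prune=False,
                           train_frac=1.0).fit(seed=0)
    _check_support_conservation(res.tree)


def test_pruning_shrinks_tree_and_training_accuracy(calibrated_benefits):
    mat = calibrated_benefits[calibrated_benefits["method"] == "MAT"]
    bands = po.derive_bands(calibrated_benefits)
    labels = po.classify_table(mat, bands)
    X = mat[list(po.BENEFIT_COLUMNS)]
    pruned = BenefitPathModel(X, labels, prune=True).fit(seed=2)
    unpruned = BenefitPathModel(X, labels, prune=False).fit(seed=2)
    assert pruned.tree.n_nodes() <= unpruned.tree.n_nodes()
    acc_p = pruned.evaluate("train").accuracy
    acc_u = unpruned.evaluate("train").accuracy
    assert acc_p <= acc_u + 1e-12


def test_extract_paths_pure_tree():
    X = pd.DataFrame({"yield": [1.0, 2.0]})
    y = pd.Series(["only", "only"])
    res = BenefitPathModel(X, y, train_frac=1.0, prune=False).fit(seed=0)
    paths = res.paths("only")
    assert len(paths) == 1
    assert paths[0].probability == 1.0 and paths[0].conditions == []
    assert res.paths("absent") == []


def test_path_conditions_are_consistent(calibrated_benefits):
    mt = calibrated_benefits[calibrated_benefits["method"] == "MT"]
    bands = po.derive_bands(calibrated_benefits)
    labels = po.classify_table(mt, bands)
    res = BenefitPathModel(mt[list(po.BENEFIT_COLUMNS)], labels).fit(seed=5)
    target = labels.mode()[0]
    for path in res.paths(target):
        for feat in po.BENEFIT_COLUMNS:
            lo, hi = path.interval(feat)
            assert lo < hi


def test_paths_to_high_yield_code_respect_band_threshold(calibrated_benefits):
    """Paths reaching a high-yield code must require yield at (or above) a
    threshold consistent with the fitted high-yield band limit."""
    bands = po.derive_bands(calibrated_benefits)
    mt = calibrated_benefits[calibrated_benefits["method"] == "MT"]
    labels = po.classify_table(mt, bands)
    hy = [c for c in labels.unique() if c.startswith("HY")]
    if not hy:
        pytest.skip("no high-yield records in this cohort draw")
    res = BenefitPathModel(mt[list(po.BENEFIT_COLUMNS)], labels,
                           train_frac=1.0, prune=False).fit(seed=0)
    target = labels[labels.isin(hy)].mode()[0]
    paths = res.paths(target)
    assert paths, "high-yield code unreachable in fitted tree"
    high_limit = bands.thresholds["yield"]["high"]
    for path in paths:
        lo, hi = path.interval("yield")
        # the path's feasible yield interval must reach into the high band
        assert hi > high_limit * 0.95 or lo >= high_limit * 0.8


def test_evaluate_classifier_perfect_and_hand_example():
    ev = evaluate_classifier(["a", "b", "a"], ["a", "b", "a"])
    assert ev.accuracy == 1.0
    assert ev.confusion.loc["a", "a"] == 2 and ev.confusion.loc["b", "b"] == 1
    # TP 3, FP 1, FN 1, TN 5 on the positive class
    truth = ["pos"] * 4 + ["neg"] * 6
    pred = ["pos"] * 3 + ["neg"] + ["pos"] + ["neg"] * 5
    ev = evaluate_classifier(truth, pred)
    assert ev.accuracy == pytest.approx(0.8)
    assert ev.detection_prevalence["pos"] == pytest.approx(0.4)


def test_empty_test_set_is_an_error():
    with pytest.raises(ValueError):
        evaluate_classifier([], [])


def test_bagging_single_unbootstrapped_tree_matches_plain_tree(calibrated_benefits):
    md = calibrated_benefits[calibrated_benefits["method"] == "MD"]
    bands = po.derive_bands(calibrated_benefits)
    labels = po.classify_table(md, bands)
    X = md[list(po.BENEFIT_COLUMNS)].reset_index(drop=True)
    labels = pd.Series(list(labels))
    bag = BaggingPathModel(X, labels, n_bags=1, bootstrap=False).fit(seed=4)
    Xtr = X.iloc[bag.train_idx]
    ytr = labels.iloc[bag.train_idx].to_numpy()
    tree = _grow(Xtr, ytr, sorted(set(ytr)), 0, None, 1, 1e-12)
    Xte = X.iloc[bag.test_idx]
    single = np.array([tree.predict_one(row) for _, row in Xte.iterrows()])
    assert (bag.predict(Xte) == single).all()


def test_stratified_split_preserves_class_proportions():
    labels = pd.Series(["a"] * 40 + ["b"] * 20 + ["c"] * 8)
    rng = np.random.default_rng(0)
    train_idx, test_idx = stratified_split(labels, 0.75, rng)
    for klass, n in (("a", 40), ("b", 20), ("c", 8)):
        in_train = (labels.iloc[train_idx] == klass).sum()
        assert abs(in_train - 0.75 * n) <= 1


def test_bagging_usually_at_least_as_accurate_as_single_tree(calibrated_benefits):
    """On a shared stratified split, majority voting over bootstrap trees is
    at least as accurate as one pruned tree in most replicates."""
    mt = calibrated_benefits[calibrated_benefits["method"] == "MT"]
    bands = po.derive_bands(calibrated_benefits)
    labels = pd.Series(list(po.classify_table(mt, bands)))
    X = mt[list(po.BENEFIT_COLUMNS)].reset_index(drop=True)
    wins = 0
    for seed in range(10):
        bag = BaggingPathModel(X, labels, n_bags=11).fit(seed=seed)
        Xtr = X.iloc[bag.train_idx]
        ytr = labels.iloc[bag.train_idx]
        single = BenefitPathModel(Xtr, ytr, train_frac=1.0, prune=True).fit(seed=seed)
        Xte = X.iloc[bag.test_idx]
        yte = labels.iloc[bag.test_idx]
        acc_tree = evaluate_classifier(yte, single.predict(Xte)).accuracy
        acc_bag = bag.evaluate("test").accuracy
        if acc_bag >= acc_tree - 1e-12:
            wins += 1
    assert wins >= 7
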