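"""From-scratch CART decision trees and a bagged random-forest classifier.

Trees are grown by recursive binary partitioning on the Gini impurity
criterion: every candidate split is a midpoint between consecutive distinct
sorted values of one feature, the split maximizing the weighted impurity
decrease wins, and ties break deterministically by (feature order, lower
threshold).  Samples with feature value <= threshold route left.

The forest bags trees on bootstrap resamples with per-split feature
subsampling (mtry = floor(sqrt(p)) by default) and predicts by majority
vote with ties resolved toward the class of lower canonical (sorted)
order.  Feature importance is the classical mean decrease in Gini
impurity, recorded while growing: each split contributes its impurity
decrease weighted by the fraction of training samples reaching the node,
summed per tree, averaged over trees and normalized to sum to 1.  The
"representative tree" of a forest is the member whose own predictions
agree most with the ensemble vote.

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TreeNode",
    "Forest",
    "TreeParams",
    "ImportanceRanking",
    "gini_impurity",
    "best_split",
    "grow_tree",
    "grow_forest",
    "predict",
    "feature_importance",
    "representative_tree",
    "tree_to_dict",
    "tree_from_dict",
    "save_model",
    "load_model",
    "CartClassifier",
    "RandomForestClassifier",
]


@dataclass
class TreeNode:
    """One node of a CART tree.

    Internal nodes carry (feature, threshold, left, right); leaves carry
    only class counts.  Every node records its training sample count and,
    for internal nodes, the weighted Gini decrease of its split (relative
    to the samples reaching the node) for importance accounting.
    """

    class_counts: dict[str, int]
    n_samples: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    impurity_decrease: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())


@dataclass
class Forest:
    """A bagged ensemble of CART trees grown from a single seed."""

    trees: list[TreeNode]
    n_trees: int
    mtry: int
    seed: int
    bootstrap: bool
    classes: tuple[str, ...]
    feature_names: tuple[str, ...]


@dataclass
class TreeParams:
    """Growth limits for a single tree.

    max_depth None means unlimited; min_leaf_size is the minimum number of
    training samples each child of a split must keep; mtry None means all
    features are candidates at every split.
    """

    max_depth: int | None = None
    min_leaf_size: int = 1
    mtry: int | None = None


#: Ordered (feature, mean-decrease-in-Gini) pairs, non-increasing.
ImportanceRanking = list


def gini_impurity(class_counts: Mapping[str, float] | Sequence[float]) -> float:
    """Gini impurity 1 - sum((n_c / n)^2) of a class-count vector."""
    counts = np.asarray(
        list(class_counts.values())
        if isinstance(class_counts, Mapping)
        else class_counts,
        dtype=float,
    )
    if (counts < 0).any():
        raise ValueError("negative class counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("empty node: total count is zero")
    p = counts / total
    return float(1.0 - (p**2).sum())


def _as_matrix(X, feature_names=None):
    """Coerce X to (array, feature_names); DataFrames supply their columns."""
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(str(c) for c in X.columns)
    arr = np.asarray(X, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1)
    if feature_names is None:
        feature_names = tuple(f"feature_{j}" for j in range(arr.shape[1]))
    return arr, tuple(feature_names)


def _scan_feature(v, codes, k, min_leaf):
    """Best midpoint split of one feature.

    Returns (decrease, threshold) or None.  Candidate thresholds are
    midpoints between consecutive distinct sorted values; both children
    must keep >= min_leaf samples.  Among equal decreases the lowest
    threshold wins (argmax returns the first, and candidates are scanned
    in increasing value order).
    """
    n = v.shape[0]
    order = np.argsort(v, kind="mergesort")
    vs = v[order]
    ys = codes[order]
    # cumulative class counts over the sorted prefix
    onehot = ys[:, None] == np.arange(k)[None, :]
    cum = np.cumsum(onehot, axis=0).astype(float)
    total = cum[-1]
    nl = np.arange(1, n, dtype=float)
    valid = (vs[1:] > vs[:-1]) & (nl >= min_leaf) & ((n - nl) >= min_leaf)
    if not valid.any():
        return None
    idx = np.nonzero(valid)[0]
    cl = cum[idx]
    nl = nl[idx]
    nr = n - nl
    cr = total[None, :] - cl
    gl = 1.0 - ((cl / nl[:, None]) ** 2).sum(axis=1)
    gr = 1.0 - ((cr / nr[:, None]) ** 2).sum(axis=1)
    parent = 1.0 - ((total / n) ** 2).sum()
    decrease = parent - (nl * gl + nr * gr) / n
    best = int(np.argmax(decrease))
    i = idx[best]
    threshold = (vs[i] + vs[i + 1]) / 2.0
    return float(decrease[best]), float(threshold)


def best_split(X, y, candidate_features=None, min_leaf_size: int = 1, feature_names=None):
    """Exhaustive best Gini split over the candidate features.

    ``candidate_features`` is an iterable of feature indices (default: all);
    candidates are scanned in ascending index order so ties resolve toward
    the earlier feature, then the lower threshold.  Returns
    ``(feature_name, threshold, impurity_decrease)`` or ``None`` when no
    split decreases the impurity.
    """
    X, feature_names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if X.shape[0] < 2:
        return None
    classes, codes = np.unique(y, return_inverse=True)
    if classes.shape[0] < 2:
        return None
    if candidate_features is None:
        candidate_features = range(X.shape[1])
    best = None
    for j in sorted(candidate_features):
        result = _scan_feature(X[:, j], codes, classes.shape[0], min_leaf_size)
        if result is None:
            continue
        decrease, threshold = result
        # strict > keeps the earliest feature on exact ties
        if decrease > 1e-15 and (best is None or decrease > best[2]):
            best = (feature_names[j], threshold, decrease)
    return best


def _grow(X, y_codes, idx, classes, feature_names, params, rng, depth, n_total):
    counts_arr = np.bincount(y_codes[idx], minlength=len(classes))
    counts = {classes[c]: int(counts_arr[c]) for c in range(len(classes))}
    node = TreeNode(class_counts=counts, n_samples=int(idx.shape[0]))
    n_nonzero = int((counts_arr > 0).sum())
    if (
        n_nonzero < 2
        or idx.shape[0] < 2 * params.min_leaf_size
        or (params.max_depth is not None and depth >= params.max_depth)
    ):
        return node
    p = X.shape[1]
    if params.mtry is not None and params.mtry < p:
        # keep the rng's draw order: ties then favor a random feature, which
        # avoids a systematic importance bias toward low-index features
        candidates = rng.choice(p, size=params.mtry, replace=False).tolist()
    else:
        candidates = range(p)
    sub_codes = y_codes[idx]
    sub_classes, sub_inverse = np.unique(sub_codes, return_inverse=True)
    best = None
    for j in candidates:
        result = _scan_feature(
            X[idx, j], sub_inverse, sub_classes.shape[0], params.min_leaf_size
        )
        if result is None:
            continue
        decrease, threshold = result
        if decrease > 1e-15 and (best is None or decrease > best[2]):
            best = (j, threshold, decrease)
    if best is None:
        return node
    j, threshold, decrease = best
    go_left = X[idx, j] <= threshold
    node.feature = feature_names[j]
    node.threshold = threshold
    node.impurity_decrease = decrease
    node.left = _grow(
        X, y_codes, idx[go_left], classes, feature_names, params, rng, depth + 1, n_total
    )
    node.right = _grow(
        X, y_codes, idx[~go_left], classes, feature_names, params, rng, depth + 1, n_total
    )
    return node


def grow_tree(X, y, params: TreeParams | None = None, rng=None, feature_names=None) -> TreeNode:
    """Grow a CART tree by recursive partitioning on Gini impurity.

    Splitting stops at purity, the depth limit, or when a child would fall
    below ``min_leaf_size``.  When ``params.mtry`` is below the feature
    count, each split draws that many candidate features without
    replacement from ``rng``.
    """
    params = params or TreeParams()
    X, feature_names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    if X.shape[0] == 0:
        raise ValueError("cannot grow a tree from an empty dataset")
    if rng is None:
        rng = np.random.default_rng(0)
    classes = tuple(str(c) for c in np.unique(y.astype(str)))
    lookup = {c: i for i, c in enumerate(classes)}
    y_codes = np.array([lookup[str(v)] for v in y], dtype=np.int64)
    idx = np.arange(X.shape[0])
    return _grow(X, y_codes, idx, classes, feature_names, params, rng, 0, X.shape[0])


def grow_forest(
    X,
    y,
    n_trees: int = 500,
    params: TreeParams | None = None,
    seed: int = 0,
    bootstrap: bool = True,
    feature_names=None,
) -> Forest:
    """Grow a bagged random forest.

    Each tree sees a bootstrap resample (n draws with replacement) and
    subsamples ``mtry = floor(sqrt(p))`` candidate features per split by
    default.  The whole ensemble is a pure function of the seed.
    """
    X, feature_names = _as_matrix(X, feature_names)
    y = np.asarray(y)
    n, p = X.shape
    if n < 2:
        raise ValueError("forest needs at least 2 samples")
    params = params or TreeParams()
    if params.mtry is None:
        params = TreeParams(
            max_depth=params.max_depth,
            min_leaf_size=params.min_leaf_size,
            mtry=max(1, int(np.floor(np.sqrt(p)))),
        )
    classes = tuple(str(c) for c in np.unique(y.astype(str)))
    streams = np.random.SeedSequence(seed).spawn(n_trees)
    trees = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        if bootstrap:
            sample = rng.integers(0, n, size=n)
        else:
            sample = np.arange(n)
        trees.append(grow_tree(X[sample], y[sample], params, rng, feature_names))
    return Forest(
        trees=trees,
        n_trees=n_trees,
        mtry=params.mtry,
        seed=seed,
        bootstrap=bootstrap,
        classes=classes,
        feature_names=feature_names,
    )


def _leaf_prediction(node: TreeNode) -> str:
    counts = node.class_counts
    best_count = max(counts.values())
    # canonical (sorted) class order breaks ties
    return sorted(c for c, v in counts.items() if v == best_count)[0]


def _predict_tree(node: TreeNode, row, name_to_col) -> str:
    while not node.is_leaf:
        if node.feature not in name_to_col:
            raise ValueError(f"unknown feature {node.feature!r} at prediction time")
        if row[name_to_col[node.feature]] <= node.threshold:
            node = node.left
        else:
            node = node.right
    return _leaf_prediction(node)


def predict(model: TreeNode | Forest, X, feature_names=None) -> np.ndarray:
    """Predict class labels with a tree or a forest.

    DataFrames are matched to the model's training features by column
    name; plain arrays must already be in training feature order.  Forest
    votes are majority with ties going to the class of lower sorted order.
    """
    if isinstance(model, Forest):
        if isinstance(X, pd.DataFrame):
            X = X.rename(columns=str)
            missing = set(model.feature_names) - set(X.columns)
            if missing:
                raise ValueError(f"unknown/missing features: {sorted(missing)}")
            X = X[list(model.feature_names)]
        arr, names = _as_matrix(X, model.feature_names)
        name_to_col = {f: j for j, f in enumerate(names)}
        votes = np.empty((len(model.trees), arr.shape[0]), dtype=object)
        for t, tree in enumerate(model.trees):
            votes[t] = [_predict_tree(tree, arr[i], name_to_col) for i in range(arr.shape[0])]
        out = []
        for i in range(arr.shape[0]):
            tally: dict[str, int] = {}
            for t in range(len(model.trees)):
                tally[votes[t, i]] = tally.get(votes[t, i], 0) + 1
            top = max(tally.values())
            winners = sorted(c for c, v in tally.items() if v == top)
            out.append(winners[0])
        return np.array(out, dtype=object)
    arr, names = _as_matrix(X, feature_names)
    name_to_col = {f: j for j, f in enumerate(names)}
    return np.array(
        [_predict_tree(model, arr[i], name_to_col) for i in range(arr.shape[0])],
        dtype=object,
    )


def _accumulate_importance(node: TreeNode, n_root: int, acc: dict[str, float]) -> None:
    if node.is_leaf:
        return
    acc[node.feature] = acc.get(node.feature, 0.0) + node.impurity_decrease * (
        node.n_samples / n_root
    )
    _accumulate_importance(node.left, n_root, acc)
    _accumulate_importance(node.right, n_root, acc)


def feature_importance(forest: Forest) -> ImportanceRanking:
    """Mean decrease in Gini impurity per feature, normalized to sum to 1.

    Importances are accumulated from the split records stored at training
    time.  The ranking covers every training feature, is non-increasing,
    and breaks ties by canonical feature order.
    """
    totals = {f: 0.0 for f in forest.feature_names}
    for tree in forest.trees:
        acc: dict[str, float] = {}
        _accumulate_importance(tree, tree.n_samples, acc)
        for f, v in acc.items():
            totals[f] += v
    means = {f: v / len(forest.trees) for f, v in totals.items()}
    grand = sum(means.values())
    if grand > 0:
        means = {f: v / grand for f, v in means.items()}
    order = {f: j for j, f in enumerate(forest.feature_names)}
    return sorted(means.items(), key=lambda item: (-item[1], order[item[0]]))


def representative_tree(forest: Forest, X) -> TreeNode:
    """The member tree most agreeing with the forest's majority vote on X.

    Ties resolve toward the lowest tree index.
    """
    ensemble = predict(forest, X)
    best_tree = None
    best_agreement = -1.0
    if isinstance(X, pd.DataFrame):
        X = X.rename(columns=str)[list(forest.feature_names)]
    arr, names = _as_matrix(X, forest.feature_names)
    name_to_col = {f: j for j, f in enumerate(names)}
    for tree in forest.trees:
        preds = np.array(
            [_predict_tree(tree, arr[i], name_to_col) for i in range(arr.shape[0])],
            dtype=object,
        )
        agreement = float((preds == ensemble).mean())
        if agreement > best_agreement:
            best_agreement = agreement
            best_tree = tree
    return best_tree


# -- serialization -----------------------------------------------------------

def tree_to_dict(node: TreeNode) -> dict:
    d: dict = {
        "class_counts": node.class_counts,
        "n_samples": node.n_samples,
    }
    if not node.is_leaf:
        d.update(
            feature=node.feature,
            threshold=node.threshold,
            impurity_decrease=node.impurity_decrease,
            left=tree_to_dict(node.left),
            right=tree_to_dict(node.right),
        )
    return d


def tree_from_dict(d: dict) -> TreeNode:
    node = TreeNode(
        class_counts={str(k): int(v) for k, v in d["class_counts"].items()},
        n_samples=int(d["n_samples"]),
    )
    if "feature" in d:
        node.feature = d["feature"]
        node.threshold = float(d["threshold"])
        node.impurity_decrease = float(d.get("impurity_decrease", 0.0))
        node.left = tree_from_dict(d["left"])
        node.right = tree_from_dict(d["right"])
    return node


def save_model(model: TreeNode | Forest, path) -> None:
    """Serialize a tree or forest to a JSON file."""
    if isinstance(model, Forest):
        payload = {
            "kind": "forest",
            "n_trees": model.n_trees,
            "mtry": model.mtry,
            "seed": model.seed,
            "bootstrap": model.bootstrap,
            "classes": list(model.classes),
            "feature_names": list(model.feature_names),
            "trees": [tree_to_dict(t) for t in model.trees],
        }
    else:
        payload = {"kind": "tree", "root": tree_to_dict(model)}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path) -> TreeNode | Forest:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload["kind"] == "forest":
        return Forest(
            trees=[tree_from_dict(t) for t in payload["trees"]],
            n_trees=int(payload["n_trees"]),
            mtry=int(payload["mtry"]),
            seed=int(payload["seed"]),
            bootstrap=bool(payload["bootstrap"]),
            classes=tuple(payload["classes"]),
            feature_names=tuple(payload["feature_names"]),
        )
    return tree_from_dict(payload["root"])


# -- estimator-style wrappers for the evaluation harness ---------------------

class CartClassifier:
    """Single CART tree with a scikit-learn-like fit/predict surface."""

    def __init__(self, max_depth=None, min_leaf_size=1, seed=0):
        self.params = TreeParams(max_depth=max_depth, min_leaf_size=min_leaf_size)
        self.seed = seed
        self.tree_: TreeNode | None = None
        self.feature_names_: tuple[str, ...] | None = None

    def fit(self, X, y):
        arr, names = _as_matrix(X)
        self.feature_names_ = names
        self.tree_ = grow_tree(
            arr, y, self.params, np.random.default_rng(self.seed), names
        )
        return self

    def predict(self, X):
        if isinstance(X, pd.DataFrame):
            X = X.rename(columns=str)[list(self.feature_names_)]
        return predict(self.tree_, X, self.feature_names_)


class RandomForestClassifier:
    """Bagged CART forest with a scikit-learn-like fit/predict surface."""

    def __init__(self, n_trees=500, max_depth=None, min_leaf_size=1, mtry=None, seed=0):
        self.n_trees = n_trees
        self.params = TreeParams(max_depth=max_depth, min_leaf_size=min_leaf_size, mtry=mtry)
        self.seed = seed
        self.forest_: Forest | None = None

    def fit(self, X, y):
        self.forest_ = grow_forest(
            X, y, n_trees=self.n_trees, params=self.params, seed=self.seed
        )
        return self

    def predict(self, X):
        return predict(self.forest_, X)
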