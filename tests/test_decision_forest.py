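"""CART and random-forest mechanics: splits, growth, voting, importance."""

import numpy as np
import pandas as pd
import pytest

from phenotax.decision_forest import (
    Forest,
    TreeParams,
    best_split,
    feature_importance,
    gini_impurity,
    grow_forest,
    grow_tree,
    load_model,
    predict,
    representative_tree,
    save_model,
)
from phenotax.synthetic_data import planted_rule_dataset, planted_threshold_dataset


class TestGini:
    @pytest.mark.parametrize(
        "counts, expected",
        [({"a": 10, "b": 0}, 0.0), ({"a": 5, "b": 5}, 0.5), ({"a": 2, "b": 2, "c": 2}, 2 / 3)],
    )
    def test_known_values(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_matches_brute_force_on_random_counts(self, rng):
        for _ in range(100):
            counts = rng.integers(0, 20, size=rng.integers(2, 6))
            if counts.sum() == 0:
                continue
            p = counts / counts.sum()
            assert gini_impurity(counts.tolist()) == pytest.approx(1 - (p**2).sum())

    def test_empty_node_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            gini_impurity({"a": 0, "b": 0})


def brute_force_best_threshold(v, y):
    """Scan every midpoint of one feature and return the best (decrease, threshold)."""
    order = np.argsort(v)
    vs, ys = v[order], y[order]
    n = len(vs)
    parent = gini_impurity(np.unique(ys, return_counts=True)[1].tolist())
    best = None
    for i in range(n - 1):
        if vs[i + 1] <= vs[i]:
            continue
        thr = (vs[i] + vs[i + 1]) / 2
        left, right = ys[: i + 1], ys[i + 1 :]
        gl = gini_impurity(np.unique(left, return_counts=True)[1].tolist())
        gr = gini_impurity(np.unique(right, return_counts=True)[1].tolist())
        dec = parent - (len(left) * gl + len(right) * gr) / n
        if best is None or dec > best[0]:
            best = (dec, thr)
    return best


class TestBestSplit:
    def test_four_point_midpoint(self):
        X = np.array([[0.1], [0.1], [0.9], [0.9]])
        y = np.array(["A", "A", "B", "B"])
        feature, threshold, decrease = best_split(X, y)
        assert threshold == pytest.approx(0.5)
        assert decrease == pytest.approx(0.5)

    def test_pure_labels_give_no_split(self):
        X = np.array([[0.1], [0.5], [0.9]])
        assert best_split(X, np.array(["A", "A", "A"])) is None

    def test_matches_exhaustive_scan_on_random_data(self, rng):
        for _ in range(25):
            v = rng.uniform(size=30)
            y = rng.choice(["A", "B", "C"], size=30)
            result = best_split(v.reshape(-1, 1), y)
            oracle = brute_force_best_threshold(v, y)
            if oracle is None or oracle[0] <= 1e-15:
                assert result is None
            else:
                assert result[1] == pytest.approx(oracle[1])
                assert result[2] == pytest.approx(oracle[0])

    def test_selects_planted_feature_among_noise(self):
        X, y = planted_threshold_dataset(400, cut=0.21, noise_features=5, seed=9)
        feature, threshold, _ = best_split(X, y)
        assert feature == "coumaryl"
        assert abs(threshold - 0.21) < 0.02


class TestGrowTree:
    def test_pure_input_gives_single_leaf(self):
        tree = grow_tree(np.random.default_rng(0).uniform(size=(8, 3)), ["A"] * 8)
        assert tree.is_leaf
        assert tree.class_counts == {"A": 8}

    def test_separable_set_gives_depth_one_tree(self):
        X = np.array([[0.1], [0.1], [0.9], [0.9]])
        y = np.array(["A", "A", "B", "B"])
        tree = grow_tree(X, y)
        assert tree.depth() == 1
        assert tree.threshold == pytest.approx(0.5)

    def test_perfect_training_accuracy_on_distinct_rows(self, rng):
        X = rng.uniform(size=(60, 4))
        y = rng.choice(["A", "B", "C"], size=60)
        tree = grow_tree(X, y)
        assert (predict(tree, X) == y).all()

    def test_min_leaf_size_respected(self, rng):
        X = rng.uniform(size=(50, 3))
        y = rng.choice(["A", "B"], size=50)
        tree = grow_tree(X, y, TreeParams(min_leaf_size=7))

        def check(node):
            if node.is_leaf:
                assert node.n_samples >= 7
            else:
                check(node.left)
                check(node.right)

        check(tree)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            grow_tree(np.empty((0, 2)), [])


class TestForest:
    def test_same_seed_identical_predictions(self):
        X, y = planted_rule_dataset(80, seed=4)
        f1 = grow_forest(X, y, n_trees=25, seed=11)
        f2 = grow_forest(X, y, n_trees=25, seed=11)
        assert (predict(f1, X) == predict(f2, X)).all()

    def test_degenerate_ensemble_equals_single_tree(self, rng):
        X = rng.uniform(size=(40, 3))
        y = rng.choice(["A", "B"], size=40)
        params = TreeParams(mtry=3)
        forest = grow_forest(X, y, n_trees=1, params=params, seed=0, bootstrap=False)
        tree = grow_tree(X, y, TreeParams(), np.random.default_rng(0))
        assert (predict(forest, X) == predict(tree, X)).all()

    def test_majority_vote_beats_noise_on_planted_signal(self):
        X, y = planted_rule_dataset(150, seed=6)
        forest = grow_forest(X, y, n_trees=100, seed=6)
        assert (predict(forest, X) == y).mean() >= 0.95

    def test_prediction_invariant_to_feature_column_order(self):
        X, y = planted_rule_dataset(100, seed=2)
        forest = grow_forest(X, y, n_trees=30, seed=2)
        shuffled = X[list(reversed(X.columns))]
        assert (predict(forest, shuffled) == predict(forest, X)).all()

    def test_unknown_feature_rejected(self):
        X, y = planted_rule_dataset(50, seed=1)
        forest = grow_forest(X, y, n_trees=5, seed=1)
        bad = X.rename(columns={"coumaryl": "mystery"})
        with pytest.raises(ValueError, match="mystery|missing"):
            predict(forest, bad)


class TestImportance:
    def test_sums_to_one_and_covers_features(self):
        X, y = planted_rule_dataset(150, seed=3)
        forest = grow_forest(X, y, n_trees=60, seed=3)
        ranking = feature_importance(forest)
        names = [f for f, _ in ranking]
        values = [v for _, v in ranking]
        assert set(names) == set(X.columns)
        assert sum(values) == pytest.approx(1.0, abs=1e-9)
        assert all(values[i] >= values[i + 1] for i in range(len(values) - 1))

    def test_single_informative_feature_ranks_first(self):
        X, y = planted_threshold_dataset(300, cut=0.21, noise_features=5, seed=8)
        forest = grow_forest(X, y, n_trees=100, seed=8)
        assert feature_importance(forest)[0][0] == "coumaryl"

    def test_all_noise_features_have_no_stable_winner(self, rng):
        winners = set()
        for seed in range(6):
            X = pd.DataFrame(
                np.random.default_rng(seed).uniform(size=(120, 4)),
                columns=["w", "x", "y", "z"],
            )
            y = np.random.default_rng(seed + 100).choice(["A", "B"], size=120)
            forest = grow_forest(X, y, n_trees=40, seed=seed)
            winners.add(feature_importance(forest)[0][0])
        assert len(winners) > 1


class TestRepresentativeTree:
    def test_identical_trees_give_first_member(self, rng):
        X = rng.uniform(size=(30, 2))
        y = rng.choice(["A", "B"], size=30)
        forest = grow_forest(X, y, n_trees=5, params=TreeParams(mtry=2), seed=0, bootstrap=False)
        rep = representative_tree(forest, X)
        assert rep is forest.trees[0]

    def test_agreement_is_maximal(self):
        X, y = planted_rule_dataset(120, seed=5)
        forest = grow_forest(X, y, n_trees=30, seed=5)
        ensemble = predict(forest, X)
        rep = representative_tree(forest, X)
        rep_agreement = (predict(rep, X, forest.feature_names) == ensemble).mean()
        for tree in forest.trees:
            agreement = (predict(tree, X, forest.feature_names) == ensemble).mean()
            assert rep_agreement >= agreement


class TestSerialization:
    def test_forest_round_trip(self, tmp_path):
        X, y = planted_rule_dataset(60, seed=7)
        forest = grow_forest(X, y, n_trees=10, seed=7)
        path = tmp_path / "forest.json"
        save_model(forest, path)
        back = load_model(path)
        assert isinstance(back, Forest)
        assert back.feature_names == forest.feature_names
        assert (predict(back, X) == predict(forest, X)).all()
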