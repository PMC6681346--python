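"""Replicated train/test evaluation, cross-validation and cluster-recovery
scoring for the chemotaxonomic classifiers.

The harness mirrors the small-n study design it serves: stratified splits
over a grid of training fractions with a handful of replications per cell,
accuracy and F1 (positive class *Erica* by default) per cell, and
stratified k-fold cross-validation.  Splits are shared across algorithms
within a (fraction, replicate) cell so algorithm comparisons are paired.

Stratified splitting uses largest-remainder rounding of the per-class
quotas toward a total of ceil(fraction * n) training samples; a 2/3 split
of 47 binary-labelled samples therefore trains on exactly 32.  Singleton
classes cannot be stratified and always go to the training side.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import comb

__all__ = [
    "SplitSpec",
    "EvalReport",
    "CrossValResult",
    "split_train_test",
    "accuracy",
    "f1_score",
    "adjusted_rand_index",
    "compare_algorithms",
    "cross_validate",
    "default_algorithms",
]

DEFAULT_FRACTIONS = (0.5, 0.6, 2.0 / 3.0, 0.8)
DEFAULT_REPLICATIONS = 5
DEFAULT_POSITIVE_CLASS = "Erica"


@dataclass(frozen=True)
class SplitSpec:
    """One train/test split request."""

    train_fraction: float
    replicate_index: int = 0
    seed: int = 0
    stratified: bool = True


@dataclass
class EvalReport:
    """Per-cell records and mean +/- sd summary of an algorithm comparison.

    ``records`` has one row per (algorithm, train_fraction, replicate) with
    accuracy and f1; failed cells carry NaN scores and a reason.
    ``summary`` aggregates mean and sd per (algorithm, train_fraction).
    """

    records: pd.DataFrame
    summary: pd.DataFrame


@dataclass
class CrossValResult:
    """Stratified k-fold cross-validation scores."""

    fold_accuracy: list[float]
    fold_f1: list[float]

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def sd_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy, ddof=1)) if len(self.fold_accuracy) > 1 else 0.0

    @property
    def mean_f1(self) -> float:
        return float(np.mean(self.fold_f1))

    @property
    def sd_f1(self) -> float:
        return float(np.std(self.fold_f1, ddof=1)) if len(self.fold_f1) > 1 else 0.0


def _derive_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=tuple(key))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def split_train_test(labels, spec: SplitSpec):
    """Stratified (or plain) train/test split of sample indices.

    Returns sorted ``(train_indices, test_indices)`` partitioning
    ``range(n)``.  The training side targets ceil(train_fraction * n)
    samples; under stratification per-class quotas are rounded by largest
    remainder and every class present keeps at least one training sample.
    A singleton class is assigned to training with a warning.
    """
    labels = np.asarray([str(v) for v in np.asarray(labels)])
    n = labels.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not (0.0 < spec.train_fraction < 1.0):
        raise ValueError(f"train_fraction {spec.train_fraction} outside (0, 1)")
    n_train = math.ceil(spec.train_fraction * n)
    if n_train >= n:
        raise ValueError(
            f"train_fraction {spec.train_fraction} leaves no test samples (n={n})"
        )
    rng = np.random.default_rng(_derive_seed(spec.seed, spec.replicate_index))
    if not spec.stratified:
        perm = rng.permutation(n)
        train = np.sort(perm[:n_train])
        test = np.sort(perm[n_train:])
        return train, test

    classes = sorted(set(labels.tolist()))
    quotas: dict[str, int] = {}
    remainders: list[tuple[float, str]] = []
    for c in classes:
        n_c = int((labels == c).sum())
        if n_c == 1:
            warnings.warn(
                f"class {c!r} has a single sample; assigned to training "
                "(cannot stratify a singleton)",
                stacklevel=2,
            )
            quotas[c] = 1
            continue
        q = spec.train_fraction * n_c
        quotas[c] = max(1, int(math.floor(q)))
        remainders.append((q - math.floor(q), c))
    # distribute the remaining train slots by largest remainder
    short = n_train - sum(quotas.values())
    for _, c in sorted(remainders, key=lambda t: (-t[0], t[1])):
        if short <= 0:
            break
        n_c = int((labels == c).sum())
        if quotas[c] < n_c - 1:  # keep >=1 test sample per stratifiable class
            quotas[c] += 1
            short -= 1
    train_parts = []
    for c in classes:
        members = np.nonzero(labels == c)[0]
        members = rng.permutation(members)
        train_parts.append(members[: quotas[c]])
    train = np.sort(np.concatenate(train_parts))
    mask = np.ones(n, dtype=bool)
    mask[train] = False
    test = np.nonzero(mask)[0]
    if test.shape[0] == 0:
        raise ValueError("split left no test samples")
    return train, test


def accuracy(true_labels, predicted_labels) -> float:
    """Fraction of exact label matches."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    if t.shape[0] == 0:
        raise ValueError("empty label vectors")
    return float((t.astype(str) == p.astype(str)).mean())


def f1_score(
    true_labels, predicted_labels, positive_class: str = DEFAULT_POSITIVE_CLASS
) -> float:
    """Binary F1 = 2 P R / (P + R) for the given positive class.

    Degenerate case: when precision + recall is 0 (no true and no
    predicted positives, or nothing retrieved correctly) the score is 0 by
    convention, with a warning when the case is vacuous.
    """
    t = np.asarray(true_labels).astype(str)
    p = np.asarray(predicted_labels).astype(str)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: {t.shape} vs {p.shape}")
    pos = str(positive_class)
    tp = int(((t == pos) & (p == pos)).sum())
    fp = int(((t != pos) & (p == pos)).sum())
    fn = int(((t == pos) & (p != pos)).sum())
    if tp == 0:
        if fp == 0 and fn == 0:
            warnings.warn(
                f"no true or predicted {pos!r} samples; F1 reported as 0 by convention",
                stacklevel=2,
            )
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    return float(2 * precision * recall / (precision + recall))


def adjusted_rand_index(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two partitions of the same items.

    Pair-counting form: ARI = (sum_ij C(n_ij,2) - E) / (max - E) with the
    usual expectation under the permutation model.  1 for identical
    partitions (up to relabelling), ~0 for independent ones.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("partitions must label the same items")
    n = a.shape[0]
    table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
    sum_cells = comb(table, 2).sum()
    sum_rows = comb(table.sum(axis=1), 2).sum()
    sum_cols = comb(table.sum(axis=0), 2).sum()
    total = comb(n, 2)
    expected = sum_rows * sum_cols / total if total > 0 else 0.0
    max_index = (sum_rows + sum_cols) / 2.0
    if max_index == expected:
        return 1.0
    return float((sum_cells - expected) / (max_index - expected))


def compare_algorithms(
    X,
    y,
    algorithms: Mapping[str, Callable[[int], object]],
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    n_replications: int = DEFAULT_REPLICATIONS,
    seed: int = 0,
    positive_class: str = DEFAULT_POSITIVE_CLASS,
    stratified: bool = True,
) -> EvalReport:
    """Replicated paired comparison of classifier factories.

    ``algorithms`` maps a name to a factory ``factory(seed) -> estimator``
    with ``fit(X, y)`` and ``predict(X)``.  Each (fraction, replicate) cell
    draws one stratified split shared by all algorithms; per-cell seeds are
    derived deterministically from ``seed``.  Failures are recorded (NaN
    scores plus the reason), not raised.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    y = np.asarray([str(v) for v in np.asarray(y)])
    X_frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    records = []
    for fi, fraction in enumerate(fractions):
        for rep in range(n_replications):
            split_seed = _derive_seed(seed, 0, fi, rep)
            train, test = split_train_test(
                y, SplitSpec(fraction, replicate_index=rep, seed=split_seed, stratified=stratified)
            )
            for ai, (name, factory) in enumerate(algorithms.items()):
                algo_seed = _derive_seed(seed, 1, fi, rep, ai)
                record = {
                    "algorithm": name,
                    "train_fraction": fraction,
                    "replicate": rep,
                    "n_train": int(train.shape[0]),
                    "n_test": int(test.shape[0]),
                    "accuracy": np.nan,
                    "f1": np.nan,
                    "error": "",
                }
                try:
                    model = factory(algo_seed)
                    model.fit(X_frame.iloc[train], y[train])
                    pred = model.predict(X_frame.iloc[test])
                    record["accuracy"] = accuracy(y[test], pred)
                    record["f1"] = f1_score(y[test], pred, positive_class)
                except Exception as exc:  # recorded, not raised
                    record["error"] = f"{type(exc).__name__}: {exc}"
                records.append(record)
    frame = pd.DataFrame.from_records(records)
    summary = (
        frame.groupby(["algorithm", "train_fraction"], sort=False)
        .agg(
            mean_accuracy=("accuracy", "mean"),
            sd_accuracy=("accuracy", "std"),
            mean_f1=("f1", "mean"),
            sd_f1=("f1", "std"),
            n_failed=("error", lambda e: int((e != "").sum())),
        )
        .reset_index()
    )
    return EvalReport(records=frame, summary=summary)


def _stratified_folds(labels, n_folds: int, rng) -> list[np.ndarray]:
    """Stratified fold assignment; fold sizes differ by at most one."""
    labels = np.asarray(labels)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for c in sorted(set(labels.tolist())):
        members = rng.permutation(np.nonzero(labels == c)[0])
        for idx in members:
            # deal each sample to the currently smallest fold (stable order)
            target = min(range(n_folds), key=lambda f: (len(folds[f]), f))
            folds[target].append(int(idx))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(
    X,
    y,
    factory: Callable[[int], object],
    n_folds: int = 5,
    seed: int = 0,
    positive_class: str = DEFAULT_POSITIVE_CLASS,
) -> CrossValResult:
    """Stratified k-fold cross-validation of one classifier factory.

    Every sample is tested exactly once; folds are seed-reproducible and
    their sizes differ by at most one.
    """
    y = np.asarray([str(v) for v in np.asarray(y)])
    n = y.shape[0]
    if not (2 <= n_folds <= n):
        raise ValueError(f"n_folds={n_folds} must be in [2, n={n}]")
    X_frame = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, dtype=float))
    rng = np.random.default_rng(_derive_seed(seed, 2))
    folds = _stratified_folds(y, n_folds, rng)
    accs: list[float] = []
    f1s: list[float] = []
    for k, test in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test] = False
        train = np.nonzero(mask)[0]
        model = factory(_derive_seed(seed, 3, k))
        model.fit(X_frame.iloc[train], y[train])
        pred = model.predict(X_frame.iloc[test])
        accs.append(accuracy(y[test], pred))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f1s.append(f1_score(y[test], pred, positive_class))
    return CrossValResult(fold_accuracy=accs, fold_f1=f1s)


def default_algorithms(n_trees: int = 200, max_depth: int | None = None):
    """Named classifier factories for the standard comparison.

    Always includes the package's own random forest and single CART tree
    ("recursive partitioning"); adds a support-vector machine backed by
    scikit-learn when that backend is importable.
    """
    from .decision_forest import CartClassifier, RandomForestClassifier

    algorithms: dict[str, Callable[[int], object]] = {
        "random_forest": lambda seed: RandomForestClassifier(
            n_trees=n_trees, max_depth=max_depth, seed=seed
        ),
        "recursive_partitioning": lambda seed: CartClassifier(
            max_depth=max_depth, seed=seed
        ),
    }
    try:  # optional external backend
        from sklearn.svm import SVC

        algorithms["svm"] = lambda seed: SVC(kernel="rbf", random_state=seed)
    except ImportError:
        pass
    return algorithms
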