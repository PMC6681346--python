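"""Rule-based *Erica* identification, Z-score normalization, Ward/Euclidean
hierarchical clustering and PCA.

The explicit biomarker rule flags a sample as *Erica* when its relative
coumaryl phenol contribution exceeds 0.20 (strictly) and its relative
benzoic acid contribution lies in the closed interval [0.05, 0.12].  Both
inputs are fractions of the total phenol content, so the rule is invariant
to overall phenol abundance.

Clustering follows the standard chemometric recipe: Z-score each feature
(n-1 denominator), Euclidean distances, Ward minimum-variance linkage, cut
the dendrogram at k groups.  Merge heights are reported as Ward cost
increments (the increase in total within-cluster sum of squares caused by
each merge).  PCA is computed by singular-value decomposition of the
centered matrix with a deterministic sign convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from .features import RelativeGroupAbundances, recovery_correct
from .registry_io import CompoundRegistry, Dataset, default_registry

__all__ = [
    "COUMARYL_THRESHOLD",
    "BENZOIC_RANGE",
    "RuleResult",
    "ClusterResult",
    "classify_erica_rule",
    "zscore_normalize",
    "ward_cluster",
    "cluster_feature_matrix",
    "pca",
]

#: Relative coumaryl contribution above which the rule may fire (strict).
COUMARYL_THRESHOLD = 0.20
#: Closed interval of relative benzoic-acid contribution for the rule.
BENZOIC_RANGE = (0.05, 0.12)


@dataclass(frozen=True)
class RuleResult:
    """Outcome of the two-condition *Erica* biomarker rule for one sample."""

    is_erica: bool
    coumaryl_pass: bool
    benzoic_pass: bool
    coumaryl_value: float
    benzoic_value: float


@dataclass
class ClusterResult:
    """Agglomerative clustering outcome.

    ``labels`` assigns each sample a group index in 1..k.  ``merge_history``
    is an (n-1, 3) array of (cluster_a, cluster_b, height) rows in scipy
    linkage convention (original samples 0..n-1, the i-th merge creating
    cluster n+i); heights are Ward cost increments and non-decreasing.
    """

    labels: np.ndarray
    merge_history: np.ndarray
    k: int


def classify_erica_rule(
    rel: RelativeGroupAbundances | Mapping[str, float],
    coumaryl_threshold: float = COUMARYL_THRESHOLD,
    benzoic_range: tuple[float, float] = BENZOIC_RANGE,
) -> RuleResult:
    """Apply the coumaryl/benzoic biomarker rule to one sample.

    Accepts a :class:`RelativeGroupAbundances` or any mapping with
    ``coumaryl`` and ``benzoic`` fractions.  The coumaryl condition is a
    strict inequality; the benzoic condition is a closed interval, so
    boundary values are reported as passes there.
    """
    if isinstance(rel, RelativeGroupAbundances):
        coumaryl = rel.coumaryl
        benzoic = rel.benzoic
    else:
        coumaryl = float(rel["coumaryl"])
        benzoic = float(rel["benzoic"])
    lo, hi = benzoic_range
    coumaryl_pass = coumaryl > coumaryl_threshold
    benzoic_pass = lo <= benzoic <= hi
    return RuleResult(
        is_erica=coumaryl_pass and benzoic_pass,
        coumaryl_pass=coumaryl_pass,
        benzoic_pass=benzoic_pass,
        coumaryl_value=coumaryl,
        benzoic_value=benzoic,
    )


def zscore_normalize(matrix):
    """Column-wise Z-score: Z = (X - mean(X)) / sd(X), sample sd (n-1).

    Constant columns have no scale and are mapped to all-zeros with a
    warning.  DataFrames come back as DataFrames with the same labels.
    """
    is_frame = isinstance(matrix, pd.DataFrame)
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    if X.shape[0] < 2:
        raise ValueError("Z-score normalization needs at least 2 samples")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant column(s) mapped to zeros",
            stacklevel=2,
        )
    safe_sd = np.where(constant, 1.0, sd)
    Z = (X - mean) / safe_sd
    Z[:, constant] = 0.0
    if is_frame:
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z


def ward_cluster(matrix, k: int) -> ClusterResult:
    """Ward minimum-variance agglomerative clustering cut at k groups.

    Operates on the matrix as given (callers normalize first).  Heights in
    the merge history are Ward cost increments, i.e. the growth of the
    total within-cluster sum of squares at each merge; they are
    non-decreasing along the agglomeration.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    n = X.shape[0]
    if not (1 <= k <= n):
        raise ValueError(f"k={k} must be between 1 and n={n}")
    Z = linkage(X, method="ward")
    labels = fcluster(Z, t=k, criterion="maxclust")
    # scipy's ward heights are sqrt(2 * delta ESS); report the ESS increment.
    merge_history = np.column_stack([Z[:, 0], Z[:, 1], Z[:, 2] ** 2 / 2.0])
    return ClusterResult(labels=np.asarray(labels), merge_history=merge_history, k=k)


def cluster_feature_matrix(
    dataset: Dataset,
    registry: CompoundRegistry | None = None,
    level: str = "compounds",
    correct_recovery: bool = True,
) -> pd.DataFrame:
    """Z-scored feature matrix for clustering a dataset.

    ``level="compounds"`` uses the sixteen absolute contents (g kg^-1 TOC);
    ``level="groups"`` uses the six group sums instead.
    """
    from .features import group_sums

    registry = registry or default_registry()
    profiles = [
        recovery_correct(s) if (correct_recovery and s.recovery is not None) else s
        for s in dataset
    ]
    ids = [s.sample_id for s in profiles]
    if level == "compounds":
        frame = pd.DataFrame(
            [[p.contents[c] for c in registry.compounds] for p in profiles],
            index=ids,
            columns=list(registry.compounds),
        )
    elif level == "groups":
        frame = pd.DataFrame(
            [group_sums(p, registry).as_dict() for p in profiles], index=ids
        )
    else:
        raise ValueError(f"unknown feature level {level!r}")
    return zscore_normalize(frame)


def pca(matrix, n_components: int):
    """Principal component analysis by SVD of the centered matrix.

    Returns ``(scores, loadings, explained_variance_fractions)`` where
    ``loadings`` has orthonormal columns, fractions are non-increasing and
    sum to at most 1, and each component's largest-magnitude loading entry
    is positive (deterministic sign convention).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D samples x features matrix")
    n, p = X.shape
    if not (1 <= n_components <= min(n - 1, p)):
        raise ValueError(
            f"n_components={n_components} must be in [1, min(n-1, p)] = "
            f"[1, {min(n - 1, p)}]"
        )
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total_var = float((s**2).sum())
    if total_var == 0:
        raise ValueError("degenerate input: all rows identical (zero variance)")
    loadings = Vt[:n_components].T  # (p, k), orthonormal columns
    scores = U[:, :n_components] * s[:n_components]
    # Sign convention: flip each component so its largest |loading| is positive.
    for j in range(n_components):
        i = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[i, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    fractions = (s[:n_components] ** 2) / total_var
    return scores, loadings, fractions
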