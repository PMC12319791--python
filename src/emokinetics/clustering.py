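"""Cross-run spatial similarity of emotion responses and hierarchical
clustering.

The spatial response pattern of an emotion (its Fisher-z correlation map
over ROIs, averaged over participants and runs in a run set) is compared
between the training and held-out runs of every cross-validation split:
entry (i, j) of the similarity matrix is the across-ROI Pearson correlation
of train-pattern i with test-pattern j, averaged over the 10 splits.
Computing the similarity strictly across non-overlapping run sets avoids
the circularity of within-run comparisons, and the diagonal is the
between-run reliability of each emotion's pattern (not forced to 1).  The
same average-linkage (UPGMA) clustering with optimal leaf ordering and a
70 %-of-maximum-linkage cutoff serves both this neural matrix and the
rating-space correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, ClusterMixin

from .config import ValidationError
from .fitting import enumerate_run_splits
from .mapping import fisher_z

__all__ = [
    "SimilarityStructure", "emotion_pattern", "cross_run_similarity",
    "cross_run_beta_similarity", "beta_patterns", "rating_similarity",
    "generalized_dice", "hcluster", "cluster_cut", "EmotionClusterer",
]


def emotion_pattern(r: np.ndarray, runs: list[str],
                    run_set: tuple[str, ...],
                    use_fisher_z: bool = True) -> np.ndarray:
    """Group-mean response pattern per condition within a run set.

    ``r`` is the (participant x ROI x emotion x run) correlation tensor;
    the pattern is the mean over participants and the selected runs of the
    Fisher-z correlations, giving an (emotion x ROI) matrix.
    """
    if len(run_set) == 0:
        raise ValidationError("empty run set")
    idx = [runs.index(x) for x in run_set]
    z = fisher_z(r) if use_fisher_z else r
    return z[:, :, :, idx].mean(axis=(0, 3)).T           # emotion x ROI


def _corr_rows(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Row-by-row correlation matrix: out[i, j] = corr(A[i], B[j])."""
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    sa = np.sqrt((Ac ** 2).sum(axis=1))
    sb = np.sqrt((Bc ** 2).sum(axis=1))
    if (sa == 0).any() or (sb == 0).any():
        raise ValidationError(
            "constant pattern(s): similarity undefined for rows "
            f"{list(np.flatnonzero(sa == 0))} / {list(np.flatnonzero(sb == 0))}"
        )
    return (Ac @ Bc.T) / np.outer(sa, sb)


def cross_run_similarity(r: np.ndarray, runs: list[str], n_train: int,
                         conditions: list[str],
                         use_fisher_z: bool = True
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train-vs-test spatial similarity averaged over run splits.

    Returns the symmetrised matrix ((M + M.T) / 2) and the raw asymmetric
    average; the diagonal is the between-run pattern reliability.
    """
    splits = enumerate_run_splits(runs, n_train)
    acc = np.zeros((len(conditions), len(conditions)))
    for split in splits:
        pat_train = emotion_pattern(r, runs, split.train, use_fisher_z)
        pat_test = emotion_pattern(r, runs, split.test, use_fisher_z)
        acc += _corr_rows(pat_train, pat_test)
    raw = acc / len(splits)
    sym = (raw + raw.T) / 2.0
    return (pd.DataFrame(sym, index=conditions, columns=conditions),
            pd.DataFrame(raw, index=conditions, columns=conditions))


def beta_patterns(dataset, designs: dict, run_set: tuple[str, ...]
                  ) -> np.ndarray:
    """Emotion x ROI response patterns from a full-model OLS fit.

    Unlike single-regressor correlation maps, the joint fit unmixes the
    temporal correlation between emotion regressors, so the pattern of an
    emotion reflects its own response weights only.
    """
    from .fitting import LinearEncodingModel, _design_matrix, _stack_runs

    z, _ = _stack_runs(dataset, tuple(run_set))
    Y = z.mean(axis=0)
    Y = Y - Y.mean(axis=0)
    X = _design_matrix(designs, tuple(run_set))
    return LinearEncodingModel().fit(X, Y).coef_


def cross_run_beta_similarity(dataset, designs: dict, n_train: int
                              ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Train-vs-test similarity of full-model beta patterns (the
    beta-pattern variant of :func:`cross_run_similarity`)."""
    runs = dataset.runs
    conditions = designs[runs[0]].emotions
    splits = enumerate_run_splits(runs, n_train)
    acc = np.zeros((len(conditions), len(conditions)))
    for split in splits:
        pat_train = beta_patterns(dataset, designs, split.train)
        pat_test = beta_patterns(dataset, designs, split.test)
        acc += _corr_rows(pat_train, pat_test)
    raw = acc / len(splits)
    sym = (raw + raw.T) / 2.0
    return (pd.DataFrame(sym, index=conditions, columns=conditions),
            pd.DataFrame(raw, index=conditions, columns=conditions))


def rating_similarity(designs: dict, emotions: list[str],
                      tasks: tuple[str, ...] = ("perceived", "felt")
                      ) -> pd.DataFrame:
    """Temporal correlation matrix of emotion model time series.

    Regressors are concatenated across runs per (emotion, task) condition;
    entry (i, j) is the Pearson correlation of the two concatenated series.
    Used for the rating-space clustering alongside the neural one.
    """
    runs = sorted({run for run, _ in designs})
    cols = {}
    for task in tasks:
        mats = [designs[(run, task)].matrix[emotions].to_numpy()
                for run in runs]
        stacked = np.concatenate(mats, axis=0)
        for e, emo in enumerate(emotions):
            cols[f"{emo}:{task}"] = stacked[:, e]
    frame = pd.DataFrame(cols)
    return frame.corr()


def generalized_dice(mask_a, mask_b) -> float:
    """Two-sided Dice overlap of signed {-1, 0, +1} maps.

    2 * (|P_a & P_b| + |N_a & N_b|) / (|P_a| + |P_b| + |N_a| + |N_b|);
    defined as 0 when both maps are empty.
    """
    a = np.asarray(mask_a)
    b = np.asarray(mask_b)
    if a.shape != b.shape:
        raise ValidationError("masks must share their ROI set")
    for m in (a, b):
        if not np.isin(m, (-1, 0, 1)).all():
            raise ValidationError("masks must be ternary {-1, 0, +1}")
    pos = int(((a == 1) & (b == 1)).sum())
    neg = int(((a == -1) & (b == -1)).sum())
    denom = int((a == 1).sum() + (b == 1).sum()
                + (a == -1).sum() + (b == -1).sum())
    if denom == 0:
        return 0.0
    return 2.0 * (pos + neg) / denom


def dice_similarity_matrix(masks: pd.DataFrame) -> pd.DataFrame:
    """Pairwise generalized Dice between the columns of a signed mask."""
    cols = list(masks.columns)
    out = np.zeros((len(cols), len(cols)))
    for i, ci in enumerate(cols):
        for j, cj in enumerate(cols):
            out[i, j] = generalized_dice(masks[ci], masks[cj])
    return pd.DataFrame(out, index=cols, columns=cols)


def hcluster(similarity: pd.DataFrame) -> tuple[np.ndarray, list[int]]:
    """Average-linkage (UPGMA) clustering with optimal leaf ordering.

    Distance is d = 1 - similarity.  Returns the scipy linkage matrix and
    the leaf order that maximises the sum of adjacent-leaf similarities
    subject to the tree.
    """
    sim = np.asarray(similarity, dtype=float)
    if np.isnan(sim).any():
        bad = sorted({similarity.index[i]
                      for i in np.unique(np.argwhere(np.isnan(sim)))})
        raise ValidationError(f"NaN similarity entries for {bad}")
    if sim.shape[0] != sim.shape[1] or not np.allclose(sim, sim.T,
                                                       atol=1e-10):
        raise ValidationError("similarity matrix must be square symmetric")
    dist = 1.0 - sim
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    Z = hierarchy.linkage(condensed, method="average")
    Z = hierarchy.optimal_leaf_ordering(Z, condensed)
    order = list(hierarchy.leaves_list(Z))
    return Z, order


def cluster_cut(Z: np.ndarray, fraction: float,
                n_leaves: int | None = None) -> np.ndarray:
    """Cut the tree at ``fraction`` of the maximum merge height.

    Merges strictly below the cut are applied (MATLAB dendrogram
    convention: a merge at exactly the cut height is excluded).  Clusters
    with a single member are labelled 0 ("unclustered"); multi-member
    clusters get labels 1..k in leaf order of their lowest-index member.
    """
    if not (0 < fraction <= 1):
        raise ValidationError("fraction must lie in (0, 1]")
    Z = np.asarray(Z, dtype=float)
    if n_leaves is None:
        n_leaves = Z.shape[0] + 1
    cutoff = fraction * Z[:, 2].max() if Z.shape[0] else 0.0
    parent = list(range(2 * n_leaves - 1))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for m in range(Z.shape[0]):
        if Z[m, 2] < cutoff:
            a, b = find(int(Z[m, 0])), find(int(Z[m, 1]))
            parent[a] = parent[b] = n_leaves + m
    groups: dict[int, list[int]] = {}
    for leaf in range(n_leaves):
        groups.setdefault(find(leaf), []).append(leaf)
    labels = np.zeros(n_leaves, dtype=int)
    next_label = 1
    for root in sorted(groups, key=lambda g: min(groups[g])):
        members = groups[root]
        if len(members) > 1:
            labels[members] = next_label
            next_label += 1
    return labels


@dataclass
class SimilarityStructure:
    """A similarity matrix with its dendrogram and cluster assignment."""

    conditions: list[str]
    matrix: pd.DataFrame
    linkage: np.ndarray
    leaf_order: list[int]
    labels: pd.Series
    asymmetric: pd.DataFrame | None = None
    cutoff_fraction: float = 0.70

    @property
    def reliability(self) -> pd.Series:
        return pd.Series(np.diag(self.matrix.to_numpy()),
                         index=self.conditions)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max())

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage)

        def rec(node):
            if node.is_leaf():
                return str(self.conditions[node.id])
            return (f"({rec(node.left)}:{node.dist - node.left.dist:.6g},"
                    f"{rec(node.right)}:{node.dist - node.right.dist:.6g})")

        return rec(tree) + ";"


class EmotionClusterer(BaseEstimator, ClusterMixin):
    """UPGMA clustering of a condition x condition similarity matrix.

    Fit attributes: ``linkage_``, ``leaf_order_``, ``labels_`` (0 marks
    unclustered singletons at the cutoff).
    """

    def __init__(self, cutoff_fraction: float = 0.70):
        self.cutoff_fraction = cutoff_fraction

    def fit(self, X, y=None):
        sim = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X))
        self.conditions_ = list(sim.columns)
        self.linkage_, self.leaf_order_ = hcluster(sim)
        self.labels_ = cluster_cut(self.linkage_, self.cutoff_fraction)
        return self

    def structure(self, similarity: pd.DataFrame,
                  asymmetric: pd.DataFrame | None = None
                  ) -> SimilarityStructure:
        self.fit(similarity)
        return SimilarityStructure(
            conditions=self.conditions_, matrix=similarity,
            linkage=self.linkage_, leaf_order=self.leaf_order_,
            labels=pd.Series(self.labels_, index=self.conditions_),
            asymmetric=asymmetric, cutoff_fraction=self.cutoff_fraction,
        )
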