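"""Cross-sample similarity: Spearman matrices, UPGMA clustering, floored PCA,
fold-change reproducibility and the Nutridoma-upregulated gene-set filter.

All operations expect log10-scale expression with shared gene rows.  The
distance used for clustering is one minus the Spearman rank correlation,
so merge heights live in [0, 2]; correlations use average-rank ties.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .expression import ExpressionMatrix

__all__ = [
    "Dendrogram",
    "PcaEmbedding",
    "FoldChangeResult",
    "spearman_matrix",
    "cluster_samples",
    "pca_embed",
    "fold_change_reproducibility",
    "select_upregulated_genes",
]


@dataclass(frozen=True)
class Dendrogram:
    """Average-linkage tree over samples in correlation-distance space."""

    linkage: np.ndarray          # scipy linkage matrix
    labels: tuple                # leaf labels in linkage index order
    leaf_order: tuple            # labels in dendrogram left-to-right order

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def cut(self, n_clusters: int) -> pd.Series:
        """Flat cluster assignment for a given number of clusters."""
        flat = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return pd.Series(flat, index=list(self.labels), name="cluster")

    def to_newick(self) -> str:
        """Newick string with merge heights as branch lengths."""
        tree = hierarchy.to_tree(self.linkage)

        def walk(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = walk(node.left, node.dist)
            right = walk(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = walk(tree.left, tree.dist)
        right = walk(tree.right, tree.dist)
        return f"({left},{right});"


@dataclass(frozen=True)
class PcaEmbedding:
    """Sample coordinates on principal components of floored log expression."""

    coordinates: pd.DataFrame        # samples x components
    variance_ratio: np.ndarray       # fraction of variance per component
    floor: float


@dataclass(frozen=True)
class FoldChangeResult:
    """Between-replicate reproducibility of per-gene log10 fold changes."""

    pearson_r: float
    spearman_rho: float
    table: pd.DataFrame              # per-gene fold changes for each replicate


def spearman_matrix(values: pd.DataFrame | ExpressionMatrix) -> pd.DataFrame:
    """Pairwise Spearman correlation between sample columns.

    Ties receive average ranks.  A constant column has undefined rank
    correlation; its off-diagonal entries are reported as NaN with a
    warning rather than silently coerced.
    """
    if isinstance(values, ExpressionMatrix):
        values = values.values
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    ranks = values.rank(axis=0, method="average")
    constant = ranks.nunique(axis=0) == 1
    with np.errstate(invalid="ignore"):  # constant columns handled below
        corr = np.corrcoef(ranks.to_numpy(), rowvar=False)
    corr = pd.DataFrame(corr, index=values.columns, columns=values.columns)
    if constant.any():
        bad = list(values.columns[constant])
        warnings.warn(f"constant columns with undefined correlation: {bad}", stacklevel=2)
        corr.loc[constant, :] = np.nan
        corr.loc[:, constant] = np.nan
    np.fill_diagonal(corr.values, 1.0)
    return corr


def cluster_samples(corr: pd.DataFrame) -> Dendrogram:
    """UPGMA (average-linkage) clustering with distance = 1 - Spearman rho.

    Ties in linkage distance are broken by merging the pair whose leaf
    labels sort first: samples are ordered lexicographically before the
    (deterministic, index-ordered) linkage computation.
    """
    if corr.isna().to_numpy().any():
        pairs = [
            (corr.index[i], corr.columns[j])
            for i, j in zip(*np.where(corr.isna().to_numpy()))
            if i < j
        ]
        raise ValueError(f"missing correlations for pairs: {pairs}")
    labels = sorted(corr.index)
    c = corr.loc[labels, labels].to_numpy(dtype=float)
    dist = 1.0 - c
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry for squareform
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="average")
    order = hierarchy.leaves_list(linkage)
    return Dendrogram(linkage, tuple(labels), tuple(labels[i] for i in order))


def pca_embed(
    matrix: ExpressionMatrix | pd.DataFrame,
    floor: float = -2.0,
    n_components: int | None = None,
) -> PcaEmbedding:
    """PCA of samples after flooring log10 expression at ``floor``.

    Values below the floor are replaced by the floor before decomposition
    so lowly expressed (noisy) genes cannot dominate the components.  Genes
    are the features and are mean-centered; components are ordered by
    explained variance.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    if values.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    floored = values.clip(lower=floor)
    X = floored.to_numpy(dtype=float).T  # samples x genes
    non_constant = (X.max(axis=0) - X.min(axis=0)) > 0
    if non_constant.sum() < 2:
        raise ValueError("fewer than 2 non-constant genes after flooring")
    if n_components is None:
        n_components = min(X.shape[0], X.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    coords = pca.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    coordinates = pd.DataFrame(coords, index=values.columns, columns=cols)
    return PcaEmbedding(coordinates, pca.explained_variance_ratio_, floor)


def fold_change_reproducibility(
    log_matrix: pd.DataFrame | ExpressionMatrix,
    pair1: tuple[str, str],
    pair2: tuple[str, str],
    min_mean: float = -1.0,
) -> FoldChangeResult:
    """Correlation of per-gene fold changes between two replicate pairs.

    Each pair is (treated, control) sample names; the per-gene log10 fold
    change is treated minus control on the log scale.  Genes whose mean
    log10 expression over the four samples falls below ``min_mean`` are
    excluded before correlating the two fold-change vectors.
    """
    values = log_matrix.values if isinstance(log_matrix, ExpressionMatrix) else log_matrix
    cols = [*pair1, *pair2]
    missing = [c for c in cols if c not in values.columns]
    if missing:
        raise ValueError(f"samples not in matrix: {missing}")
    sub = values[cols]
    keep = sub.mean(axis=1) >= min_mean
    sub = sub[keep]
    if len(sub) < 3:
        raise ValueError("fewer than 3 genes survive the mean-expression filter")
    fc1 = sub[pair1[0]] - sub[pair1[1]]
    fc2 = sub[pair2[0]] - sub[pair2[1]]
    r = float(stats.pearsonr(fc1, fc2).statistic)
    rho = float(stats.spearmanr(fc1, fc2).statistic)
    table = pd.DataFrame({"fold_change_rep1": fc1, "fold_change_rep2": fc2})
    return FoldChangeResult(r, rho, table)


def select_upregulated_genes(
    log_matrix: pd.DataFrame | ExpressionMatrix,
    pairs: Sequence[tuple[str, str]],
    min_mean: float = -1.0,
    min_fold: float = 3.0,
) -> list:
    """Genes consistently upregulated in every matched (treated, control) pair.

    A gene is retained iff its mean log10 expression across all samples in
    the pairs is at least ``min_mean`` AND its fold change is at least
    ``min_fold`` (inclusive) in every pair.  Fold changes are evaluated on
    the floored log scale, so zero-expression genes contribute finite
    (floored) values rather than infinite ratios.
    """
    values = log_matrix.values if isinstance(log_matrix, ExpressionMatrix) else log_matrix
    if not pairs:
        raise ValueError("at least one (treated, control) pair required")
    cols: list[str] = []
    for treated, control in pairs:
        for c in (treated, control):
            if c not in values.columns:
                raise ValueError(f"sample {c!r} not in matrix")
            if c not in cols:
                cols.append(c)
    sub = values[cols]
    mean_ok = sub.mean(axis=1) >= min_mean
    # small epsilon keeps the inclusive bound inclusive under float rounding
    log_min_fold = np.log10(min_fold) - 1e-12
    fold_ok = pd.Series(True, index=values.index)
    for treated, control in pairs:
        fold_ok &= (values[treated] - values[control]) >= log_min_fold
    return list(values.index[mean_ok & fold_ok])
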