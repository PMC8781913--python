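"""Feature-relation analysis from surrogate splits.

The relation parameter between an ordered feature pair (i, j) is the
*mean adjusted agreement*: the average, over every node of the forest
where j is the primary splitter, of i's surrogate adjusted agreement at
that node (0 when i is not among the node's stored surrogates).  It
measures how well i can stand in for j in the fitted trees -- mutual
impact on the outcome -- and therefore goes beyond plain correlation.

The directed matrix is symmetrized as S = (M + M^T) / 2 for clustering
(Ward linkage on Euclidean row distances) and for threshold-based merging
of features that stem from the same metabolite (adducts/fragments).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, leaves_list, linkage

from ._kernels import _maa_accumulate
from .forest import Forest
from .table import FeatureTable

__all__ = [
    "RelationMatrix",
    "ClusterResult",
    "MergeGroups",
    "mean_adjusted_agreement",
    "cluster_relations",
    "pearson_relation",
    "merge_features",
]


@dataclass
class RelationMatrix:
    """Directed relation values over a feature subset.

    ``directed.loc[i, j]`` is the mean adjusted agreement of i as a
    surrogate for primary j (for correlation-kind matrices the matrix is
    symmetric to begin with).  The diagonal is set to 1 by convention for
    heatmaps and is excluded from analysis.
    """

    directed: pd.DataFrame
    kind: str = "mean_adjusted_agreement"  # or "pearson_abs"

    def __post_init__(self) -> None:
        if not self.directed.index.equals(self.directed.columns):
            raise ValueError("relation matrix must be square with matching labels")
        vals = self.directed.to_numpy()
        if np.nanmin(vals) < -1e-12 or np.nanmax(vals) > 1.0 + 1e-12:
            raise ValueError("relation values must lie in [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.directed.index

    def symmetrized(self) -> pd.DataFrame:
        s = 0.5 * (self.directed + self.directed.T)
        np.fill_diagonal(s.values, 1.0)
        return s

    def to_csv(self, path: str) -> None:
        self.directed.rename_axis("feature_id").to_csv(path)

    @classmethod
    def from_csv(cls, path: str, kind: str = "mean_adjusted_agreement") -> "RelationMatrix":
        df = pd.read_csv(path, index_col=0)
        df.columns = df.columns.astype(str)
        df.index = df.index.astype(str)
        return cls(df, kind=kind)


@dataclass
class ClusterResult:
    """Ward/Euclidean hierarchical clustering of a relation matrix."""

    linkage_matrix: np.ndarray
    labels: pd.Series  # flat cluster id per feature (1..n_clusters)
    leaf_order: list  # feature ids in dendrogram order

    def n_clusters(self) -> int:
        return int(self.labels.nunique())


@dataclass
class MergeGroups:
    """Connected components of the thresholded symmetrized relation graph."""

    threshold: float
    groups: list = field(default_factory=list)  # list of frozensets, size >= 2

    def as_sets(self) -> list:
        return [set(g) for g in self.groups]


def mean_adjusted_agreement(forest: Forest, feature_subset=None) -> RelationMatrix:
    """Directed mean adjusted agreement matrix over a feature subset.

    M[i, j] averages i's recorded surrogate adjusted agreement over *all*
    nodes (across all trees) where j is the primary splitter; nodes where
    i was crowded out of the stored top-s list contribute 0.  Columns of
    features that never split are all zero.
    """
    if forest.sur_feat is None:
        raise ValueError("forest was grown without surrogates; relations unavailable")
    p = forest.p
    adj_sum = np.zeros((p, p))
    primary_nodes = np.zeros(p, dtype=np.int64)
    _maa_accumulate(
        forest.node_feature, forest.sur_feat, forest.sur_adj, forest.sur_count,
        adj_sum, primary_nodes,
    )
    denom = np.where(primary_nodes > 0, primary_nodes, 1)
    M = adj_sum / denom[None, :]
    names = pd.Index([str(f) for f in forest.feature_names])
    df = pd.DataFrame(M, index=names, columns=names)
    if feature_subset is not None:
        subset = pd.Index([str(f) for f in feature_subset])
        missing = subset.difference(names)
        if len(missing):
            raise KeyError(f"features not in forest: {list(missing)}")
        if len(subset) == 0:
            raise ValueError("feature subset is empty")
        df = df.loc[subset, subset]
    np.fill_diagonal(df.values, 1.0)
    return RelationMatrix(df, kind="mean_adjusted_agreement")


def pearson_relation(table: FeatureTable, feature_subset=None) -> RelationMatrix:
    """Absolute pairwise Pearson correlations, as a comparison baseline.

    Zero-variance features get all-zero rows/columns with a warning.
    """
    intens = table.intensities
    if feature_subset is not None:
        intens = intens.loc[:, pd.Index(feature_subset)]
    vals = intens.to_numpy(dtype=float)
    sds = vals.std(axis=0)
    flat = sds == 0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance feature(s); correlation rows set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.abs(np.corrcoef(vals, rowvar=False))
    corr[np.isnan(corr)] = 0.0
    corr[flat, :] = 0.0
    corr[:, flat] = 0.0
    np.fill_diagonal(corr, 1.0)
    names = pd.Index([str(c) for c in intens.columns])
    return RelationMatrix(pd.DataFrame(corr, index=names, columns=names), kind="pearson_abs")


def cluster_relations(rel: RelationMatrix, n_clusters: int) -> ClusterResult:
    """Ward-linkage clustering of the symmetrized relation matrix rows.

    Euclidean distances between rows of S feed the agglomeration; flat
    labels are cut at ``n_clusters`` and the dendrogram leaf order is
    returned for heatmap layout.
    """
    S = rel.symmetrized()
    n = S.shape[0]
    if n < 2:
        raise ValueError("need at least 2 features to cluster")
    if n_clusters > n:
        raise ValueError(f"n_clusters={n_clusters} exceeds {n} features")
    Z = linkage(S.to_numpy(), method="ward", metric="euclidean")
    labels = fcluster(Z, t=n_clusters, criterion="maxclust")
    order = [S.index[i] for i in leaves_list(Z)]
    return ClusterResult(
        linkage_matrix=Z,
        labels=pd.Series(labels, index=S.index, name="cluster"),
        leaf_order=order,
    )


def merge_features(rel: RelationMatrix, threshold: float = 0.9) -> MergeGroups:
    """Groups of features with pairwise symmetrized relation >= threshold.

    Builds the graph on the matrix's features with edges where
    S >= threshold and returns its connected components of size >= 2
    (candidate same-metabolite feature groups).  Output is invariant to
    feature order; raising the threshold never enlarges a group.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    S = rel.symmetrized()
    ids = list(S.index)
    A = S.to_numpy() >= threshold
    np.fill_diagonal(A, False)
    # connected components by BFS
    seen = np.zeros(len(ids), dtype=bool)
    groups = []
    for start in range(len(ids)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = [start]
        while stack:
            u = stack.pop()
            for v in np.flatnonzero(A[u]):
                if not seen[v]:
                    seen[v] = True
                    stack.append(v)
                    comp.append(v)
        if len(comp) > 1:
            groups.append(frozenset(ids[i] for i in sorted(comp)))
    groups.sort(key=lambda g: sorted(g))
    return MergeGroups(threshold=threshold, groups=groups)


def relation_heatmap(rel: RelationMatrix, path: str, n_clusters: int | None = None) -> None:
    """Render the clustered symmetrized relation matrix to PNG/SVG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    S = rel.symmetrized()
    if S.shape[0] >= 2:
        order = cluster_relations(rel, n_clusters or min(2, S.shape[0])).leaf_order
        S = S.loc[order, order]
    fig, ax = plt.subplots(figsize=(8, 7))
    im = ax.imshow(S.to_numpy(), vmin=0.0, vmax=1.0, cmap="viridis")
    ax.set_xticks(range(S.shape[0]))
    ax.set_yticks(range(S.shape[0]))
    ax.set_xticklabels(S.columns, rotation=90, fontsize=5)
    ax.set_yticklabels(S.index, fontsize=5)
    fig.colorbar(im, ax=ax, label=rel.kind)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
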