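"""Structure checks over the cancer-related signature: hierarchical
clustering of samples and 3-D principal-component scores.

Distance between sample profiles is 1 - Pearson correlation with average
linkage; the dendrogram can be serialized as Newick text.  Tumor/normal
separation is summarized as cluster purity at a two-cluster cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix, ValidationError


@dataclass
class Dendrogram:
    sample_ids: list[str]
    linkage: np.ndarray  # scipy linkage matrix, or empty for single leaf
    metric: str
    method: str

    def cut(self, n_clusters: int) -> np.ndarray:
        """Flat cluster labels (1..k) for each sample."""
        if len(self.sample_ids) == 1:
            return np.array([1])
        return hierarchy.fcluster(self.linkage, t=n_clusters, criterion="maxclust")

    def to_newick(self) -> str:
        if len(self.sample_ids) == 1:
            return f"{self.sample_ids[0]};"
        tree = hierarchy.to_tree(self.linkage)

        def walk(node) -> str:
            if node.is_leaf():
                return self.sample_ids[node.id]
            left, right = walk(node.get_left()), walk(node.get_right())
            bl = node.dist - node.get_left().dist
            br = node.dist - node.get_right().dist
            return f"({left}:{bl:.6g},{right}:{br:.6g})"

        return walk(tree) + ";"


def hierarchical_cluster(
    matrix: ExpressionMatrix, method: str = "average", metric: str = "correlation"
) -> Dendrogram:
    """Cluster samples (columns) of the signature-restricted matrix."""
    x = matrix.values.T  # samples x miRNAs
    if x.shape[0] < 1:
        raise ValidationError("no samples to cluster")
    if x.shape[0] == 1:
        return Dendrogram(list(matrix.sample_ids), np.empty((0, 4)), metric, method)
    if metric == "correlation" and np.any(x.std(axis=1) == 0):
        # constant profiles have undefined correlation distance
        raise ValidationError("constant sample profile; correlation distance undefined")
    d = pdist(x, metric=metric)
    z = hierarchy.linkage(d, method=method)
    return Dendrogram(list(matrix.sample_ids), z, metric, method)


@dataclass
class PCAScores:
    sample_ids: list[str]
    scores: np.ndarray  # samples x components
    explained_variance_ratio: np.ndarray
    components: np.ndarray  # components x miRNAs


def pca_scores(matrix: ExpressionMatrix, n_components: int = 3) -> PCAScores:
    """Principal-component scores of samples over the signature miRNAs.

    Centered (not scaled) PCA via SVD; scores are the centered data
    projected on the orthonormal components.
    """
    x = matrix.values.T  # samples x miRNAs
    n = x.shape[0]
    if n < 3:
        raise ValidationError("PCA needs at least 3 samples")
    centered = x - x.mean(axis=0, keepdims=True)
    total_var = centered.var(axis=0, ddof=1).sum()
    if total_var == 0:
        raise ValidationError("constant matrix; PCA undefined")
    k = min(n_components, n - 1, x.shape[1])
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    scores = u[:, :k] * s[:k]
    evr = (s[:k] ** 2) / (s**2).sum()
    return PCAScores(list(matrix.sample_ids), scores, evr, vt[:k])


def cluster_purity(labels_true, labels_pred) -> float:
    """Sample-weighted purity: fraction of samples in their cluster's
    majority class, averaged over clusters weighted by cluster size."""
    labels_true = np.asarray(labels_true)
    labels_pred = np.asarray(labels_pred)
    total = 0
    for c in np.unique(labels_pred):
        members = labels_true[labels_pred == c]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return total / len(labels_true)


def separation_purity(
    matrix: ExpressionMatrix, labels, use: str = "tree", seed: int = 0
) -> float:
    """Tumor/normal separation score in [0.5, 1].

    ``use='tree'``: purity of the best two-cluster dendrogram cut.
    ``use='pca'``: 2-means on the 3-D PC scores.
    A single distinct label yields purity 1 trivially (degenerate).
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        return 1.0
    if use == "tree":
        dg = hierarchical_cluster(matrix)
        pred = dg.cut(2)
    elif use == "pca":
        from sklearn.cluster import KMeans

        scores = pca_scores(matrix).scores
        pred = KMeans(n_clusters=2, n_init=10, random_state=seed).fit_predict(scores)
    else:
        raise ValueError(f"unknown mode {use!r}")
    return cluster_purity(labels, pred)
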