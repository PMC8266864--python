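"""PCA and Euclidean average-linkage (UPGMA) hierarchical clustering.

Sample-level structure is examined on log2(normalized + 1) expression;
DEG heatmap clustering operates on row-standardized (scaled and centered)
values.  The UPGMA implementation keeps an explicit merge history in the
conventional linkage-matrix layout so dendrograms can be cut at any k and
exported as Newick trees.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Literal

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .errors import ConfigurationError, DataError


@dataclasses.dataclass
class PCAResult:
    scores: pd.DataFrame  # samples × components
    loadings: pd.DataFrame  # genes × components
    explained_variance_fraction: np.ndarray


def pca(log_expression: pd.DataFrame, n_components: int = 2) -> PCAResult:
    """Principal components of a genes × samples log-expression matrix.

    Genes are mean-centered; components come from the singular value
    decomposition of the centered matrix.  The sign of each component is
    fixed so that the largest-magnitude loading entry is positive, making
    the result deterministic.
    """
    n_genes, n_samples = log_expression.shape
    if n_samples < 2:
        raise ConfigurationError("PCA needs at least 2 samples")
    if n_components > min(n_genes, n_samples):
        raise ConfigurationError(
            f"n_components={n_components} exceeds min(genes, samples)="
            f"{min(n_genes, n_samples)}"
        )
    X = log_expression.to_numpy(float)
    if not np.all(np.isfinite(X)):
        raise DataError("non-finite values in expression matrix")
    centered = (X - X.mean(axis=1, keepdims=True)).T  # samples × genes
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total_var = (s**2).sum()
    frac = (s**2 / total_var)[:n_components] if total_var > 0 else np.zeros(n_components)
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    for k in range(n_components):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=log_expression.columns, columns=comp_names),
        loadings=pd.DataFrame(loadings, index=log_expression.index, columns=comp_names),
        explained_variance_fraction=frac,
    )


@dataclasses.dataclass
class Dendrogram:
    """Agglomerative merge history in linkage-matrix form.

    ``merges`` has one row per merge: (cluster id 1, cluster id 2, height,
    size of merged cluster); leaves are numbered 0..n-1 in ``leaf_labels``
    order and internal nodes n, n+1, ... in merge order.
    """

    merges: np.ndarray  # (n - 1) × 4
    leaf_labels: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def to_newick(self) -> str:
        """Newick string with ultrametric branch lengths (merge half-heights)."""
        from skbio import TreeNode

        tree = TreeNode.from_linkage_matrix(self.merges, self.leaf_labels)
        return str(tree).strip()


def hierarchical_cluster(
    matrix: pd.DataFrame, axis: Literal["samples", "genes"] = "samples"
) -> Dendrogram:
    """UPGMA (unweighted average linkage) over Euclidean distances.

    ``axis='samples'`` clusters columns, ``'genes'`` clusters rows.  Ties in
    the minimum inter-cluster distance are broken by the lexicographically
    smallest (id1, id2) pair of cluster ids, which makes the merge history
    deterministic.
    """
    if axis == "samples":
        points = matrix.to_numpy(float).T
        labels = list(matrix.columns)
    elif axis == "genes":
        points = matrix.to_numpy(float)
        labels = list(matrix.index)
    else:
        raise ConfigurationError("axis must be 'samples' or 'genes'")
    n = len(labels)
    if n < 2:
        raise ConfigurationError("clustering needs at least 2 items")
    if not np.all(np.isfinite(points)):
        raise DataError("non-finite values in clustering input")

    size_total = 2 * n - 1
    D = np.full((size_total, size_total), np.inf)
    D[:n, :n] = squareform(pdist(points, metric="euclidean"))
    np.fill_diagonal(D, np.inf)
    sizes = np.zeros(size_total, dtype=int)
    sizes[:n] = 1
    active = np.zeros(size_total, dtype=bool)
    active[:n] = True
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = D[np.ix_(idx, idx)]
        iu = np.triu_indices(len(idx), k=1)
        flat = sub[iu]
        best = int(np.argmin(flat))  # argmin returns the first minimum:
        i, j = int(idx[iu[0][best]]), int(idx[iu[1][best]])  # lexicographic tie-break
        height = D[i, j]
        new = n + step
        si, sj = sizes[i], sizes[j]
        others = idx[(idx != i) & (idx != j)]
        D[new, others] = (si * D[i, others] + sj * D[j, others]) / (si + sj)
        D[others, new] = D[new, others]
        sizes[new] = si + sj
        active[[i, j]] = False
        active[new] = True
        merges[step] = (i, j, height, si + sj)

    return Dendrogram(merges=merges, leaf_labels=labels)


def cut_tree(dendrogram: Dendrogram, k: int) -> pd.Series:
    """Cut the dendrogram into exactly k clusters.

    With monotone merge heights, applying the first n - k merges yields the
    k-cluster partition.  Cluster labels are integers 1..k assigned by first
    appearance in leaf order.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ConfigurationError(f"k must be in [1, {n}]")
    parent = np.arange(2 * n - 1)

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        i, j, _, _ = dendrogram.merges[step]
        new = n + step
        parent[find(int(i))] = new
        parent[find(int(j))] = new
    roots = [find(leaf) for leaf in range(n)]
    relabel: dict[int, int] = {}
    labels = []
    for r in roots:
        if r not in relabel:
            relabel[r] = len(relabel) + 1
        labels.append(relabel[r])
    return pd.Series(labels, index=dendrogram.leaf_labels, name="cluster")


def row_standardize(log_expression: pd.DataFrame, ddof: int = 0) -> pd.DataFrame:
    """Center and scale each gene (row) to mean 0, SD 1.

    The population SD (divide by n) is the default; ``ddof=1`` selects the
    sample SD.  Zero-variance rows are mapped to all-zero rows with a
    warning rather than NaNs.
    """
    X = log_expression.to_numpy(float)
    mean = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=ddof, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} constant row(s) standardized to zeros", stacklevel=2
        )
    sd = np.where(sd == 0, 1.0, sd)
    out = (X - mean) / sd
    out[flat, :] = 0.0
    return pd.DataFrame(out, index=log_expression.index, columns=log_expression.columns)
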