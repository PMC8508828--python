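"""Hierarchical clustering on correlation distance and PCA of ln I profiles.

Conditions (compound x concentration) or biomarkers are clustered
agglomeratively on d(u, v) = 1 - Pearson r(u, v) with average linkage
(complete selectable). PCA is computed on the column-mean-centered
condition x biomarker matrix via SVD; variance fractions sum to 1 and each
component's sign is fixed so its largest-magnitude loading is positive.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from pelitox.library_io import ValidationError

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy linkage matrix (merge list with heights)
    labels: list[str]
    method: str
    leaf_order: list[str]


@dataclasses.dataclass
class PcaResult:
    scores: pd.DataFrame  # conditions x components
    loadings: pd.DataFrame  # biomarkers x components
    variance_fractions: np.ndarray


def _items(matrix: pd.DataFrame, axis: str) -> tuple[np.ndarray, list[str]]:
    if axis == "columns":
        return matrix.to_numpy(dtype=float).T, [str(c) for c in matrix.columns]
    if axis == "rows":
        return matrix.to_numpy(dtype=float), [str(i) for i in matrix.index]
    raise ValidationError(f"axis must be 'rows' or 'columns', got {axis!r}")


def cluster(
    matrix: pd.DataFrame, axis: str = "columns", method: str = "average"
) -> ClusterResult:
    """Agglomerative clustering of profile rows or columns.

    Distance is the correlation distance 1 - r; linkage is ``average`` by
    default (``complete`` selectable). Zero-variance items make correlation
    undefined and are rejected by name. Non-monotone merge heights (possible
    for average linkage on a non-metric dissimilarity) are logged, not hidden.
    """
    X, labels = _items(matrix, axis)
    if len(labels) < 2:
        raise ValidationError("clustering needs >= 2 items")
    if method not in ("average", "complete"):
        raise ValidationError(f"unsupported linkage {method!r}")
    variances = X.var(axis=1)
    dead = [labels[i] for i in np.nonzero(variances == 0)[0]]
    if dead:
        raise ValidationError(f"zero-variance items (correlation undefined): {dead[:10]}")
    d = pdist(X, metric="correlation")
    Z = hierarchy.linkage(d, method=method)
    if (np.diff(Z[:, 2]) < -1e-12).any():
        logger.warning("non-monotone merge heights in %s-linkage dendrogram", method)
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterResult(linkage=Z, labels=labels, method=method, leaf_order=order)


def to_newick(result: ClusterResult) -> str:
    """Serialize a dendrogram as a Newick string with branch lengths.

    Branch length of a node is its parent's merge height minus its own.
    """
    tree = hierarchy.to_tree(result.linkage)

    def fmt(node, parent_dist: float) -> str:
        length = parent_dist - node.dist
        if node.is_leaf():
            return f"{result.labels[node.id]}:{length:.10g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = fmt(tree.left, tree.dist)
    right = fmt(tree.right, tree.dist)
    return f"({left},{right});"


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA of conditions in biomarker space (column-mean-centered SVD).

    ``matrix`` is biomarkers x conditions; conditions act as observations.
    ``variance_fractions`` covers every component and sums to 1.
    """
    if matrix.shape[1] < 3:
        raise ValidationError("PCA needs >= 3 conditions")
    X = matrix.to_numpy(dtype=float).T  # conditions x biomarkers
    Xc = X - X.mean(axis=0, keepdims=True)
    if not np.any(Xc):
        raise ValidationError("rank-0 matrix: no variance to decompose")
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    fractions = s**2 / np.sum(s**2)
    # sign convention: largest-magnitude loading per component positive
    for j in range(len(s)):
        i_max = np.argmax(np.abs(Vt[j]))
        if Vt[j, i_max] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    k = len(s) if n_components is None else min(n_components, len(s))
    comp_names = [f"PC{i + 1}" for i in range(k)]
    scores = pd.DataFrame(
        (U[:, :k] * s[:k]), index=[str(c) for c in matrix.columns], columns=comp_names
    )
    loadings = pd.DataFrame(
        Vt[:k].T, index=[str(i) for i in matrix.index], columns=comp_names
    )
    return PcaResult(scores=scores, loadings=loadings, variance_fractions=fractions)


def plot_profile_heatmap(
    matrix: pd.DataFrame, path, clip: float = 2.0, cmap: str = "RdYlGn_r"
) -> None:
    """Basic clipped ln I heatmap export (display values clipped to +/- clip)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    values = np.clip(matrix.to_numpy(dtype=float), -clip, clip)
    fig, ax = plt.subplots(
        figsize=(max(4, 0.25 * matrix.shape[1]), max(4, 0.12 * matrix.shape[0]))
    )
    im = ax.imshow(values, aspect="auto", cmap=cmap, vmin=-clip, vmax=clip)
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns], rotation=90, fontsize=5)
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index], fontsize=4)
    fig.colorbar(im, ax=ax, label="mean ln I (clipped)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
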