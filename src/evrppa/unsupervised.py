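"""Exploratory views: Z-score standardization, two-way Ward clustering, covariance PCA.

Standardization is per endpoint (column) with the sample-SD (n-1) convention.
Two-way hierarchical clustering agglomerates rows and columns of the
standardized matrix under Euclidean distance and Ward's method; trees are
exportable as Newick strings.  PCA eigen-decomposes the covariance matrix of
column-centered (not scaled) data, with components ordered by decreasing
eigenvalue and the sign fixed so each component's largest-magnitude loading is
positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)


@dataclass
class ClusteringResult:
    row_order: list[int]
    col_order: list[int]
    row_linkage: np.ndarray  # scipy linkage matrices (merge sequences + heights)
    col_linkage: np.ndarray
    standardized: pd.DataFrame


@dataclass
class PcaResult:
    scores: pd.DataFrame      # samples x components
    loadings: pd.DataFrame    # endpoints x components
    explained_variance: np.ndarray  # fraction per component


def zscore_standardize(matrix: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-endpoint Z score: column mean 0, SD 1 (sample-SD convention).

    Columns with zero SD or fewer than 2 finite values are dropped with a
    warning — they carry no contrast.
    """
    values = matrix.astype(float)
    sd = values.std(ddof=ddof)
    n_finite = values.notna().sum()
    bad = (sd == 0) | sd.isna() | (n_finite < 2)
    if bad.any():
        logger.warning("dropping %d zero-variance endpoints: %s",
                       int(bad.sum()), list(values.columns[bad]))
        values = values.loc[:, ~bad]
        sd = sd[~bad]
    return (values - values.mean()) / sd


def hierarchical_cluster(
    matrix: pd.DataFrame,
    distance: str = "euclidean",
    linkage: str = "ward",
    standardize: bool = True,
) -> ClusteringResult:
    """Two-way agglomerative clustering of a samples x endpoints matrix.

    Rows and columns are clustered independently on the (optionally
    Z-standardized) matrix.  Missing cells are rejected; impute or drop
    incomplete endpoints upstream.
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("clustering needs >= 2 rows and >= 2 columns")
    data = zscore_standardize(matrix) if standardize else matrix.astype(float)
    if data.isna().any().any():
        raise ValueError("matrix contains missing cells; clustering requires complete data")
    X = data.to_numpy()
    row_link = hierarchy.linkage(pdist(X, metric=distance), method=linkage)
    col_link = hierarchy.linkage(pdist(X.T, metric=distance), method=linkage)
    row_order = hierarchy.leaves_list(row_link).tolist()
    col_order = hierarchy.leaves_list(col_link).tolist()
    return ClusteringResult(
        row_order=row_order, col_order=col_order,
        row_linkage=row_link, col_linkage=col_link,
        standardized=data,
    )


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch lengths."""
    tree = hierarchy.to_tree(link)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return walk(tree, tree.dist) + ";"


def pca_covariance(matrix: pd.DataFrame, n_components: int | None = None) -> PcaResult:
    """PCA via eigen-decomposition of the endpoint covariance matrix.

    Data are column-centered but not scaled.  All components are returned by
    default; ``explained_variance`` fractions sum to 1 over the full set.
    """
    values = matrix.astype(float)
    if values.isna().any().any():
        raise ValueError("PCA requires complete data")
    n, p = values.shape
    if n < 2:
        raise ValueError("PCA needs >= 2 samples")
    centered = values - values.mean()
    cov = np.cov(centered.to_numpy(), rowvar=False, ddof=1)
    cov = np.atleast_2d(cov)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-magnitude loading positive
    for j in range(eigvecs.shape[1]):
        i_max = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i_max, j] < 0:
            eigvecs[:, j] *= -1.0
    if n_components is not None:
        eigvals = eigvals[:n_components]
        eigvecs = eigvecs[:, :n_components]
    total = eigvals.sum() if n_components is None else np.clip(
        np.trace(cov), a_min=np.finfo(float).tiny, a_max=None
    )
    explained = eigvals / total if total > 0 else np.zeros_like(eigvals)
    comp_names = [f"PC{j + 1}" for j in range(eigvecs.shape[1])]
    scores = centered.to_numpy() @ eigvecs
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.index, columns=comp_names),
        loadings=pd.DataFrame(eigvecs, index=values.columns, columns=comp_names),
        explained_variance=np.asarray(explained, dtype=float),
    )
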