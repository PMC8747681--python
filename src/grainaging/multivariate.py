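"""Exploratory structure: UPGMA dendrograms and canonical-variates biplots.

Traits and genotypes are clustered with average-linkage (UPGMA) on
Euclidean distances between standardized rows, giving ultrametric trees
(heights are half the cophenetic distance, so two items at distance d
merge at height d/2).  Linear discriminant / canonical variates analysis
maximizes the between-class to within-class scatter ratio and is run
separately for color and size/shape trait sets; scores and trait loadings
for the first two axes form the biplot.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


def standardize(
    matrix: np.ndarray, columns=None
) -> tuple[np.ndarray, list]:
    """Z-score columns; zero-variance columns are dropped with a warning.

    Returns ``(z, kept)`` where ``kept`` lists the surviving column
    identifiers (indices, or labels when ``columns`` is given).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 rows")
    labels = list(columns) if columns is not None else list(range(X.shape[1]))
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all columns are constant")
    if not keep.all():
        dropped = [l for l, k in zip(labels, keep) if not k]
        warnings.warn(f"dropping constant columns: {dropped}", stacklevel=2)
    X = X[:, keep]
    z = (X - X.mean(axis=0)) / X.std(axis=0)
    return z, [l for l, k in zip(labels, keep) if k]


def genotype_trait_means(trait_table: pd.DataFrame, traits) -> pd.DataFrame:
    """Mean trait vector per genotype, years pooled."""
    if "genotype" not in trait_table.columns:
        raise ValueError("trait table lacks a genotype column")
    return trait_table.groupby("genotype")[list(traits)].mean()


@dataclass
class Dendrogram:
    """UPGMA merge tree; heights are ultrametric (cophenetic distance / 2)."""

    linkage: np.ndarray           # scipy linkage matrix (distances)
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2] / 2.0

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def cophenetic(self) -> np.ndarray:
        """Condensed cophenetic distance matrix."""
        return hierarchy.cophenet(self.linkage)

    def to_newick(self) -> str:
        """Newick export; branch lengths are height differences."""
        n = self.n_leaves
        heights = self.heights

        def node(i: int) -> tuple[str, float]:
            if i < n:
                return self.labels[i], 0.0
            a, b = int(self.linkage[i - n, 0]), int(self.linkage[i - n, 1])
            h = heights[i - n]
            sa, ha = node(a)
            sb, hb = node(b)
            return f"({sa}:{h - ha:.6g},{sb}:{h - hb:.6g})", h

        s, _ = node(2 * n - 2)
        return s + ";"


def upgma_tree(
    data: np.ndarray,
    labels=None,
    is_distance: bool | None = None,
) -> Dendrogram:
    """UPGMA (average linkage) tree.

    ``data`` is either a square symmetric distance matrix or a feature
    matrix (rows = items); in the latter case rows are standardized
    column-wise and Euclidean distances are used.  ``is_distance=None``
    auto-detects (square, symmetric, zero diagonal).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("need a 2-D array")
    n = X.shape[0]
    if labels is None:
        labels = [f"item{i}" for i in range(n)]
    labels = [str(l) for l in labels]
    if len(labels) != n:
        raise ValueError("labels length must match the number of rows")

    square = X.shape[0] == X.shape[1]
    if is_distance is None:
        is_distance = bool(
            square and np.allclose(X, X.T) and np.allclose(np.diag(X), 0)
        )
    if is_distance:
        if not square or not np.allclose(X, X.T):
            raise ValueError("distance matrix must be square and symmetric")
        if (X < 0).any():
            raise ValueError("distances must be non-negative")
        condensed = squareform(X, checks=False)
    else:
        z, _ = standardize(X)
        condensed = pdist(z, metric="euclidean")
    Z = hierarchy.linkage(condensed, method="average")
    return Dendrogram(linkage=Z, labels=labels)


def cut_clusters(tree: Dendrogram, k: int) -> np.ndarray:
    """Cluster labels (1..k) from cutting the k-1 highest merges."""
    if not 1 <= k <= tree.n_leaves:
        raise ValueError(f"k must be in [1, {tree.n_leaves}]")
    return hierarchy.fcluster(tree.linkage, t=k, criterion="maxclust")


@dataclass
class BiplotResult:
    """Canonical-variates scores, loadings and eigenvalues."""

    scores: np.ndarray       # (n_items, n_axes)
    loadings: np.ndarray     # (n_traits, n_axes) discriminant coefficients
    eigenvalues: np.ndarray
    trait_names: list[str] = field(default_factory=list)
    class_labels: np.ndarray | None = None
    regularized: bool = False


def lda_biplot(
    matrix: np.ndarray,
    classes,
    trait_names=None,
    ridge: float = 1e-8,
) -> BiplotResult:
    """Canonical variates: axes maximizing between/within scatter ratio.

    Input columns are standardized first.  The within-class scatter is
    ridge-regularized when (near-)singular, which is logged.  The number
    of axes is min(n_traits, n_classes - 1).
    """
    classes = np.asarray(classes)
    levels, inverse = np.unique(classes, return_inverse=True)
    if len(levels) < 2:
        raise ValueError("need >= 2 classes")
    counts = np.bincount(inverse)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 rows")
    z, kept = standardize(np.asarray(matrix, dtype=float), trait_names)
    n, p = z.shape

    grand = z.mean(axis=0)
    Sw = np.zeros((p, p))
    Sb = np.zeros((p, p))
    for g in range(len(levels)):
        sel = z[inverse == g]
        mu = sel.mean(axis=0)
        d = sel - mu
        Sw += d.T @ d
        Sb += len(sel) * np.outer(mu - grand, mu - grand)

    reg = False
    eps = ridge * np.trace(Sw) / p if np.trace(Sw) > 0 else ridge
    if np.linalg.matrix_rank(Sw) < p:
        reg = True
        logger.info("within-class scatter singular; ridge applied")
    Sw_r = Sw + eps * np.eye(p)

    eigvals, eigvecs = linalg.eigh(Sb, Sw_r)
    order = np.argsort(eigvals)[::-1]
    n_axes = min(p, len(levels) - 1)
    eigvals = np.maximum(eigvals[order][:n_axes], 0.0)
    # scipy normalizes v' Sw v = 1; rescale so the within-class
    # *covariance* of each canonical score is 1 (standard CVA units)
    W = eigvecs[:, order[:n_axes]] * np.sqrt(max(n - len(levels), 1))
    scores = (z - grand) @ W
    return BiplotResult(
        scores=scores,
        loadings=W,
        eigenvalues=eigvals,
        trait_names=[str(t) for t in kept],
        class_labels=classes,
        regularized=reg,
    )
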