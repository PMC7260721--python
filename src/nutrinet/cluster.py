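"""k-means grouping of log2FC profiles and PCA of dataset similarity.

Genes are clustered on their fold-change profiles (Euclidean distance,
no row standardization by default since all columns share the log2FC
scale) with Lloyd's algorithm, k-means++ seeding and the best of
``n_init`` restarts by within-cluster sum of squares.  Groups are
relabeled G1..Gk by decreasing size for stable reporting.  The Lloyd loop
asserts that its objective never increases between iterations; an empty
cluster is re-seeded from the point currently farthest from its centroid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ClusterAssignment", "PCAResult", "kmeans_profiles", "pca_scores"]


@dataclass
class ClusterAssignment:
    labels: pd.Series  # gene -> "G1".."Gk"
    centroids: pd.DataFrame  # group x condition
    inertia: float  # within-cluster sum of squares
    seed: int


@dataclass
class PCAResult:
    scores: pd.DataFrame  # rows x components
    loadings: pd.DataFrame  # columns x components, orthonormal
    variance_explained: np.ndarray  # sums to 1 (zeros when degenerate)
    degenerate: bool = False


def _kmeans_pp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        total = d2.sum()
        if total <= 0:
            centers[j] = X[rng.integers(n)]
            continue
        centers[j] = X[rng.choice(n, p=d2 / total)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def _lloyd(X: np.ndarray, centers: np.ndarray, max_iter: int = 300, tol: float = 1e-10):
    k = centers.shape[0]
    prev_inertia = np.inf
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = d2.argmin(axis=1)
        inertia = d2[np.arange(X.shape[0]), labels].sum()
        # objective must not increase across Lloyd iterations
        assert inertia <= prev_inertia + 1e-9 * max(1.0, prev_inertia), "k-means objective increased"
        for j in range(k):
            mask = labels == j
            if mask.any():
                centers[j] = X[mask].mean(axis=0)
            else:
                # re-seed an empty cluster from the point farthest from its centroid
                resid = ((X - centers[labels]) ** 2).sum(axis=1)
                far = int(resid.argmax())
                centers[j] = X[far]
                labels[far] = j
        if prev_inertia - inertia <= tol * max(1.0, prev_inertia):
            prev_inertia = inertia
            break
        prev_inertia = inertia
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    labels = d2.argmin(axis=1)
    inertia = d2[np.arange(X.shape[0]), labels].sum()
    return labels, centers, float(inertia)


def kmeans_profiles(
    matrix: pd.DataFrame, k: int = 5, n_init: int = 10, seed: int = 0
) -> ClusterAssignment:
    """Cluster gene profiles into k groups; best of n_init restarts.

    Deterministic given ``seed``.  Raises when k exceeds the number of
    genes (rows).
    """
    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("profile matrix contains non-finite values")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of genes ({X.shape[0]})")
    if k < 1:
        raise ValueError("k must be >=1")
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(max(1, n_init)):
        centers = _kmeans_pp_init(X, k, rng)
        labels, centers, inertia = _lloyd(X, centers)
        if best is None or inertia < best[2]:
            best = (labels, centers, inertia)
    labels, centers, inertia = best
    # relabel by decreasing cluster size (ties: by first occurrence)
    sizes = np.bincount(labels, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    rename = {int(old): f"G{rank + 1}" for rank, old in enumerate(order)}
    named = pd.Series([rename[int(l)] for l in labels], index=matrix.index, name="group")
    centroids = pd.DataFrame(
        centers[order], index=[f"G{r + 1}" for r in range(k)], columns=matrix.columns
    )
    return ClusterAssignment(labels=named, centroids=centroids, inertia=inertia, seed=seed)


def pca_scores(matrix: pd.DataFrame | np.ndarray) -> PCAResult:
    """Column-mean-centered SVD principal components.

    Returns scores (rows projected onto components), orthonormal loadings
    and the fraction of variance carried by each component.  A constant
    matrix has zero total variance and is flagged degenerate with all
    variance shares zero.
    """
    df = matrix if isinstance(matrix, pd.DataFrame) else pd.DataFrame(np.asarray(matrix))
    X = df.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 2 rows and 2 columns")
    centered = X - X.mean(axis=0, keepdims=True)
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    total = (s**2).sum()
    if total <= 1e-300:
        ncomp = s.size
        comp_names = [f"PC{i + 1}" for i in range(ncomp)]
        return PCAResult(
            scores=pd.DataFrame(np.zeros((X.shape[0], ncomp)), index=df.index, columns=comp_names),
            loadings=pd.DataFrame(Vt.T, index=df.columns, columns=comp_names),
            variance_explained=np.zeros(ncomp),
            degenerate=True,
        )
    comp_names = [f"PC{i + 1}" for i in range(s.size)]
    scores = pd.DataFrame(U * s, index=df.index, columns=comp_names)
    loadings = pd.DataFrame(Vt.T, index=df.columns, columns=comp_names)
    return PCAResult(scores, loadings, (s**2) / total, degenerate=False)
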