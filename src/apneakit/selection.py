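"""Dimensionality-reduction analyses over an epoch feature table.

The selection procedure: z-score the features on training statistics,
eigendecompose the sample covariance (PCA), keep the smallest set of
leading components reaching a cumulative-variance target, and retain the
features that weigh most (largest |loading|) within those components.
Class structure is summarized by a dendrogram over the class mean vectors
under the pooled within-class Mahalanobis metric (the distance structure a
one-way MANOVA is built on), plus the Pearson correlation matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


def zscore(table: pd.DataFrame, stats_from: np.ndarray | None = None) -> pd.DataFrame:
    """Standardize each column with mean/SD (ddof=1) computed on the
    ``stats_from`` row mask (the training split); zero-SD columns are
    dropped with a warning."""
    if table.shape[0] == 0:
        raise ValueError("empty table")
    ref = table if stats_from is None else table.loc[np.asarray(stats_from)]
    mu = ref.mean(axis=0)
    sd = ref.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        dropped = list(table.columns[~keep.to_numpy()])
        warnings.warn(f"dropping zero-variance columns: {dropped}")
    return (table.loc[:, keep.to_numpy()] - mu[keep]) / sd[keep]


@dataclass
class PCASelectionResult:
    """Loadings (features x components), explained-variance fractions and,
    after :func:`select_by_loadings`, the retained feature names."""

    feature_names: list[str]
    loadings: np.ndarray
    explained: np.ndarray
    retained: list[str] = field(default_factory=list)
    n_pcs_used: int = 0

    @property
    def cumulative(self) -> np.ndarray:
        return np.cumsum(self.explained)


def pca_covariance(table: pd.DataFrame) -> PCASelectionResult:
    """PCA via eigendecomposition of the sample covariance matrix.

    Components are ordered by decreasing eigenvalue; each column is signed
    so its largest-magnitude loading is positive.
    """
    X = table.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature table")
    cov = np.cov(X, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] = -eigvec[:, j]
    total = eigval.sum()
    explained = eigval / total if total > 0 else eigval
    return PCASelectionResult(list(table.columns), eigvec, explained)


def select_by_loadings(
    result: PCASelectionResult, var_target: float = 0.9, top_k_per_pc: int = 10
) -> list[str]:
    """Retain the union, over the smallest leading-PC set reaching
    ``var_target`` cumulative variance, of each PC's ``top_k_per_pc``
    features by |loading|; ordered by first PC of appearance then
    |loading| descending.  Also recorded on ``result``."""
    if not 0 < var_target <= 1:
        raise ValueError("var_target must lie in (0, 1]")
    cum = result.cumulative
    n_pcs = int(np.searchsorted(cum, var_target - 1e-12) + 1)
    n_pcs = min(n_pcs, len(result.explained))
    names = np.array(result.feature_names)
    retained: list[str] = []
    for j in range(n_pcs):
        w = np.abs(result.loadings[:, j])
        top = np.argsort(-w, kind="stable")[:top_k_per_pc]
        top = top[np.argsort(-w[top], kind="stable")]
        for idx in top:
            if names[idx] not in retained:
                retained.append(str(names[idx]))
    result.retained = retained
    result.n_pcs_used = n_pcs
    return retained


@dataclass
class ClassDendrogram:
    """Complete-linkage merge tree over class means in the pooled
    within-class Mahalanobis metric."""

    labels: list[str]
    distance_matrix: np.ndarray  # condensed-form square matrix
    linkage: np.ndarray  # scipy linkage matrix (k-1 merges)
    wilks_lambda: float | None = None

    def first_split(self) -> tuple[set[str], set[str]]:
        """The two leaf groups separated by the final (root) merge."""
        n = len(self.labels)
        members: dict[int, set[int]] = {i: {i} for i in range(n)}
        for k, (a, b, _, _) in enumerate(self.linkage):
            members[n + k] = members[int(a)] | members[int(b)]
        a, b = int(self.linkage[-1, 0]), int(self.linkage[-1, 1])
        return (
            {self.labels[i] for i in members[a]},
            {self.labels[i] for i in members[b]},
        )

    def to_newick(self) -> str:
        n = len(self.labels)
        nodes: dict[int, str] = {i: self.labels[i] for i in range(n)}
        heights: dict[int, float] = {i: 0.0 for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage):
            a, b = int(a), int(b)
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            nodes[n + k] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + k] = h
        return nodes[n + len(self.linkage) - 1] + ";"


def pooled_within_covariance(X: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Pooled within-class covariance S_W = sum_k (n_k - 1) S_k / (N - K)."""
    classes = np.unique(labels)
    p = X.shape[1]
    sw = np.zeros((p, p))
    n_total = 0
    for c in classes:
        Xc = X[labels == c]
        if len(Xc) < 2:
            raise ValueError(f"class {c!r} needs at least 2 rows")
        sw += (len(Xc) - 1) * np.cov(Xc, rowvar=False, ddof=1)
        n_total += len(Xc)
    return sw / (n_total - len(classes))


def mahalanobis_class_distances(
    X: np.ndarray, labels: np.ndarray
) -> tuple[list[str], np.ndarray]:
    """Pairwise Mahalanobis distances between class mean vectors under the
    pooled within-class covariance.  A ridge of 1e-6 * trace/p is added if
    the pooled covariance is singular."""
    labels = np.asarray(labels)
    # globally constant features carry no class information and make the
    # pooled covariance exactly singular; drop them up front
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    classes = [str(c) for c in np.unique(labels)]
    means = np.stack([X[labels == c].mean(axis=0) for c in classes])
    sw = pooled_within_covariance(X, labels)
    p = sw.shape[0]
    eigvals = np.linalg.eigvalsh(sw)
    if eigvals[0] <= 1e-10 * max(eigvals[-1], 1e-300):
        warnings.warn("ill-conditioned pooled covariance; adding ridge 1e-6 * trace/p")
        sw = sw + 1e-6 * np.trace(sw) / p * np.eye(p)
    cho = np.linalg.cholesky(sw)
    k = len(classes)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            d = means[i] - means[j]
            z = np.linalg.solve(cho, d)
            D[i, j] = D[j, i] = float(np.sqrt(z @ z))
    return classes, D


def wilks_lambda(X: np.ndarray, labels: np.ndarray) -> float:
    """Wilks' Lambda = |W| / |W + B| for the one-way multivariate layout."""
    labels = np.asarray(labels)
    classes = np.unique(labels)
    grand = X.mean(axis=0)
    W = np.zeros((X.shape[1],) * 2)
    B = np.zeros_like(W)
    for c in classes:
        Xc = X[labels == c]
        mc = Xc.mean(axis=0)
        W += (Xc - mc).T @ (Xc - mc)
        B += len(Xc) * np.outer(mc - grand, mc - grand)
    sign_w, logdet_w = np.linalg.slogdet(W)
    sign_t, logdet_t = np.linalg.slogdet(W + B)
    if sign_w <= 0 or sign_t <= 0:
        return float("nan")
    return float(np.exp(logdet_w - logdet_t))


def manova_dendrogram(table: pd.DataFrame, labels: Sequence[str]) -> ClassDendrogram:
    """Dendrogram of class means: Mahalanobis distances under the pooled
    within-class covariance, complete-linkage agglomeration.  Wilks' Lambda
    is reported alongside; the pipeline consumes only the merge structure."""
    X = table.to_numpy(dtype=float)
    labels = np.asarray([str(l) for l in labels])
    if len(np.unique(labels)) < 2:
        raise ValueError("need at least 2 classes")
    classes, D = mahalanobis_class_distances(X, labels)
    Z = hierarchy.linkage(squareform(D, checks=False), method="complete")
    return ClassDendrogram(classes, D, Z, wilks_lambda=wilks_lambda(X, labels))


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix with unit diagonal; zero-variance columns
    get zero off-diagonal entries (flagged via warning)."""
    X = table.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite values in feature table")
    sd = X.std(axis=0, ddof=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"zero-variance columns in correlation matrix: {list(table.columns[degenerate])}"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C = np.where(np.isfinite(C), C, 0.0)
    np.fill_diagonal(C, 1.0)
    return pd.DataFrame(C, index=table.columns, columns=table.columns)
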