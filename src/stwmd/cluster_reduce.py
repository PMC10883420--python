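"""Gene-class discovery: k-means clustering of DEG profiles and per-class
first-principal-component (eigen-feature) extraction.

Clustering operates on z-scored gene profiles across stage-samples.  An
optional 2-D embedding (t-SNE or UMAP) can precede k-means for parity with
visual workflows; the full-dimensional profiles are the reproducible
default.  ``k`` is selected by maximal mean silhouette over a configured
range unless pinned.  Classes are labelled ClusterA, ClusterB, ... in
decreasing size order (ties by smallest gene index) so the naming is
deterministic.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .errors import ConfigurationError


@dataclass
class GeneClustering:
    genes: list[str]
    k: int
    labels: pd.Series  # gene -> ClusterX
    sizes: pd.Series  # ClusterX -> size
    k_selection: dict[int, float]  # candidate k -> mean silhouette
    seed: int
    embedding: pd.DataFrame | None = None

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    @property
    def class_labels(self) -> list[str]:
        return list(self.sizes.index)


@dataclass
class ClusterComponents:
    """Per-class PC1 scores over stage-samples and variance-contribution rates."""

    scores: pd.DataFrame  # samples x classes
    vcr: pd.Series  # class -> fraction of class variance explained by PC1
    low_vcr: list[str]  # classes below the 50% adequacy benchmark


def _cluster_name(i: int) -> str:
    if i < 26:
        return f"Cluster{string.ascii_uppercase[i]}"
    return f"Cluster{i + 1}"


def _zscore_rows(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, keepdims=True)
    sd = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd


def cluster_genes(
    matrix: pd.DataFrame,
    *,
    k: int | None = None,
    k_range: tuple[int, int] = (2, 8),
    embedding: str = "none",
    seed: int = 0,
    n_init: int = 10,
) -> GeneClustering:
    """Group genes (rows of ``matrix``) into k classes by k-means.

    ``matrix`` is genes x stage-samples; rows are z-scored before anything
    else so clustering sees profile shapes, not absolute levels.
    """
    genes = list(matrix.index)
    X = _zscore_rows(matrix.to_numpy(dtype=float))
    n = len(genes)

    emb_frame = None
    if embedding == "tsne":
        from sklearn.manifold import TSNE

        perplexity = min(30.0, max(2.0, (n - 1) / 3.0))
        coords = TSNE(
            n_components=2, random_state=seed, perplexity=perplexity, init="pca"
        ).fit_transform(X)
        emb_frame = pd.DataFrame(coords, index=genes, columns=["dim1", "dim2"])
        X = coords
    elif embedding == "umap":
        import umap

        coords = umap.UMAP(n_components=2, random_state=seed).fit_transform(X)
        emb_frame = pd.DataFrame(np.asarray(coords), index=genes, columns=["dim1", "dim2"])
        X = np.asarray(coords)
    elif embedding != "none":
        raise ConfigurationError(f"unknown embedding {embedding!r}")

    k_selection: dict[int, float] = {}
    if k is None:
        lo, hi = k_range
        candidates = [kk for kk in range(lo, hi + 1) if 2 <= kk <= n - 1]
        if not candidates:
            raise ConfigurationError(
                f"no feasible k in range {k_range} for {n} genes"
            )
        best_k, best_score = None, -np.inf
        for kk in candidates:
            km = KMeans(n_clusters=kk, n_init=n_init, random_state=seed).fit(X)
            score = float(silhouette_score(X, km.labels_))
            k_selection[kk] = score
            if score > best_score:
                best_k, best_score = kk, score
        k = best_k
    elif not 1 <= k <= n:
        raise ConfigurationError(f"k={k} infeasible for {n} genes")

    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    raw = km.labels_

    # deterministic naming: decreasing size, ties by smallest member index
    order = sorted(
        range(k),
        key=lambda c: (-int((raw == c).sum()), int(np.nonzero(raw == c)[0][0])),
    )
    name_of = {c: _cluster_name(i) for i, c in enumerate(order)}
    labels = pd.Series([name_of[c] for c in raw], index=genes, name="cluster")
    sizes = labels.value_counts().reindex([_cluster_name(i) for i in range(k)])

    return GeneClustering(
        genes=genes,
        k=int(k),
        labels=labels,
        sizes=sizes,
        k_selection=k_selection,
        seed=seed,
        embedding=emb_frame,
    )


def cluster_pc1(matrix: pd.DataFrame, clustering: GeneClustering) -> ClusterComponents:
    """First principal component of each gene class across stage-samples.

    PCA runs on the samples x class-genes submatrix (genes centered), so the
    PC1 score vector is one coordinate per stage-sample with zero mean.  The
    sign is fixed so PC1 correlates nonnegatively with the class's mean
    expression profile.  The variance-contribution rate (VCR) is the fraction
    of the class's variance explained by PC1; classes below 50% are flagged
    as inadequately summarized by a single component.
    """
    samples = list(matrix.columns)
    scores = {}
    vcr = {}
    for label in clustering.class_labels:
        members = clustering.members(label)
        if not members:
            raise ConfigurationError(f"class {label} is empty")
        X = matrix.loc[members].to_numpy(dtype=float).T  # samples x genes
        pca = PCA(n_components=1)
        s = pca.fit_transform(X)[:, 0]
        ratio = float(pca.explained_variance_ratio_[0])
        mean_profile = X.mean(axis=1)
        centered = mean_profile - mean_profile.mean()
        if float(np.dot(s, centered)) < 0:
            s = -s
        scores[label] = s
        vcr[label] = ratio
    frame = pd.DataFrame(scores, index=samples)
    vcr_series = pd.Series(vcr, name="vcr")
    low = list(vcr_series.index[vcr_series < 0.5])
    return ClusterComponents(scores=frame, vcr=vcr_series, low_vcr=low)
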