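"""Spectral clustering of relevance maps (SpRAy-style) with eigengap model
selection, plus a 2-D embedding for visualization.

Maps are mean-pooled to a coarse grid, flattened, and connected in a
symmetrized k-nearest-neighbor graph with Gaussian edge weights (bandwidth =
median neighbor distance). The number of decision strategies k is estimated
from the spectrum of the symmetric normalized Laplacian: at least the number
of (near-)connected components, otherwise the largest eigengap between
consecutive eigenvalues up to ``max_clusters``. Cluster labels come from
seeded k-means on the row-normalized leading eigenvectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import eigh
from sklearn.cluster import KMeans
from sklearn.manifold import TSNE

from .lrp import RelevanceMap

__all__ = [
    "ClusterConfig",
    "ClusterResult",
    "build_affinity",
    "spectral_cluster",
    "embed_2d",
]


@dataclass(frozen=True)
class ClusterConfig:
    downsample_shape: tuple[int, int, int] = (8, 8, 8)
    k_neighbors: int = 10
    max_clusters: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.max_clusters < 2:
            raise ValueError("max_clusters must be >= 2")


@dataclass
class ClusterResult:
    labels: np.ndarray  # cluster label per map, 1..k
    eigenvalues: np.ndarray  # non-decreasing Laplacian spectrum
    k: int
    embedding: np.ndarray | None = None  # optional 2-D coordinates


def _pool(map_: RelevanceMap, target: tuple[int, int, int]) -> np.ndarray:
    r = map_.R
    if any(s % t != 0 for s, t in zip(r.shape, target)):
        raise ValueError(f"map shape {r.shape} not divisible by pool target {target}")
    f = [s // t for s, t in zip(r.shape, target)]
    return r.reshape(
        target[0], f[0], target[1], f[1], target[2], f[2]
    ).mean(axis=(1, 3, 5)).ravel()


def _features(maps: Sequence[RelevanceMap], config: ClusterConfig) -> np.ndarray:
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("maps are on different grids")
    return np.stack([_pool(m, config.downsample_shape) for m in maps])


def build_affinity(maps: Sequence[RelevanceMap], config: ClusterConfig = ClusterConfig()) -> np.ndarray:
    """Symmetrized k-NN Gaussian affinity over pooled, flattened maps."""
    feats = _features(maps, config)
    n = len(feats)
    if n < config.k_neighbors + 1:
        raise ValueError(
            f"need more than k_neighbors={config.k_neighbors} maps, got {n}"
        )
    d2 = np.maximum(
        np.sum(feats**2, axis=1)[:, None]
        + np.sum(feats**2, axis=1)[None, :]
        - 2 * feats @ feats.T,
        0.0,
    )
    dist = np.sqrt(d2)
    np.fill_diagonal(dist, np.inf)
    knn_idx = np.argsort(dist, axis=1)[:, : config.k_neighbors]
    neighbor_d = np.take_along_axis(dist, knn_idx, axis=1)
    sigma = float(np.median(neighbor_d[np.isfinite(neighbor_d)]))
    if sigma <= 0:
        sigma = 1.0  # all maps identical: every kept edge gets weight 1
    w = np.zeros((n, n))
    rows = np.repeat(np.arange(n), config.k_neighbors)
    cols = knn_idx.ravel()
    w[rows, cols] = np.exp(-(dist[rows, cols] ** 2) / (2 * sigma**2))
    w = np.maximum(w, w.T)
    np.fill_diagonal(w, 0.0)
    return w


def _normalized_laplacian(affinity: np.ndarray) -> np.ndarray:
    deg = affinity.sum(axis=1)
    inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(np.where(deg > 0, deg, 1.0)), 0.0)
    lap = np.eye(len(affinity)) - inv_sqrt[:, None] * affinity * inv_sqrt[None, :]
    return (lap + lap.T) / 2.0


def spectral_cluster(
    affinity: np.ndarray,
    config: ClusterConfig = ClusterConfig(),
    force_k: int | None = None,
) -> ClusterResult:
    """Cluster from an affinity matrix; k by eigengap unless forced."""
    n = len(affinity)
    lap = _normalized_laplacian(affinity)
    eigenvalues, eigenvectors = eigh(lap)
    n_components = int(np.sum(eigenvalues < 1e-8))
    if force_k is not None:
        k = force_k
    else:
        # eigengap: candidate k requires the k-th smallest eigenvalue to be
        # small (k near-zero eigenvalues ~ k loosely coupled groups); among
        # candidates pick the largest gap to the next eigenvalue
        kmax = min(config.max_clusters, n - 1)
        candidates = [
            kk for kk in range(2, kmax + 1) if eigenvalues[kk - 1] < 0.5
        ]
        if candidates:
            gaps = {kk: eigenvalues[kk] - eigenvalues[kk - 1] for kk in candidates}
            k = max(gaps, key=gaps.get)
        else:
            k = 1
        k = max(k, n_components, 1)
    if k == 1:
        labels = np.ones(n, dtype=int)
    else:
        vec = eigenvectors[:, :k]
        norms = np.linalg.norm(vec, axis=1, keepdims=True)
        vec = vec / np.where(norms > 0, norms, 1.0)
        km = KMeans(n_clusters=k, n_init=10, random_state=config.seed)
        labels = km.fit_predict(vec) + 1
    return ClusterResult(labels=labels, eigenvalues=eigenvalues, k=k)


def embed_2d(
    maps: Sequence[RelevanceMap], config: ClusterConfig = ClusterConfig()
) -> np.ndarray:
    """Seeded t-SNE coordinates of the pooled maps, one (x, y) per map."""
    feats = _features(maps, config)
    if len(feats) < 3:
        raise ValueError("need at least three maps to embed")
    perplexity = float(min(30.0, max(2.0, (len(feats) - 2) / 3.0)))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=config.seed,
    )
    return tsne.fit_transform(feats)
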