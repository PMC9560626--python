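"""Normalization, downsampling and 2-D embedding of the training sample.

Density estimation is unreliable in the original 30-50 dimensional marker
space, so the pipeline z-scores a uniform downsample of the data and
projects it to two dimensions with a nonlinear embedding (t-SNE by default,
UMAP selectable).  The normalizer is fit on the downsample only and reused
at prediction time; the full dataset is never preprocessed globally.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

logger = logging.getLogger(__name__)

__all__ = [
    "Normalizer",
    "EmbeddingModel",
    "fit_normalizer",
    "downsample",
    "fit_embedding",
]


@dataclass
class Normalizer:
    """Per-feature z-score transform with a floor on the standard deviation.

    Standard deviations use the population convention (ddof=0).  Features
    whose sd falls below ``floor`` (effectively constant columns) keep
    ``sd = 1`` so they pass through centered but unscaled.
    """

    means: np.ndarray
    sds: np.ndarray
    floor: float = 1e-8

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.shape[1] != self.means.shape[0]:
            raise ValueError(
                f"feature count mismatch: normalizer has {self.means.shape[0]}, "
                f"input has {X.shape[1]}"
            )
        return (X - self.means) / self.sds


def fit_normalizer(X: np.ndarray, floor: float = 1e-8) -> Normalizer:
    """Fit a z-score normalizer on ``X`` (population sd, ddof=0)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a 2-D matrix with at least 2 rows")
    if floor <= 0:
        raise ValueError("floor must be positive")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=0)
    sds = np.where(sds < floor, 1.0, sds)
    return Normalizer(means=means, sds=sds, floor=floor)


def downsample(X: np.ndarray, target_size: Optional[int] = None, seed: int = 0) -> np.ndarray:
    """Uniform random row indices without replacement.

    Defaults to ``min(n_points, 100000)`` — a downsample of one to two
    hundred thousand events is enough to learn a stable embedding for
    cytometry-scale data.  A ``target_size`` exceeding the number of rows is
    clipped with a warning.
    """
    n = np.asarray(X).shape[0]
    if target_size is None:
        target_size = min(n, 100_000)
    if target_size <= 0:
        raise ValueError("target_size must be positive")
    if target_size > n:
        logger.warning("target_size %d exceeds n_points %d; clipping", target_size, n)
        target_size = n
    rng = np.random.default_rng(seed)
    return rng.choice(n, size=target_size, replace=False)


@dataclass
class EmbeddingModel:
    """A fitted 2-D embedding of the normalized downsample."""

    method: str
    params: dict = field(default_factory=dict)
    train_coords: np.ndarray = None
    train_indices: Optional[np.ndarray] = None
    pca_components: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.train_coords is not None and self.train_coords.shape[1] != 2:
            raise ValueError("train_coords must have exactly 2 columns")


def _embed_tsne(X: np.ndarray, params: dict, seed: int) -> np.ndarray:
    perplexity = float(params.get("perplexity", 30.0))
    n = X.shape[0]
    if n <= 3 * perplexity:
        raise ValueError(
            f"t-SNE requires n_points > 3*perplexity; got n={n} with "
            f"perplexity={perplexity} (reduce perplexity or provide more points)"
        )
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        init="pca",
        random_state=seed,
        max_iter=int(params.get("max_iter", 500)),
    )
    return np.asarray(tsne.fit_transform(X), dtype=np.float64)


def _embed_umap(X: np.ndarray, params: dict, seed: int) -> np.ndarray:
    import umap  # deferred: slow import, only needed for this backend

    n_neighbors = int(params.get("n_neighbors", 15))
    if X.shape[0] <= n_neighbors:
        raise ValueError(
            f"UMAP requires n_points > n_neighbors; got n={X.shape[0]} with "
            f"n_neighbors={n_neighbors}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reducer = umap.UMAP(
            n_components=2,
            n_neighbors=n_neighbors,
            min_dist=float(params.get("min_dist", 0.1)),
            random_state=seed,
        )
        coords = reducer.fit_transform(X)
    return np.asarray(coords, dtype=np.float64)


def _embed_pca(X: np.ndarray, params: dict, seed: int) -> np.ndarray:
    # Linear fallback backend: deterministic and fast, adequate when cluster
    # structure is already visible in the top two principal components.
    return np.asarray(
        PCA(n_components=2, random_state=seed).fit_transform(X), dtype=np.float64
    )


_BACKENDS = {"tsne": _embed_tsne, "umap": _embed_umap, "pca": _embed_pca}


def fit_embedding(
    X_norm: np.ndarray,
    method: str = "tsne",
    params: Optional[dict] = None,
    n_pcs: Optional[int] = None,
    seed: int = 0,
    train_indices: Optional[np.ndarray] = None,
) -> EmbeddingModel:
    """Project the normalized downsample to a 2-D map.

    An optional PCA projection to ``n_pcs`` dimensions precedes the
    nonlinear step (useful for strongly correlated features; off by
    default).  Backends share one contract: matrix in, 2-column matrix out,
    deterministic under ``seed`` where the backend supports it.

    Parameters
    ----------
    X_norm : ndarray
        Normalized downsample (rows = points).
    method : {"tsne", "umap", "pca"}
        Embedding backend; t-SNE is the default because it preserves the
        local ordination density estimation relies on.
    params : dict, optional
        Backend parameters (``perplexity`` for t-SNE, ``n_neighbors`` /
        ``min_dist`` for UMAP).
    n_pcs : int, optional
        If given, linearly project to this many PCs first.
    """
    X_norm = np.asarray(X_norm, dtype=np.float64)
    params = dict(params or {})
    if method not in _BACKENDS:
        raise ValueError(f"unknown embedding method {method!r}; choose from {sorted(_BACKENDS)}")
    pca_components = None
    X_in = X_norm
    if n_pcs is not None:
        if n_pcs > X_norm.shape[1]:
            raise ValueError("n_pcs cannot exceed n_features")
        pca = PCA(n_components=n_pcs, random_state=seed).fit(X_norm)
        pca_components = pca.components_.T
        X_in = X_norm @ pca_components
    coords = _BACKENDS[method](X_in, params, seed)
    return EmbeddingModel(
        method=method,
        params=params,
        train_coords=coords,
        train_indices=None if train_indices is None else np.asarray(train_indices),
        pca_components=pca_components,
    )
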