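"""Synthetic data generators used as fixtures and benchmarks.

Two families are provided:

* cytometry-scale Gaussian mixtures (tens of features, 10^3-10^7 points),
  emulating the structure of mass-cytometry expression matrices where each
  cell population is approximately a Gaussian cloud in marker space;
* the classic six two-dimensional clustering benchmark families popularised
  by the scikit-learn clustering demo page (noisy circles, noisy moons,
  isotropic / varied-covariance / anisotropic blobs, and structureless
  uniform noise).

All generators take an explicit integer seed and never touch global RNG
state, so fixtures are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from sklearn import datasets as _skdata

__all__ = ["LabeledDataset", "make_gaussian_mixture", "make_benchmark_2d", "BENCHMARK_KINDS"]

BENCHMARK_KINDS = (
    "noisy_circles",
    "noisy_moons",
    "blobs",
    "varied_blobs",
    "aniso_blobs",
    "no_structure",
)


@dataclass
class LabeledDataset:
    """A numeric matrix with optional ground-truth labels.

    Attributes
    ----------
    X : ndarray of shape (n_points, n_features)
        The data matrix.  Never contains NaN/Inf.
    y : ndarray of shape (n_points,) or None
        Integer class labels; -1 marks noise / no class.  ``None`` when the
        generator has no ground truth (e.g. structureless noise).
    seed : int
        Seed used to generate the data.
    meta : dict
        Generator name and parameter record.
    """

    X: np.ndarray
    y: Optional[np.ndarray] = None
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")
        if self.y is not None:
            self.y = np.asarray(self.y, dtype=np.int64)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("y length does not match number of points")

    @property
    def n_points(self) -> int:
        return self.X.shape[0]

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


def make_gaussian_mixture(
    n_points: int,
    n_features: int = 30,
    n_clusters: int = 10,
    separation: float = 10.0,
    cov_spread: float = 0.5,
    weights: Optional[np.ndarray] = None,
    seed: int = 0,
) -> LabeledDataset:
    """Sample a Gaussian mixture with tunable component overlap.

    Component centers are drawn i.i.d. from N(0, separation^2 * I), so
    ``separation`` directly controls how far apart clusters sit relative to
    their unit base covariance.  Each component's covariance is an isotropic
    unit covariance scaled by ``(1 + cov_spread * u)`` with
    ``u ~ Uniform(0, 1)``, giving clusters of visibly different sizes when
    ``cov_spread > 0``.

    Parameters
    ----------
    n_points, n_features, n_clusters : int
        Matrix size and number of mixture components.
    separation : float
        Standard deviation of the center distribution; larger values mean
        better-separated clusters.
    cov_spread : float
        Relative spread of per-component covariance scales (0 = identical).
    weights : array-like, optional
        Mixture weights (must sum to 1 within 1e-9); uniform if omitted.
    seed : int
        RNG seed; identical arguments give bit-identical output.

    Returns
    -------
    LabeledDataset
        ``y`` records the generating component of each row; ``meta`` stores
        the generating centers and covariance scales for oracle tests.
    """
    if n_points <= 0 or n_features <= 0 or n_clusters <= 0:
        raise ValueError("n_points, n_features and n_clusters must be positive")
    if n_clusters > n_points:
        raise ValueError("n_clusters cannot exceed n_points")
    if separation <= 0:
        raise ValueError("separation must be positive")
    if cov_spread < 0:
        raise ValueError("cov_spread must be nonnegative")
    if weights is None:
        w = np.full(n_clusters, 1.0 / n_clusters)
    else:
        w = np.asarray(weights, dtype=np.float64)
        if w.shape != (n_clusters,):
            raise ValueError(f"weights must have length {n_clusters}, got {w.shape}")
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1 within 1e-9")

    rng = np.random.default_rng(seed)
    centers = rng.normal(0.0, separation, size=(n_clusters, n_features))
    cov_scales = 1.0 + cov_spread * rng.uniform(size=n_clusters)
    y = rng.choice(n_clusters, size=n_points, p=w)
    X = rng.standard_normal((n_points, n_features))
    X *= np.sqrt(cov_scales)[y, None]
    X += centers[y]
    meta = {
        "generator": "gaussian_mixture",
        "n_clusters": n_clusters,
        "separation": separation,
        "cov_spread": cov_spread,
        "centers": centers,
        "cov_scales": cov_scales,
    }
    return LabeledDataset(X=X, y=y, seed=seed, meta=meta)


def make_benchmark_2d(
    kind: str,
    n_points: int = 1500,
    noise: float = 0.05,
    seed: int = 0,
) -> LabeledDataset:
    """Generate one of the six standard 2-D clustering benchmark datasets.

    ``no_structure`` is uniform noise on the unit square and carries no
    labels (``y is None``): it serves as a negative control and evaluation
    code must handle unlabeled data explicitly.

    Parameters
    ----------
    kind : str
        One of ``noisy_circles``, ``noisy_moons``, ``blobs``,
        ``varied_blobs``, ``aniso_blobs``, ``no_structure``.
    n_points : int
        Number of points (>= 10).
    noise : float
        Noise level for circles/moons (ignored for the blob families).
    seed : int
        RNG seed.
    """
    if kind not in BENCHMARK_KINDS:
        raise ValueError(f"unknown benchmark kind {kind!r}; choose from {BENCHMARK_KINDS}")
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    if noise < 0:
        raise ValueError("noise must be nonnegative")

    y: Optional[np.ndarray]
    if kind == "noisy_circles":
        X, y = _skdata.make_circles(
            n_samples=n_points, factor=0.5, noise=noise, random_state=seed
        )
    elif kind == "noisy_moons":
        X, y = _skdata.make_moons(n_samples=n_points, noise=noise, random_state=seed)
    elif kind == "blobs":
        X, y = _skdata.make_blobs(n_samples=n_points, random_state=seed)
    elif kind == "varied_blobs":
        X, y = _skdata.make_blobs(
            n_samples=n_points, cluster_std=[1.0, 2.5, 0.5], random_state=seed
        )
    elif kind == "aniso_blobs":
        X, y = _skdata.make_blobs(n_samples=n_points, random_state=seed)
        transform = np.array([[0.6, -0.6], [-0.4, 0.8]])
        X = X @ transform
    else:  # no_structure
        rng = np.random.default_rng(seed)
        X = rng.uniform(size=(n_points, 2))
        y = None
    meta = {"generator": "benchmark_2d", "kind": kind, "noise": noise}
    return LabeledDataset(X=np.asarray(X, dtype=np.float64), y=y, seed=seed, meta=meta)
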