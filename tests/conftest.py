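"""Shared fixtures: synthetic datasets and session-scoped fitted models.

Fitting a full model (embedding + density stage + supervised agglomeration)
is the expensive part of the suite, so the two models used across the
prediction / acceptance tests are built once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from halclust import RunConfig, fit_pipeline, make_gaussian_mixture


@pytest.fixture(scope="session")
def blob8_dataset():
    """8 well-separated Gaussian components in 30-D, 20k points."""
    return make_gaussian_mixture(
        n_points=20_000, n_features=30, n_clusters=8, separation=10.0, seed=3
    )


@pytest.fixture(scope="session")
def blob8_model(blob8_dataset):
    """Default pipeline (t-SNE embedding) fit on a 3000-point downsample."""
    cfg = RunConfig(seed=1, downsample_size=3000)
    return fit_pipeline(blob8_dataset.X, cfg)


def make_overlap_trio(seed: int = 5, n_per: int = 3000, delta: float = 4.0):
    """Three 30-D unit Gaussians: A and B overlap, C is far away.

    A and B sit ``delta`` standard deviations apart (the offset spread over
    eight features, as marker shifts are in cytometry), so their
    Bayes-optimal pairwise accuracy is Phi(delta/2); ``delta`` is calibrated
    so the measured random-forest out-of-sample accuracy lands near 0.975,
    engineering a merge whose edge score falls between cv 0.97 and 0.98.
    C is ~16 sd away from both and perfectly separable.
    """
    rng = np.random.default_rng(seed)
    d = 30
    a = rng.standard_normal((n_per, d))
    b = rng.standard_normal((n_per, d))
    b[:, :8] += delta / np.sqrt(8)
    c = rng.standard_normal((n_per, d))
    c[:, 10:20] += 5.0
    X = np.vstack([a, b, c])
    y = np.repeat([0, 1, 2], n_per)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


@pytest.fixture(scope="session")
def overlap_model():
    """Fitted model on the engineered A/B-overlap fixture (PCA embedding)."""
    X, y = make_overlap_trio()
    cfg = RunConfig(
        seed=2,
        downsample_size=3000,
        embedding={"method": "pca", "params": {}, "n_pcs": None},
    )
    model = fit_pipeline(X, cfg)
    return model, X, y
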