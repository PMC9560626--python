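"""End-to-end training pipeline and run configuration.

``fit_pipeline`` composes the stages: uniform downsample -> z-score
normalization (fit on the downsample only) -> 2-D embedding -> held-out
bandwidth selection -> neighbor graph -> pure-cluster detection ->
extended-neighborhood merge -> supervised agglomeration, and returns the
trained model (merge tree + normalizer) that labels arbitrarily many
unreduced points.  Every stage logs its parameters, sizes and timing, and
the canonical config hash is stored in the model for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from typing import Optional

import numpy as np

from halclust.density import (
    approx_knn,
    extended_neighborhood_merge,
    find_pure_clusters,
    select_bandwidth,
)
from halclust.embedding import downsample, fit_embedding, fit_normalizer
from halclust.io import FittedModel, save_model
from halclust.linkage import agglomerate

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "fit_pipeline"]


@dataclass
class RunConfig:
    """All pipeline parameters, serializable to a canonical hashed form."""

    seed: int = 0
    downsample_size: Optional[int] = None  # None -> min(n, 100000)
    embedding: dict = field(default_factory=lambda: {"method": "tsne", "params": {},
                                                     "n_pcs": None})
    density: dict = field(default_factory=lambda: {
        "purity_threshold": 0.99,
        "neighbor_fraction": 0.02,
        "relax_factor": 2.0,
        "purity_drop": 0.05,
        "knn_method": "exact",
    })
    linkage: dict = field(default_factory=lambda: {
        "k": 3,
        "n_bootstrap": 10,
        "classifier": {"kind": "rf", "n_estimators": 100, "train_cap": 5000},
        "min_cluster_size": 12,
    })
    input: Optional[str] = None
    output: Optional[str] = None

    def canonical_json(self) -> str:
        rec = asdict(self)
        rec.pop("input", None)
        rec.pop("output", None)
        return json.dumps(rec, sort_keys=True, separators=(",", ":"))

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]


def _stage(name: str, start: float) -> float:
    now = time.perf_counter()
    logger.info("[%s] done in %.2fs", name, now - start)
    return now


def fit_pipeline(
    X: np.ndarray,
    config: Optional[RunConfig] = None,
    save_to: Optional[str] = None,
) -> FittedModel:
    """Train a clustering model on ``X`` under ``config``.

    Parameters
    ----------
    X : ndarray of shape (n_points, n_features)
        Raw (untransformed) data matrix.
    config : RunConfig, optional
        Pipeline parameters; defaults are suitable for cytometry-like data.
    save_to : str, optional
        If given, the fitted model archive is written here (overrides
        ``config.output``).

    Returns
    -------
    FittedModel
        Merge tree + normalizer; feed to :func:`halclust.predict` /
        :func:`halclust.sweep_cv_scores`.
    """
    cfg = config or RunConfig()
    X = np.asarray(X, dtype=np.float64)
    t = time.perf_counter()
    logger.info("fit: n=%d, d=%d, config=%s", X.shape[0], X.shape[1], cfg.config_hash)

    idx = downsample(X, cfg.downsample_size, seed=cfg.seed)
    X_sub = X[idx]
    t = _stage(f"downsample (kept {len(idx)})", t)

    normalizer = fit_normalizer(X_sub)
    X_norm = normalizer.transform(X_sub)
    t = _stage("normalize", t)

    emb = fit_embedding(
        X_norm,
        method=cfg.embedding.get("method", "tsne"),
        params=cfg.embedding.get("params"),
        n_pcs=cfg.embedding.get("n_pcs"),
        seed=cfg.seed,
        train_indices=idx,
    )
    coords = emb.train_coords
    t = _stage(f"embedding ({emb.method})", t)

    bw = select_bandwidth(coords, seed=cfg.seed)
    t = _stage(f"bandwidth (h={bw.h:.4g})", t)

    graph = approx_knn(
        coords,
        neighbor_fraction=cfg.density.get("neighbor_fraction", 0.02),
        method=cfg.density.get("knn_method", "exact"),
        seed=cfg.seed,
    )
    t = _stage(f"knn (m={graph.m})", t)

    dm = find_pure_clusters(
        coords, graph, bw.h,
        purity_threshold=cfg.density.get("purity_threshold", 0.99),
    )
    t = _stage(f"pure clusters ({dm.n_clusters} modes)", t)

    dm = extended_neighborhood_merge(
        dm, coords,
        relax_factor=cfg.density.get("relax_factor", 2.0),
        purity_drop=cfg.density.get("purity_drop", 0.05),
        seed=cfg.seed,
        graph=graph,
        knn_method=cfg.density.get("knn_method", "exact"),
    )
    t = _stage(f"extended merge ({dm.n_clusters} clusters)", t)

    tree = agglomerate(
        X_norm,
        dm.labels,
        k=cfg.linkage.get("k", 3),
        classifier_spec=cfg.linkage.get("classifier"),
        n_bootstrap=cfg.linkage.get("n_bootstrap", 10),
        seed=cfg.seed,
        min_cluster_size=cfg.linkage.get("min_cluster_size", 12),
    )
    t = _stage(f"agglomeration ({tree.n_leaves} leaves)", t)

    model = FittedModel(tree=tree, normalizer=normalizer,
                        config=json.loads(cfg.canonical_json()),
                        seed=cfg.seed, config_hash=cfg.config_hash,
                        train_indices=idx, train_labels=dm.labels.copy())
    out = save_to or cfg.output
    if out:
        save_model(model, out)
        logger.info("model written to %s", out)
    return model
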