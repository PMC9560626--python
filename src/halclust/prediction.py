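"""Label new points by descending the merge tree with the stored ensembles.

A point starts at the root and, while the current node's cv-score exceeds
the user's threshold, is routed to one child by the node's classifier
ensemble (majority vote).  Descent stops at the first node whose cv-score
is not above the threshold; that node's id is the point's cluster label.
Every emitted cluster is therefore separable from all others with mean
accuracy above the chosen cv-score: higher thresholds give fewer, broader
clusters, and the default 0.5 (chance) typically emits the full set of
pure clusters.

Because the tree's cv-scores are nonincreasing from root to leaf, the
partitions at an ascending list of cv-scores are nested coarsenings, and a
whole sweep costs one tree descent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np

from halclust.linkage import MergeTree

__all__ = ["ClusteringResult", "predict", "sweep_cv_scores"]


@dataclass
class ClusteringResult:
    """Per-point labels at one or several cv-scores, with provenance."""

    labels: Dict[float, np.ndarray]
    cv_scores: List[float]
    cluster_counts: Dict[float, int] = field(default_factory=dict)
    model_id: dict = field(default_factory=dict)


def _resolve(model):
    """Accept either a bare MergeTree or a fitted model with .tree/.normalizer."""
    if isinstance(model, MergeTree):
        return model, None
    return model.tree, getattr(model, "normalizer", None)


def _ensemble_route(node, X: np.ndarray) -> np.ndarray:
    """Majority vote of the node's ensemble: 0 -> first child, 1 -> second."""
    votes = np.zeros(X.shape[0])
    for clf in node.ensemble:
        votes += clf.predict(X)
    # exact ties go to the first child (deterministic)
    return (votes * 2 > len(node.ensemble)).astype(np.int64)


def _descend(tree: MergeTree, X: np.ndarray, cv_score: float) -> np.ndarray:
    labels = np.full(X.shape[0], tree.root, dtype=np.int64)
    frontier = [(tree.root, np.arange(X.shape[0]))]
    while frontier:
        node_id, idx = frontier.pop()
        node = tree.nodes[node_id]
        if node.children is None or node.cv_score <= cv_score:
            continue  # descent stops here; labels already hold node_id
        side = _ensemble_route(node, X[idx])
        for child, mask in ((node.children[0], side == 0), (node.children[1], side == 1)):
            sub = idx[mask]
            if sub.size:
                labels[sub] = child
                frontier.append((child, sub))
    return labels


def predict(
    model,
    X_new: np.ndarray,
    cv_score: float = 0.5,
    chunk_size: int = 100_000,
) -> np.ndarray:
    """Label each row of ``X_new`` at the requested cv-score.

    ``model`` is a fitted pipeline model (tree + normalizer) or a bare
    :class:`MergeTree` (then ``X_new`` must already be normalized).  Points
    are processed in chunks of ``chunk_size`` rows to bound memory; the
    output is independent of the chunking because each point is routed
    independently.
    """
    if not 0.5 <= cv_score <= 1.0:
        raise ValueError("cv_score must lie in [0.5, 1.0]")
    tree, normalizer = _resolve(model)
    X_new = np.atleast_2d(np.asarray(X_new, dtype=np.float64))
    if normalizer is not None:
        if X_new.shape[1] != normalizer.means.shape[0]:
            raise ValueError(
                f"feature count mismatch: model expects "
                f"{normalizer.means.shape[0]}, got {X_new.shape[1]}"
            )
        transform = normalizer.transform
    else:
        transform = lambda x: x  # noqa: E731
    out = np.empty(X_new.shape[0], dtype=np.int64)
    for start in range(0, X_new.shape[0], chunk_size):
        chunk = transform(X_new[start : start + chunk_size])
        out[start : start + chunk_size] = _descend(tree, chunk, cv_score)
    return out


def sweep_cv_scores(
    model,
    X_new: np.ndarray,
    cv_scores: Sequence[float],
    chunk_size: int = 100_000,
) -> ClusteringResult:
    """Labels at every requested cv-score from a single tree descent.

    The tree is descended once at the finest (lowest) threshold; the label
    at any coarser threshold is the stop node's nearest ancestor whose
    cv-score does not exceed that threshold, so nesting of the partitions
    holds by construction.
    """
    cv_scores = [float(c) for c in cv_scores]
    if not cv_scores:
        raise ValueError("cv_scores must be non-empty")
    if any(not 0.5 <= c <= 1.0 for c in cv_scores):
        raise ValueError("all cv_scores must lie in [0.5, 1.0]")
    if sorted(cv_scores) != cv_scores:
        raise ValueError("cv_scores must be sorted ascending")
    tree, _ = _resolve(model)
    fine = predict(model, X_new, cv_scores[0], chunk_size=chunk_size)

    parent = {}
    for nid, node in tree.nodes.items():
        if node.children is not None:
            for c in node.children:
                parent[c] = nid

    def stop_ancestor(node_id: int, c: float) -> int:
        # walk root-ward until the node's parent would still descend
        path = [node_id]
        while path[-1] in parent:
            path.append(parent[path[-1]])
        for nid in reversed(path):  # root first
            if tree.nodes[nid].cv_score <= c or nid == node_id:
                return nid
        return node_id

    labels = {cv_scores[0]: fine}
    counts = {cv_scores[0]: int(len(np.unique(fine)))}
    uniq = np.unique(fine)
    lookup = np.arange(max(tree.nodes) + 1, dtype=np.int64)
    for c in cv_scores[1:]:
        for u in uniq:
            lookup[int(u)] = stop_ancestor(int(u), c)
        lab = lookup[fine]
        labels[c] = lab
        counts[c] = int(len(np.unique(lab)))
    return ClusteringResult(labels=labels, cv_scores=cv_scores, cluster_counts=counts)
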