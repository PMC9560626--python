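"""Supervised agglomeration of pure clusters in the original feature space.

Two clusters are "similar" when a classifier cannot tell them apart: every
edge of the cluster graph carries the out-of-sample accuracy of a
classifier trained to separate the two clusters on the unreduced,
normalized features (the *edge score*, 0.5 = chance, 1.0 = perfectly
separable).  With N pure clusters the initial sweep trains N(N-1)/2
classifiers; each cluster is then connected to the k clusters hardest to
distinguish from it, and the pair with the globally lowest deep-swept score
is merged, repeatedly, until one cluster remains.  Each merge stores its
classifier ensemble and score in an internal node of the merge tree — the
trained model artifact used for prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterGraph",
    "TreeNode",
    "MergeTree",
    "edge_score",
    "build_cluster_graph",
    "deep_sweep",
    "agglomerate",
    "DEFAULT_CLASSIFIER_SPEC",
]

DEFAULT_CLASSIFIER_SPEC = {"kind": "rf", "n_estimators": 100, "train_cap": 5000}


def _make_classifier(spec: dict, seed: int):
    kind = spec.get("kind", "rf")
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=int(spec.get("n_estimators", 100)),
            random_state=seed,
            n_jobs=1,
        )
    if kind == "svm":
        return SVC(kernel=spec.get("kernel", "rbf"), C=float(spec.get("C", 1.0)),
                   random_state=seed)
    raise ValueError(f"unknown classifier kind {spec.get('kind')!r}")


def _pair_rng(seed: int, a: int, b: int) -> np.random.Generator:
    # deterministic per-(seed, pair) stream so edge scores do not depend on
    # evaluation order
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(a, b)))


def _balanced_pair_data(
    X: np.ndarray,
    labels: np.ndarray,
    a: int,
    b: int,
    rng: np.random.Generator,
    train_cap: int = 5000,
) -> Tuple[np.ndarray, np.ndarray]:
    """Members of a and b, larger class downsampled to the smaller's size.

    Class balancing makes chance accuracy mean exactly 0.5 regardless of
    cluster size imbalance; each class is additionally capped at
    ``train_cap`` points to bound classifier cost.
    """
    ia = np.flatnonzero(labels == a)
    ib = np.flatnonzero(labels == b)
    size = min(len(ia), len(ib), train_cap)
    if len(ia) > size:
        ia = rng.choice(ia, size=size, replace=False)
    if len(ib) > size:
        ib = rng.choice(ib, size=size, replace=False)
    Xp = np.vstack([X[ia], X[ib]])
    yp = np.concatenate([np.zeros(len(ia), dtype=np.int64), np.ones(len(ib), dtype=np.int64)])
    return Xp, yp


def edge_score(
    X_hd: np.ndarray,
    labels: np.ndarray,
    a: int,
    b: int,
    classifier_spec: Optional[dict] = None,
    cv: object = 5,
    seed: int = 0,
    min_cluster_size: int = 12,
) -> float:
    """Cross-validated out-of-sample accuracy separating clusters a and b.

    ``cv`` is either an integer number of stratified folds (default 5) or a
    float test fraction for a single stratified split.  A pair with a
    cluster below ``min_cluster_size`` cannot be certified separable and
    scores 0.0 (it will be merged first), with a warning.
    """
    if a == b:
        raise ValueError("a and b must be distinct cluster ids")
    spec = dict(DEFAULT_CLASSIFIER_SPEC, **(classifier_spec or {}))
    labels = np.asarray(labels)
    n_a = int((labels == a).sum())
    n_b = int((labels == b).sum())
    if min(n_a, n_b) < min_cluster_size:
        logger.warning(
            "cluster pair (%s, %s) has a member below min size %d "
            "(sizes %d, %d); scoring 0.0 to force the merge", a, b,
            min_cluster_size, n_a, n_b,
        )
        return 0.0
    rng = _pair_rng(seed, a, b)
    Xp, yp = _balanced_pair_data(np.asarray(X_hd), labels, a, b, rng,
                                 train_cap=int(spec.get("train_cap", 5000)))
    clf_seed = int(rng.integers(2**31))
    if isinstance(cv, float):
        Xtr, Xte, ytr, yte = train_test_split(
            Xp, yp, test_size=cv, stratify=yp, random_state=clf_seed
        )
        clf = _make_classifier(spec, clf_seed)
        clf.fit(Xtr, ytr)
        return float((clf.predict(Xte) == yte).mean())
    accs = []
    skf = StratifiedKFold(n_splits=int(cv), shuffle=True, random_state=clf_seed)
    for tr, te in skf.split(Xp, yp):
        clf = _make_classifier(spec, clf_seed)
        clf.fit(Xp[tr], yp[tr])
        accs.append((clf.predict(Xp[te]) == yp[te]).mean())
    return float(np.mean(accs))


@dataclass
class ClusterGraph:
    """Sparse undirected graph over clusters, weighted by edge score."""

    nodes: set
    edges: Dict[Tuple[int, int], float]
    k: int = 3

    def neighbors(self, node: int) -> List[int]:
        out = []
        for (a, b) in self.edges:
            if a == node:
                out.append(b)
            elif b == node:
                out.append(a)
        return out


def build_cluster_graph(scores: Dict[Tuple[int, int], float], k: int = 3) -> ClusterGraph:
    """Keep, per cluster, the k lowest-accuracy (hardest) partners.

    The per-node selections are unioned into an undirected graph; if the
    union is disconnected, the lowest-score edges bridging components are
    added until it is connected, so a next merge always exists.
    """
    if k < 1:
        raise ValueError("k must be at least 1")
    scores = {(min(a, b), max(a, b)): s for (a, b), s in scores.items()}
    nodes = sorted({i for pair in scores for i in pair})
    kept: Dict[Tuple[int, int], float] = {}
    for node in nodes:
        partners = sorted(
            ((s, other) for (a, b), s in scores.items()
             for other in ((b,) if a == node else (a,) if b == node else ()))
        )
        for s, other in partners[:k]:
            kept[(min(node, other), max(node, other))] = s

    # connectivity repair via union-find over the full score list
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for (a, b) in kept:
        parent[find(a)] = find(b)
    for (a, b), s in sorted(scores.items(), key=lambda kv: (kv[1], kv[0])):
        ra, rb = find(a), find(b)
        if ra != rb:
            kept[(a, b)] = s
            parent[ra] = rb
    return ClusterGraph(nodes=set(nodes), edges=kept, k=k)


def _deep_edge(
    X_hd: np.ndarray,
    labels: np.ndarray,
    a: int,
    b: int,
    n_bootstrap: int,
    classifier_spec: Optional[dict],
    seed: int,
    min_cluster_size: int = 12,
) -> Tuple[float, list]:
    """Bootstrap-ensemble edge score plus the fitted routing ensemble.

    A 20% stratified hold-out is fixed once; each of ``n_bootstrap``
    classifiers trains on a bootstrap resample of the remaining 80% and is
    scored on the hold-out.  The mean hold-out accuracy is the deep edge
    score and the fitted classifiers form the routing ensemble stored in
    the merge-tree node (they vote 0 = cluster a, 1 = cluster b).
    """
    spec = dict(DEFAULT_CLASSIFIER_SPEC, **(classifier_spec or {}))
    labels = np.asarray(labels)
    n_a = int((labels == a).sum())
    n_b = int((labels == b).sum())
    rng = _pair_rng(seed, a, b)
    if min(n_a, n_b) < min_cluster_size:
        logger.warning(
            "deep sweep: pair (%s, %s) below min size %d; scoring 0.0",
            a, b, min_cluster_size,
        )
        # still fit one classifier on whatever is available so prediction
        # can route through the node
        Xp, yp = _balanced_pair_data(np.asarray(X_hd), labels, a, b, rng)
        clf = _make_classifier(spec, int(rng.integers(2**31)))
        clf.fit(Xp, yp)
        return 0.0, [clf]
    Xp, yp = _balanced_pair_data(np.asarray(X_hd), labels, a, b, rng,
                                 train_cap=int(spec.get("train_cap", 5000)))
    split_seed = int(rng.integers(2**31))
    Xtr, Xte, ytr, yte = train_test_split(
        Xp, yp, test_size=0.2, stratify=yp, random_state=split_seed
    )
    accs, ensemble = [], []
    for _ in range(n_bootstrap):
        boot = rng.integers(len(ytr), size=len(ytr))
        clf = _make_classifier(spec, int(rng.integers(2**31)))
        clf.fit(Xtr[boot], ytr[boot])
        accs.append((clf.predict(Xte) == yte).mean())
        ensemble.append(clf)
    return float(np.mean(accs)), ensemble


def deep_sweep(
    graph: ClusterGraph,
    X_hd: np.ndarray,
    labels: np.ndarray,
    n_bootstrap: int = 10,
    classifier_spec: Optional[dict] = None,
    seed: int = 0,
) -> ClusterGraph:
    """Re-estimate every edge score with a bootstrap classifier ensemble.

    Averaging held-out accuracy over bootstrap-trained classifiers lowers
    the variance of the score relative to a single shallow split and
    reduces the risk of merging on an overfit estimate.
    """
    if n_bootstrap < 2:
        raise ValueError("n_bootstrap must be at least 2")
    new_edges = {}
    for (a, b) in sorted(graph.edges):
        score, _ = _deep_edge(X_hd, labels, a, b, n_bootstrap, classifier_spec, seed)
        new_edges[(a, b)] = score
    return ClusterGraph(nodes=set(graph.nodes), edges=new_edges, k=graph.k)


# ---------------------------------------------------------------------------
# merge tree


@dataclass
class TreeNode:
    """One node of the merge tree.

    Leaves are pure clusters (``children is None``).  Internal nodes record
    the merged pair, the routing ensemble trained to separate them, the raw
    measured edge score of the merge, and the monotonized ``cv_score`` used
    by prediction.
    """

    id: int
    children: Optional[Tuple[int, int]] = None
    ensemble: Optional[list] = None
    edge_score: float = 0.0
    cv_score: float = 0.0


@dataclass
class MergeTree:
    """Binary agglomeration tree over the pure clusters."""

    nodes: Dict[int, TreeNode]
    root: int
    leaves: List[int] = field(default_factory=list)

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def is_leaf(self, node_id: int) -> bool:
        return self.nodes[node_id].children is None


def _monotonize(tree: MergeTree) -> None:
    """Set cv_score = max(own raw score, children's cv_score), bottom-up.

    Raw merge scores are not guaranteed nondecreasing toward the root; the
    repair guarantees that thresholding the tree at any cv-score yields
    nested partitions.  Violations of raw monotonicity are logged.
    """
    order = sorted(
        (nid for nid in tree.nodes if not tree.is_leaf(nid))
    )  # internal ids are assigned in merge order, so ascending id = bottom-up
    for nid in order:
        node = tree.nodes[nid]
        child_cv = max(tree.nodes[c].cv_score for c in node.children)
        if node.edge_score < child_cv:
            logger.info(
                "non-monotone merge score at node %d (%.3f < child %.3f); "
                "monotonized", nid, node.edge_score, child_cv,
            )
        node.cv_score = max(node.edge_score, child_cv)
    tree.nodes[tree.root].cv_score = 1.0  # root holds all points: perfect score


def agglomerate(
    X_hd: np.ndarray,
    pure_labels: np.ndarray,
    k: int = 3,
    classifier_spec: Optional[dict] = None,
    n_bootstrap: int = 10,
    seed: int = 0,
    min_cluster_size: int = 12,
) -> MergeTree:
    """Build the merge tree by repeated least-separable-pair merging.

    Workflow per iteration: ensure every current edge carries a deep
    (bootstrap-ensemble) score; merge the globally lowest-score pair,
    breaking ties toward the lexicographically smallest id pair; store the
    pair's ensemble and score in a new internal node; score the new cluster
    against the union of its children's former neighbors; repeat until a
    single cluster remains.  After a merge only the affected edges are
    recomputed — scores between untouched clusters are cached.
    """
    X_hd = np.asarray(X_hd, dtype=np.float64)
    pure_labels = np.asarray(pure_labels, dtype=np.int64)
    leaf_ids = sorted(int(c) for c in np.unique(pure_labels) if c >= 0)
    if not leaf_ids:
        raise ValueError("need at least one pure cluster")
    nodes = {lid: TreeNode(id=lid) for lid in leaf_ids}
    if len(leaf_ids) == 1:
        return MergeTree(nodes=nodes, root=leaf_ids[0], leaves=leaf_ids)

    labels = pure_labels.copy()  # updated in place as clusters merge
    current = set(leaf_ids)
    next_id = max(leaf_ids) + 1

    # initial shallow sweep: single stratified 80/20 split per pair
    shallow = {
        (a, b): edge_score(X_hd, labels, a, b, classifier_spec, cv=0.2, seed=seed,
                           min_cluster_size=min_cluster_size)
        for a, b in combinations(leaf_ids, 2)
    }
    graph = build_cluster_graph(shallow, k=k)
    edges = dict(graph.edges)
    deep_cache: Dict[Tuple[int, int], Tuple[float, list]] = {}

    while len(current) > 1:
        for pair in sorted(edges):
            if pair not in deep_cache:
                a, b = pair
                deep_cache[pair] = _deep_edge(
                    X_hd, labels, a, b, n_bootstrap, classifier_spec, seed,
                    min_cluster_size=min_cluster_size,
                )
        best_pair = min(edges, key=lambda p: (deep_cache[p][0], p))
        a, b = best_pair
        score, ensemble = deep_cache[best_pair]
        new = next_id
        next_id += 1
        nodes[new] = TreeNode(id=new, children=(a, b), ensemble=ensemble,
                              edge_score=score)
        logger.info("merged clusters %d + %d -> %d (edge score %.3f)", a, b, new, score)

        labels[(labels == a) | (labels == b)] = new
        former_neighbors = {
            other
            for (x, y) in edges
            for other in ((y,) if x in (a, b) else (x,) if y in (a, b) else ())
        } - {a, b}
        edges = {p: s for p, s in edges.items() if a not in p and b not in p}
        deep_cache = {p: v for p, v in deep_cache.items() if a not in p and b not in p}
        current -= {a, b}
        current.add(new)
        for c in sorted(former_neighbors):
            pair = (min(new, c), max(new, c))
            edges[pair] = edge_score(
                X_hd, labels, new, c, classifier_spec, cv=0.2, seed=seed,
                min_cluster_size=min_cluster_size,
            )
        # prune each node back to its k hardest partners among cached edges,
        # keeping connectivity via the rebuild helper
        if edges:
            graph = build_cluster_graph(edges, k=k)
            edges = dict(graph.edges)
        elif len(current) > 1:
            # cached edges exhausted (components merged internally): rescore
            # the remaining cluster pairs from scratch
            edges = {
                (p, q): edge_score(X_hd, labels, p, q, classifier_spec, cv=0.2,
                                   seed=seed, min_cluster_size=min_cluster_size)
                for p, q in combinations(sorted(current), 2)
            }
            graph = build_cluster_graph(edges, k=k)
            edges = dict(graph.edges)

    tree = MergeTree(nodes=nodes, root=next_id - 1, leaves=leaf_ids)
    _monotonize(tree)
    return tree
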