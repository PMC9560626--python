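"""Pure-cluster detection by kernel density estimation in embedding space.

The density stage runs on the 2-D embedding of the downsample.  It

1. selects the Gaussian-kernel bandwidth ``h`` by minimizing the held-out
   negative log-likelihood of the kernel density estimate on a test split;
2. builds an m-nearest-neighbor graph (random-projection LSH or exact);
3. declares density modes (points that are density-maximal within their own
   neighborhood) and assigns every other point by iterated density-gradient
   ascent along the neighbor graph;
4. flags clusters whose members' neighborhoods are >= 99% label-homogeneous
   as "pure", and merges clusters whose purity collapses in an extended
   (relaxed) neighborhood — these represent the same density maximum.

The kernel is ``K_h(x, x_i) = exp(-||x - x_i||^2 / h^2) / h`` and the
density map is the plain average ``(1/N) sum_i K_h(x, x_i)``.  This kernel
is deliberately not a normalized 2-D density: the missing constant rescales
the density map uniformly and shifts the bandwidth objective by a constant,
so neither mode identities nor the selected bandwidth are affected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)

__all__ = [
    "BandwidthSelection",
    "NeighborGraph",
    "DensityModel",
    "select_bandwidth",
    "kde_density",
    "approx_knn",
    "find_pure_clusters",
    "extended_neighborhood_merge",
]

#: below this many points the density map is computed with the full O(n^2)
#: kernel sum; above it the sum is truncated to the neighbor graph.
_FULL_SUM_LIMIT = 20_000


@dataclass
class BandwidthSelection:
    """Result of held-out bandwidth selection.

    ``h`` minimizes the recorded negative log-likelihood curve; the curve
    lists every ``(h_candidate, L)`` pair the optimizer evaluated.
    """

    h: float
    nll_curve: list
    split_seed: int
    train_fraction: float


@dataclass
class NeighborGraph:
    """m-nearest-neighbor graph: per-row neighbor indices and distances.

    Rows exclude the point itself; distances are nondecreasing per row.
    """

    indices: np.ndarray
    distances: np.ndarray
    method: str = "exact"

    @property
    def m(self) -> int:
        return self.indices.shape[1]


@dataclass
class DensityModel:
    """Density map, modes and per-point pure-cluster labels."""

    coords: np.ndarray
    h: float
    density: np.ndarray
    modes: np.ndarray  # point indices of cluster centers, one per cluster
    labels: np.ndarray  # cluster id in [0, n_clusters) per point, -1 = unassigned
    pure_mask: np.ndarray  # per-cluster purity flag
    purity_threshold: float = 0.99
    purities: np.ndarray = field(default=None)

    @property
    def n_clusters(self) -> int:
        return len(self.modes)


def kde_density(
    coords_train: np.ndarray,
    coords_query: np.ndarray,
    h: float,
    chunk_size: int = 2000,
) -> np.ndarray:
    """Full-sum Gaussian kernel density estimate at the query points.

    Evaluates ``(1/N) sum_i exp(-||x - x_i||^2/h^2) / h`` exactly, chunking
    the query rows to bound memory.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    train = np.asarray(coords_train, dtype=np.float64)
    query = np.asarray(coords_query, dtype=np.float64)
    n_train = train.shape[0]
    out = np.empty(query.shape[0])
    train_sq = np.einsum("ij,ij->i", train, train)
    for start in range(0, query.shape[0], chunk_size):
        q = query[start : start + chunk_size]
        d2 = np.maximum(
            q @ train.T * -2.0 + np.einsum("ij,ij->i", q, q)[:, None] + train_sq[None, :],
            0.0,
        )
        out[start : start + chunk_size] = np.exp(-d2 / h**2).sum(axis=1)
    return out / (h * n_train)


def _truncated_density(
    coords: np.ndarray, graph: NeighborGraph, h: float
) -> np.ndarray:
    """Density restricted to each point's own neighborhood (plus itself)."""
    n = coords.shape[0]
    k = np.exp(-(graph.distances**2) / h**2).sum(axis=1) + 1.0  # self term exp(0)
    return k / (h * n)


def select_bandwidth(
    coords: np.ndarray,
    train_fraction: float = 0.5,
    bracket: Optional[tuple] = None,
    seed: int = 0,
    max_evals: int = 50,
) -> BandwidthSelection:
    """Choose the KDE bandwidth by held-out likelihood maximization.

    The sample is split into train/test; for each candidate ``h`` the
    negative log-likelihood of the test points under the train-set density
    estimate,

        L(h) = -(1/N_test) * sum_test log( sum_train K_h(x_j, x_i) ),

    is evaluated, and ``h`` is found by scalar minimization of ``L`` over a
    log-spaced bracket (default ``[1e-2 * sigma, 10 * sigma]`` with
    ``sigma`` the mean per-axis sd of the coordinates).
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if n < 20:
        raise ValueError("need at least 20 points to select a bandwidth")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    sigma = float(coords.std(axis=0, ddof=0).mean())
    if sigma == 0:
        raise ValueError("degenerate coordinates (all points identical)")
    if bracket is None:
        bracket = (1e-2 * sigma, 10.0 * sigma)

    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(2, int(round(train_fraction * n)))
    train, test = coords[perm[:n_train]], coords[perm[n_train:]]

    # pairwise squared distances once; L(h) is then cheap per candidate
    d2 = (
        np.einsum("ij,ij->i", test, test)[:, None]
        - 2.0 * test @ train.T
        + np.einsum("ij,ij->i", train, train)[None, :]
    )
    d2 = np.maximum(d2, 0.0)

    curve: list = []

    def nll(log_h: float) -> float:
        h = float(np.exp(log_h))
        # log sum_train K_h = logsumexp(-d2/h^2) - log h
        val = float(-np.mean(logsumexp(-d2 / h**2, axis=1) - np.log(h)))
        curve.append((h, val))
        return val

    res = minimize_scalar(
        nll,
        bounds=(np.log(bracket[0]), np.log(bracket[1])),
        method="bounded",
        options={"maxiter": max_evals, "xatol": 1e-3},
    )
    h_best = float(np.exp(res.x))
    return BandwidthSelection(
        h=h_best, nll_curve=curve, split_seed=seed, train_fraction=train_fraction
    )


# ---------------------------------------------------------------------------
# neighbor search


def _neighbor_count(n: int, neighbor_fraction: float, min_neighbors: int = 20,
                    max_neighbors: int = 1000) -> int:
    # neighborhood size scales linearly with the sample; 2% by default
    m = int(round(neighbor_fraction * n))
    m = max(min_neighbors, min(m, max_neighbors))
    return min(m, n - 1)


def _lsh_knn(coords: np.ndarray, m: int, seed: int, n_tables: int = 6) -> NeighborGraph:
    """Approximate m-NN via random-projection locality-sensitive hashing.

    Each table hashes every point with a handful of random hyperplanes; the
    candidate pool for a point is the union, over tables, of its hash
    bucket.  Exact distances are then computed within the pool only.
    """
    n, d = coords.shape
    rng = np.random.default_rng(seed)
    # bucket size targeted at ~2m so the candidate union comfortably covers
    # the true neighborhood
    n_bits = max(1, int(np.log2(max(n / (2 * m), 2))))
    buckets_per_table = []
    for _ in range(n_tables):
        planes = rng.standard_normal((d, n_bits))
        offsets = coords @ planes
        codes = (offsets > np.median(offsets, axis=0)).astype(np.uint8)
        keys = codes @ (1 << np.arange(n_bits, dtype=np.uint64))
        table: dict = {}
        for i, key in enumerate(keys):
            table.setdefault(int(key), []).append(i)
        buckets_per_table.append((keys, {k: np.array(v) for k, v in table.items()}))

    indices = np.empty((n, m), dtype=np.int64)
    distances = np.empty((n, m))
    for i in range(n):
        cand = np.unique(
            np.concatenate([tab[int(keys[i])] for keys, tab in buckets_per_table])
        )
        cand = cand[cand != i]
        if cand.shape[0] < m:  # pathological bucket: fall back to all points
            cand = np.delete(np.arange(n), i)
        diff = coords[cand] - coords[i]
        d2 = np.einsum("ij,ij->i", diff, diff)
        take = np.argpartition(d2, m - 1)[:m]
        order = take[np.argsort(d2[take], kind="stable")]
        indices[i] = cand[order]
        distances[i] = np.sqrt(d2[order])
    return NeighborGraph(indices=indices, distances=distances, method="lsh")


def approx_knn(
    coords: np.ndarray,
    neighbor_fraction: float = 0.02,
    method: str = "exact",
    seed: int = 0,
    n_neighbors: Optional[int] = None,
    min_neighbors: int = 20,
    max_neighbors: int = 1000,
) -> NeighborGraph:
    """Build the m-nearest-neighbor graph under Euclidean distance.

    ``m`` scales linearly with the sample size (``neighbor_fraction``,
    default 2%, floored at 20 and capped at 1000) unless ``n_neighbors``
    overrides it.  ``method="exact"`` is the oracle backend;
    ``method="lsh"`` is the random-projection approximate search.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if neighbor_fraction <= 0:
        raise ValueError("neighbor_fraction must be positive")
    m = n_neighbors if n_neighbors is not None else _neighbor_count(
        n, neighbor_fraction, min_neighbors, max_neighbors
    )
    if m < 1 or n < 2:
        raise ValueError(f"need at least 2 points and 1 neighbor (n={n}, m={m})")
    m = min(m, n - 1)
    if method == "exact":
        nn = NearestNeighbors(n_neighbors=m + 1).fit(coords)
        distances, indices = nn.kneighbors(coords)
        # drop the self column (first occurrence of each row's own index)
        keep_idx = np.empty((n, m), dtype=np.int64)
        keep_dist = np.empty((n, m))
        for i in range(n):
            row = indices[i]
            mask = row != i
            if mask.sum() == m + 1:  # self not returned (duplicate points)
                mask[-1] = False
            keep_idx[i] = row[mask][:m]
            keep_dist[i] = distances[i][mask][:m]
        return NeighborGraph(indices=keep_idx, distances=keep_dist, method="exact")
    if method == "lsh":
        return _lsh_knn(coords, m, seed)
    raise ValueError(f"unknown knn method {method!r}")


# ---------------------------------------------------------------------------
# mode finding and purity


def _cluster_purities(labels: np.ndarray, graph: NeighborGraph, n_clusters: int) -> np.ndarray:
    """Mean fraction, over each cluster's members, of same-label neighbors."""
    same = labels[graph.indices] == labels[:, None]
    purities = np.zeros(n_clusters)
    for c in range(n_clusters):
        members = labels == c
        # pooled single division keeps boundary cases (exactly 99%) exact
        purities[c] = same[members].mean() if members.any() else 1.0
    return purities


def find_pure_clusters(
    coords: np.ndarray,
    graph: NeighborGraph,
    h: float,
    purity_threshold: float = 0.99,
    density: Optional[np.ndarray] = None,
) -> DensityModel:
    """Detect density modes and assign points by density-gradient ascent.

    A point is a mode when no neighbor in its m-neighborhood has strictly
    higher density (equal-density ties defer to the lower point index, which
    keeps duplicated points in one cluster and makes runs deterministic).
    Every other point follows its highest-density neighbor, iterated until a
    mode is reached; the path terminates because density never decreases and
    index strictly decreases on ties.

    A cluster is flagged pure when the mean fraction of same-label neighbors
    over its members reaches ``purity_threshold`` (default 99%); impure
    clusters are kept but flagged.
    """
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if not 0 < purity_threshold <= 1:
        raise ValueError("purity_threshold must be in (0, 1]")
    if density is None:
        if n <= _FULL_SUM_LIMIT:
            density = kde_density(coords, coords, h)
        else:
            density = _truncated_density(coords, graph, h)
    density = np.asarray(density, dtype=np.float64)

    nbr = graph.indices
    nbr_density = density[nbr]
    best_col = nbr_density.argmax(axis=1)  # argmax returns first (= lowest index among ties
    # within the distance-sorted row; canonicalize ties by neighbor index)
    row_max = nbr_density[np.arange(n), best_col]
    succ = np.arange(n)
    for i in range(n):
        dmax = row_max[i]
        if dmax > density[i]:
            tied = nbr[i][nbr_density[i] == dmax]
            succ[i] = tied.min()
        elif dmax == density[i]:
            tied = nbr[i][nbr_density[i] == dmax]
            j = tied.min()
            if j < i:
                succ[i] = j  # duplicate/tied plateau: defer to lower index
    # pointer doubling until every chain reaches its fixed point (a mode)
    while True:
        nxt = succ[succ]
        if np.array_equal(nxt, succ):
            break
        succ = nxt
    modes = np.flatnonzero(succ == np.arange(n))
    mode_to_label = {int(mo): lab for lab, mo in enumerate(modes)}
    labels = np.array([mode_to_label[int(s)] for s in succ], dtype=np.int64)

    purities = _cluster_purities(labels, graph, len(modes))
    return DensityModel(
        coords=coords,
        h=h,
        density=density,
        modes=modes,
        labels=labels,
        pure_mask=purities >= purity_threshold,
        purity_threshold=purity_threshold,
        purities=purities,
    )


def extended_neighborhood_merge(
    model: DensityModel,
    coords: np.ndarray,
    relax_factor: float = 2.0,
    purity_drop: float = 0.05,
    seed: int = 0,
    graph: Optional[NeighborGraph] = None,
    knn_method: str = "exact",
) -> DensityModel:
    """Merge clusters that represent the same density maximum.

    Re-runs the neighbor search with a relaxed neighborhood
    (``m' = round(relax_factor * m)``).  A cluster whose purity in the
    extended neighborhood falls more than ``purity_drop`` below its original
    purity is merged with the cluster contributing the most foreign points
    to those extended neighborhoods.  Merges are closed transitively
    (union-find), and the surviving mode of a merged group is its
    highest-density mode.
    """
    if relax_factor <= 1:
        raise ValueError("relax_factor must exceed 1")
    if not 0 < purity_drop < 1:
        raise ValueError("purity_drop must be in (0, 1)")
    coords = np.asarray(coords, dtype=np.float64)
    n = coords.shape[0]
    if graph is None:
        # m implied by the model's labels: recover from original purity calc
        m_base = _neighbor_count(n, 0.02)
    else:
        m_base = graph.m
    m_ext = min(int(round(relax_factor * m_base)), n - 1)
    ext = approx_knn(coords, method=knn_method, seed=seed, n_neighbors=m_ext)

    labels = model.labels
    k = model.n_clusters
    ext_purity = _cluster_purities(labels, ext, k)

    parent = np.arange(k)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    nbr_labels = labels[ext.indices]
    for c in range(k):
        if ext_purity[c] >= model.purities[c] - purity_drop:
            continue
        members = labels == c
        foreign = nbr_labels[members].ravel()
        foreign = foreign[foreign != c]
        if foreign.size == 0:
            continue
        counts = np.bincount(foreign, minlength=k)
        target = int(counts.argmax())
        ra, rb = find(c), find(target)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)
            logger.info(
                "extended-neighborhood merge: cluster %d -> %d "
                "(purity %.3f -> %.3f)", c, target, model.purities[c], ext_purity[c]
            )

    roots = np.array([find(c) for c in range(k)])
    new_ids = {r: i for i, r in enumerate(sorted(set(roots)))}
    new_labels = np.array([new_ids[roots[lab]] for lab in labels], dtype=np.int64)
    n_new = len(new_ids)
    new_modes = np.empty(n_new, dtype=np.int64)
    for r, i in new_ids.items():
        group_modes = model.modes[roots == r]
        new_modes[i] = group_modes[np.argmax(model.density[group_modes])]

    base_graph = graph if graph is not None else ext
    purities = _cluster_purities(new_labels, base_graph, n_new)
    return DensityModel(
        coords=coords,
        h=model.h,
        density=model.density,
        modes=new_modes,
        labels=new_labels,
        pure_mask=purities >= model.purity_threshold,
        purity_threshold=model.purity_threshold,
        purities=purities,
    )
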