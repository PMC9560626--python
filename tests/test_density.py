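"""Density stage: KDE values, bandwidth selection, neighbor graphs, modes.

The brute-force oracles here (double-loop kernel sums, dense bandwidth
grids, exhaustive local-maximum scans) are deliberately naive and
independent of the library code paths they certify.
"""

import numpy as np
import pytest

from halclust.datasets import make_gaussian_mixture
from halclust.density import (
    NeighborGraph,
    _cluster_purities,
    _truncated_density,
    approx_knn,
    extended_neighborhood_merge,
    find_pure_clusters,
    kde_density,
    select_bandwidth,
)
from sklearn.metrics import adjusted_rand_score


def brute_force_kde(train, query, h):
    """O(n^2) double-loop evaluation of the kernel sum."""
    out = np.zeros(len(query))
    for i, q in enumerate(query):
        s = 0.0
        for x in train:
            s += np.exp(-np.sum((q - x) ** 2) / h**2) / h
        out[i] = s / len(train)
    return out


def brute_force_modes(coords, m, h):
    """Exhaustive scan: a point is a mode iff its full-sum density is >= the
    density of each of its m nearest points (by full pairwise sort)."""
    n = len(coords)
    dens = brute_force_kde(coords, coords, h)
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
    modes = []
    for i in range(n):
        order = np.argsort(d2[i], kind="stable")
        nbrs = [j for j in order if j != i][:m]
        if all(dens[i] >= dens[j] for j in nbrs):
            modes.append(i)
    return set(modes), dens


class TestKDE:
    def test_single_point_self_evaluation(self):
        x = np.array([[0.3, -1.2]])
        assert kde_density(x, x, h=1.0) == pytest.approx([1.0])

    def test_two_symmetric_points_at_origin(self):
        train = np.array([[1.0, 0.0], [-1.0, 0.0]])
        out = kde_density(train, np.array([[0.0, 0.0]]), h=1.0)
        assert out == pytest.approx([np.exp(-1.0)])

    def test_bandwidth_rescales_kernel(self):
        train = np.array([[2.0, 0.0]])
        out = kde_density(train, np.array([[0.0, 0.0]]), h=2.0)
        assert out == pytest.approx([np.exp(-1.0) / 2.0])

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(0)
        train = rng.normal(size=(500, 2))
        query = rng.normal(size=(40, 2))
        fast = kde_density(train, query, h=0.3, chunk_size=7)
        slow = brute_force_kde(train, query, h=0.3)
        assert np.allclose(fast, slow, rtol=1e-9)

    def test_truncated_matches_full_when_tails_negligible(self):
        # neighborhoods of 60 points at h far below the inter-point scale:
        # kernels beyond the neighborhood contribute ~exp(-100)
        rng = np.random.default_rng(1)
        coords = rng.uniform(0, 10, size=(500, 2))
        h = 0.05
        graph = approx_knn(coords, method="exact", n_neighbors=60)
        full = kde_density(coords, coords, h)
        trunc = _truncated_density(coords, graph, h)
        assert np.allclose(trunc, full, rtol=1e-6)

    def test_invalid_bandwidth(self):
        with pytest.raises(ValueError):
            kde_density(np.zeros((3, 2)), np.zeros((1, 2)), h=0.0)


class TestBandwidthSelection:
    def test_close_to_dense_grid_minimizer(self):
        rng = np.random.default_rng(0)
        coords = rng.standard_normal((2000, 2))
        sel = select_bandwidth(coords, seed=0)
        # independent oracle: 200-point dense grid over the same objective
        hs = np.geomspace(1e-2, 10, 200)
        curve = dict(sel.nll_curve)

        def objective(h):
            perm = np.random.default_rng(0).permutation(2000)
            tr, te = coords[perm[:1000]], coords[perm[1000:]]
            d2 = ((te[:, None, :] - tr[None, :, :]) ** 2).sum(-1)
            from scipy.special import logsumexp

            return -np.mean(logsumexp(-d2 / h**2, axis=1) - np.log(h))

        grid_best = hs[int(np.argmin([objective(h) for h in hs]))]
        assert grid_best / 1.5 <= sel.h <= grid_best * 1.5
        assert all(np.isfinite(v) for v in curve.values())

    def test_scale_equivariance(self):
        rng = np.random.default_rng(3)
        coords = rng.standard_normal((800, 2))
        h1 = select_bandwidth(coords, seed=0).h
        h10 = select_bandwidth(coords * 10.0, seed=0).h
        assert h10 / h1 == pytest.approx(10.0, rel=0.1)

    def test_finer_structure_selects_smaller_bandwidth(self):
        rng = np.random.default_rng(5)
        two_blobs = np.vstack(
            [rng.normal(-3, 0.3, size=(1000, 2)), rng.normal(3, 0.3, size=(1000, 2))]
        )
        one_blob = rng.normal(0, two_blobs.std(), size=(2000, 2))
        assert select_bandwidth(two_blobs, seed=0).h < select_bandwidth(one_blob, seed=0).h

    def test_degenerate_input_errors(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.zeros((100, 2)))
        with pytest.raises(ValueError):
            select_bandwidth(np.random.default_rng(0).normal(size=(10, 2)))


class TestNeighborGraph:
    def test_unit_square_geometry(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        graph = approx_knn(coords, method="exact", n_neighbors=2, min_neighbors=1)
        for i in range(4):
            # the two edge-adjacent corners, never the diagonal one
            assert set(graph.indices[i]) == {j for j in range(4)
                                             if j != i and j != 3 - i}

    def test_distances_nondecreasing_rows(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(300, 2))
        graph = approx_knn(coords, method="exact")
        assert np.all(np.diff(graph.distances, axis=1) >= 0)

    def test_duplicate_point_zero_distance(self):
        coords = np.vstack([np.zeros((2, 2)), np.random.default_rng(0).normal(size=(30, 2))])
        graph = approx_knn(coords, method="exact", n_neighbors=3, min_neighbors=1)
        assert graph.distances[0, 0] == 0.0

    def test_neighbor_count_scales_linearly(self):
        coords = np.random.default_rng(0).normal(size=(5000, 2))
        graph = approx_knn(coords, neighbor_fraction=0.02, method="exact")
        assert graph.m == 100

    def test_lsh_recall_against_exact(self):
        coords = np.random.default_rng(0).normal(size=(5000, 2))
        exact = approx_knn(coords, neighbor_fraction=0.02, method="exact")
        lsh = approx_knn(coords, neighbor_fraction=0.02, method="lsh", seed=0)
        recall = np.mean(
            [
                len(np.intersect1d(a, b)) / exact.m
                for a, b in zip(exact.indices, lsh.indices)
            ]
        )
        assert recall >= 0.9

    def test_too_few_points_errors(self):
        with pytest.raises(ValueError):
            approx_knn(np.zeros((1, 2)), method="exact")


class TestPureClusters:
    def test_two_separated_blobs_two_modes(self):
        rng = np.random.default_rng(0)
        coords = np.vstack(
            [rng.normal(-10, 0.5, size=(400, 2)), rng.normal(10, 0.5, size=(400, 2))]
        )
        truth = np.repeat([0, 1], 400)
        graph = approx_knn(coords, method="exact")
        model = find_pure_clusters(coords, graph, h=0.5)
        assert model.n_clusters == 2
        assert adjusted_rand_score(truth, model.labels) == 1.0
        assert model.pure_mask.all()

    def test_single_blob_single_pure_cluster(self):
        coords = np.random.default_rng(1).normal(size=(500, 2))
        graph = approx_knn(coords, method="exact")
        h = select_bandwidth(coords, seed=0).h
        model = find_pure_clusters(coords, graph, h)
        assert model.n_clusters == 1
        assert np.all(model.labels == 0)
        assert model.pure_mask.all()

    def test_gradient_ascent_chain_reaches_single_peak(self):
        # 1-D chain with densities [1,2,3,2,1] and 2-neighborhoods: both
        # endpoints must ascend to the central peak
        coords = np.column_stack([np.arange(5.0), np.zeros(5)])
        indices = np.array([[1, 2], [0, 2], [1, 3], [2, 4], [3, 2]])
        distances = np.abs(coords[indices, 0] - coords[:, [0, 0]])
        graph = NeighborGraph(indices=indices, distances=distances)
        density = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        model = find_pure_clusters(coords, graph, h=1.0, density=density)
        assert list(model.modes) == [2]
        assert np.all(model.labels == 0)

    def test_mode_maximal_within_own_neighborhood(self):
        rng = np.random.default_rng(2)
        coords = rng.normal(size=(800, 2))
        graph = approx_knn(coords, method="exact")
        model = find_pure_clusters(coords, graph, h=0.3)
        for mode in model.modes:
            assert np.all(model.density[mode] >= model.density[graph.indices[mode]])

    def test_gradient_ascent_assigns_every_point(self):
        rng = np.random.default_rng(3)
        coords = rng.normal(size=(1000, 2))
        graph = approx_knn(coords, method="exact")
        model = find_pure_clusters(coords, graph, h=0.2)
        assert np.all(model.labels >= 0)
        assert set(np.unique(model.labels)) == set(range(model.n_clusters))

    def test_mode_set_matches_brute_force_scan(self):
        rng = np.random.default_rng(4)
        coords = np.vstack(
            [
                rng.normal(-4, 1.0, size=(250, 2)),
                rng.normal(4, 1.0, size=(250, 2)),
                rng.normal([0, 6], 1.0, size=(250, 2)),
            ]
        )
        m, h = 25, 0.8
        graph = approx_knn(coords, method="exact", n_neighbors=m)
        model = find_pure_clusters(coords, graph, h)
        expected, dens = brute_force_modes(coords, m, h)
        assert np.allclose(model.density, dens, rtol=1e-9)
        assert set(model.modes) == expected

    def test_purity_threshold_at_99_percent(self):
        # 100-point cluster whose members see 99 same-label neighbors -> pure;
        # with 98 -> not pure
        n = 100
        indices = np.tile(np.arange(1, n + 1), (n + 1, 1))
        for i in range(n + 1):
            row = [j for j in range(n + 1) if j != i]
            indices[i] = row[:n]
        graph = NeighborGraph(indices=indices, distances=np.zeros_like(indices, dtype=float))
        labels_99 = np.array([1] + [0] * n)  # one foreign point among each row's 100
        purity = _cluster_purities(labels_99, graph, 2)[0]
        assert purity == pytest.approx(0.99)
        assert purity >= 0.99
        labels_98 = np.array([1, 1] + [0] * (n - 1))
        purity2 = _cluster_purities(labels_98, graph, 2)[0]
        assert purity2 < 0.99


class TestExtendedMerge:
    def test_oversplit_blob_merges_back(self):
        # force an over-split by using a bandwidth far below the held-out
        # optimum on a single Gaussian blob
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(1500, 2))
        graph = approx_knn(coords, method="exact", n_neighbors=12)
        h = select_bandwidth(coords, seed=0).h
        model = find_pure_clusters(coords, graph, h * 0.05)
        assert model.n_clusters > 1  # fixture premise: noisy density over-splits
        merged = extended_neighborhood_merge(
            model, coords, relax_factor=4.0, purity_drop=0.05, graph=graph
        )
        assert merged.n_clusters < model.n_clusters

    def test_separated_blobs_merge_is_noop(self):
        rng = np.random.default_rng(1)
        coords = np.vstack(
            [rng.normal(-10, 0.5, size=(300, 2)), rng.normal(10, 0.5, size=(300, 2))]
        )
        graph = approx_knn(coords, method="exact")
        model = find_pure_clusters(coords, graph, h=0.5)
        merged = extended_neighborhood_merge(model, coords, graph=graph)
        assert merged.n_clusters == model.n_clusters == 2
        assert adjusted_rand_score(model.labels, merged.labels) == 1.0

    def test_merge_closure_is_transitive(self):
        # an elongated blob over-split into >= 3 fragments must end in one
        # cluster: chained pairwise merges imply a shared label (union-find)
        rng = np.random.default_rng(2)
        coords = np.column_stack([rng.uniform(-10, 10, 4000), rng.normal(0, 0.5, 4000)])
        graph = approx_knn(coords, method="exact", n_neighbors=15)
        h = select_bandwidth(coords, seed=0).h
        model = find_pure_clusters(coords, graph, h * 0.05)
        assert model.n_clusters >= 3
        merged = extended_neighborhood_merge(
            model, coords, relax_factor=6.0, purity_drop=0.05, graph=graph
        )
        assert merged.n_clusters <= model.n_clusters // 2
        # labels must still form a valid partition indexed 0..K-1
        assert set(np.unique(merged.labels)) == set(range(merged.n_clusters))

    def test_parameter_errors(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(100, 2))
        graph = approx_knn(coords, method="exact", n_neighbors=10)
        model = find_pure_clusters(coords, graph, h=0.5)
        with pytest.raises(ValueError):
            extended_neighborhood_merge(model, coords, relax_factor=1.0)
        with pytest.raises(ValueError):
            extended_neighborhood_merge(model, coords, purity_drop=0.0)
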