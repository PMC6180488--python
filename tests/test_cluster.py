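from itertools import combinations

import igraph
import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from satkit import (
    ClusteringParams,
    cluster_pipeline,
    iterative_recluster,
    knn_jaccard_graph,
    louvain_cluster,
    pc_correlation,
)
from satkit.cluster import NeighborGraph, _knn_sets
from satkit.errors import SatkitError
from satkit.qc import EmbeddingSpace


def space_from_coords(coords, barcodes=None, n_significant=None):
    coords = np.asarray(coords, dtype=float)
    n, d = coords.shape
    return EmbeddingSpace(
        pc_scores=coords,
        pc_loadings=np.zeros((d, d)),
        eigenvalues=np.arange(d, 0, -1, dtype=float),
        gene_names=[f"g{i}" for i in range(d)],
        barcodes=barcodes or [f"c{i}" for i in range(n)],
        gene_means=np.zeros(d),
        gene_scales=np.ones(d),
        n_significant=n_significant or d,
    )


def brute_force_weights(coords, k):
    """Neighbor sets by explicit sorting; Jaccard by set arithmetic."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    sets = []
    for i in range(n):
        d = np.linalg.norm(coords - coords[i], axis=1)
        order = sorted(range(n), key=lambda j: (d[j], j))
        sets.append(set(j for j in order if j != i)[:k] if False else set([j for j in order if j != i][:k]))
    weights = {}
    for i, j in combinations(range(n), 2):
        inter = len(sets[i] & sets[j])
        union = len(sets[i] | sets[j])
        if inter:
            weights[(i, j)] = inter / union
    return weights


class TestJaccardGraph:
    def test_identical_neighbor_sets_weight_one(self):
        # cells 0 and 1 both have {2, 3} as nearest neighbors -> Jaccard 1
        coords = [[0, 10], [0, -10], [0, 0], [1, 0], [50, 0], [60, 0]]
        graph = knn_jaccard_graph(space_from_coords(coords), ClusteringParams(n_neighbors=2))
        w = {tuple(e): wt for e, wt in zip(graph.edges.tolist(), graph.weights)}
        assert w[(0, 1)] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(0)
        coords = rng.random((30, 3))
        params = ClusteringParams(n_neighbors=4)
        graph = knn_jaccard_graph(space_from_coords(coords), params)
        oracle = brute_force_weights(coords, 4)
        got = {tuple(e): wt for e, wt in zip(graph.edges.tolist(), graph.weights)}
        assert got == pytest.approx(oracle)

    def test_knn_edges_only_subset_of_snn(self):
        rng = np.random.default_rng(1)
        coords = rng.random((40, 3))
        space = space_from_coords(coords)
        sparse = knn_jaccard_graph(space, ClusteringParams(n_neighbors=5, knn_edges_only=True))
        dense = knn_jaccard_graph(space, ClusteringParams(n_neighbors=5))
        sparse_edges = set(map(tuple, sparse.edges.tolist()))
        dense_edges = set(map(tuple, dense.edges.tolist()))
        assert sparse_edges <= dense_edges

    def test_weights_in_unit_interval(self):
        rng = np.random.default_rng(2)
        graph = knn_jaccard_graph(space_from_coords(rng.random((50, 4))), ClusteringParams())
        assert (graph.weights > 0).all() and (graph.weights <= 1).all()

    def test_too_few_cells(self):
        with pytest.raises(SatkitError):
            knn_jaccard_graph(space_from_coords(np.eye(3)), ClusteringParams(n_neighbors=10))

    def test_tie_break_deterministic(self):
        # four corners of a square: all distances tied pairwise
        coords = [[0, 0], [0, 1], [1, 0], [1, 1]]
        a = _knn_sets(np.array(coords, float), 2).toarray()
        b = _knn_sets(np.array(coords, float), 2).toarray()
        np.testing.assert_array_equal(a, b)


def exhaustive_modularity(g: igraph.Graph):
    """Best modularity over all partitions of a tiny graph."""
    n = g.vcount()

    def partitions(elements):
        if not elements:
            yield []
            return
        first, rest = elements[0], elements[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
            yield [[first]] + smaller

    best = -1.0
    for part in partitions(list(range(n))):
        membership = [0] * n
        for b, block in enumerate(part):
            for v in block:
                membership[v] = b
        best = max(best, g.modularity(membership, weights="weight"))
    return best


class TestLouvain:
    def two_clique_graph(self):
        edges, weights = [], []
        for block in ([0, 1, 2], [3, 4, 5]):
            for i, j in combinations(block, 2):
                edges.append((i, j))
                weights.append(1.0)
        edges.append((2, 3))
        weights.append(0.1)
        return NeighborGraph(
            nodes=[f"c{i}" for i in range(6)],
            edges=np.array(edges),
            weights=np.array(weights),
        )

    def test_two_cliques_split(self):
        graph = self.two_clique_graph()
        result = louvain_cluster(graph, ClusteringParams(louvain_seed=0))
        labels = np.array(result.labels)
        assert len(set(labels)) == 2
        assert len(set(labels[:3])) == 1 and len(set(labels[3:])) == 1

    def test_matches_exhaustive_modularity(self):
        """Louvain's partition attains the optimum over all partitions (6 nodes)."""
        graph = self.two_clique_graph()
        result = louvain_cluster(graph, ClusteringParams(louvain_seed=0))
        g = graph.to_igraph()
        membership = [int(l) for l in result.labels]
        assert g.modularity(membership, weights="weight") == pytest.approx(
            exhaustive_modularity(g)
        )

    def test_complete_graph_single_cluster(self):
        n = 6
        edges = list(combinations(range(n), 2))
        graph = NeighborGraph(
            nodes=[f"c{i}" for i in range(n)],
            edges=np.array(edges),
            weights=np.ones(len(edges)),
        )
        result = louvain_cluster(graph, ClusteringParams(louvain_seed=0))
        assert len(set(result.labels)) == 1

    def test_seed_determinism(self):
        graph = self.two_clique_graph()
        r1 = louvain_cluster(graph, ClusteringParams(louvain_seed=7))
        r2 = louvain_cluster(graph, ClusteringParams(louvain_seed=7))
        assert r1.labels == r2.labels

    def test_beats_singletons(self):
        rng = np.random.default_rng(3)
        coords = rng.random((60, 3))
        graph = knn_jaccard_graph(space_from_coords(coords), ClusteringParams(n_neighbors=5))
        result = louvain_cluster(graph, ClusteringParams(louvain_seed=0))
        g = graph.to_igraph()
        part = [int(l) for l in result.labels]
        assert g.modularity(part, weights="weight") >= g.modularity(
            list(range(60)), weights="weight"
        )


class TestPipeline:
    def test_recovers_planted_types(self, sim5_filtered):
        """Five strongly separated types are recovered nearly perfectly."""
        result, space = cluster_pipeline(sim5_filtered, ClusteringParams(louvain_seed=5))
        ari = adjusted_rand_score(sim5_filtered.truth_labels, result.labels)
        assert ari >= 0.9
        assert space.n_significant >= 2

    def test_determinism(self, sim5_filtered):
        p = ClusteringParams(louvain_seed=9)
        a, _ = cluster_pipeline(sim5_filtered, p)
        b, _ = cluster_pipeline(sim5_filtered, p)
        assert a.labels == b.labels

    def test_params_recorded(self, sim5_filtered):
        result, _ = cluster_pipeline(sim5_filtered, ClusteringParams(louvain_seed=1))
        assert result.params["n_neighbors"] == 10
        assert "n_significant" in result.params


class TestIterativeRecluster:
    def test_group_with_substructure_recovered(self):
        """Reclustering a group holding two planted subtypes separates them."""
        from satkit import QCParams, qc_filter, simulate
        from satkit.simulate import BroadType, SimConfig, Subtype

        cfg = SimConfig(
            n_cells=1200,
            n_genes=400,
            broad_types=[
                BroadType("A", 0.6, shift=2.0,
                          subtypes=[Subtype("A1", 0.5, shift=1.5, n_markers=15),
                                    Subtype("A2", 0.5, shift=1.5, n_markers=15)]),
                BroadType("B", 0.4, shift=2.0),
            ],
            seed=21,
        )
        matrix, _ = qc_filter(simulate(cfg), QCParams(min_genes=100))
        full, _ = cluster_pipeline(matrix, ClusteringParams(louvain_seed=3))
        # pick the clusters dominated by broad type A
        import pandas as pd

        broad = pd.Series([t.split("/")[0] for t in matrix.truth_labels])
        lab = pd.Series(full.labels)
        a_clusters = {
            c for c in lab.unique() if (broad[lab == c] == "A").mean() > 0.5
        }
        sub = iterative_recluster(matrix, full, a_clusters, ClusteringParams(louvain_seed=4))
        truth_sub = [
            t for t, l in zip(matrix.truth_labels, full.labels) if l in a_clusters
        ]
        ari = adjusted_rand_score(truth_sub, sub.labels)
        assert ari >= 0.9
        assert all("/" in l for l in sub.labels)  # namespaced under the group

    def test_unknown_group_rejected(self, sim5_filtered):
        full, _ = cluster_pipeline(sim5_filtered, ClusteringParams(louvain_seed=2))
        with pytest.raises(SatkitError):
            iterative_recluster(sim5_filtered, full, {"no-such-cluster"})

    def test_tiny_group_rejected(self, sim5_filtered):
        full, _ = cluster_pipeline(sim5_filtered, ClusteringParams(louvain_seed=2))
        smallest = min(set(full.labels), key=full.labels.count)
        params = ClusteringParams(n_neighbors=10_000)
        with pytest.raises((SatkitError, ValueError)):
            iterative_recluster(sim5_filtered, full, {smallest}, params)


class TestPCCorrelation:
    def test_self_correlation_diagonal_one(self, sim5_filtered):
        from satkit import normalize_counts, run_pca

        space = run_pca(
            normalize_counts(sim5_filtered),
            sim5_filtered.gene_names,
            sim5_filtered.barcodes,
            n_components=10,
        )
        corr = pc_correlation(space, space)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-10)

    def test_split_halves_share_top_pcs(self, sim5_filtered):
        """Two random halves of structured data find the same leading axes."""
        from satkit import normalize_counts, run_pca

        rng = np.random.default_rng(5)
        order = rng.permutation(sim5_filtered.n_cells)
        half1 = sim5_filtered.subset_cells([sim5_filtered.barcodes[i] for i in order[: len(order) // 2]])
        half2 = sim5_filtered.subset_cells([sim5_filtered.barcodes[i] for i in order[len(order) // 2 :]])
        spaces = [
            run_pca(normalize_counts(h), h.gene_names, h.barcodes, n_components=10)
            for h in (half1, half2)
        ]
        corr = pc_correlation(*spaces)
        assert (corr[:4].max(axis=1) >= 0.8).all()

    def test_sign_flip_invariant(self, sim5_filtered):
        from satkit import normalize_counts, run_pca

        space = run_pca(
            normalize_counts(sim5_filtered),
            sim5_filtered.gene_names,
            sim5_filtered.barcodes,
            n_components=5,
        )
        import copy

        flipped = copy.deepcopy(space)
        flipped.pc_loadings = -flipped.pc_loadings
        np.testing.assert_allclose(
            pc_correlation(space, flipped), pc_correlation(space, space), atol=1e-12
        )

    def test_no_shared_genes(self):
        a = space_from_coords(np.random.default_rng(0).random((5, 2)))
        b = space_from_coords(np.random.default_rng(1).random((5, 2)))
        b.gene_names = ["x0", "x1"]
        with pytest.raises(SatkitError):
            pc_correlation(a, b)
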