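import networkx as nx
import numpy as np
import pytest
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree as scipy_mst

from fragcompare.chemspace import (
    knn_graph,
    minimum_spanning_forest,
    tanimoto_distance_matrix,
    tmap_layout,
    tsne_embed,
)
from fragcompare.similarity import FingerprintSpec, fingerprint_matrix

from conftest import mol


def random_fps(n, bits, seed, density=0.3):
    rng = np.random.default_rng(seed)
    return (rng.random((n, bits)) < density).astype(np.uint8)


class TestKnnGraph:
    def test_small_collection_truncates_k(self):
        fps = fingerprint_matrix(
            [mol("CCO"), mol("CCN"), mol("CCC")], FingerprintSpec("morgan2_1024")
        )
        graph = knn_graph(fps, k=50)
        assert graph.number_of_edges() == 3  # complete graph on 3 nodes

    def test_duplicates_get_zero_weight(self):
        fps = fingerprint_matrix(
            [mol("CCO"), mol("OCC"), mol("c1ccccc1")], FingerprintSpec("maccs166")
        )
        graph = knn_graph(fps, k=2)
        assert graph[0][1]["weight"] == 0.0

    def test_single_fingerprint_errors(self):
        with pytest.raises(ValueError):
            knn_graph(random_fps(1, 64, 0), k=5)

    def test_lsh_mode_agrees_with_exact(self, np_like_records,
                                        synthetic_like_records):
        records = (np_like_records + synthetic_like_records)[:200]
        fps = fingerprint_matrix(
            [mol(r.raw_smiles) for r in records], FingerprintSpec("morgan2_1024")
        )
        exact = knn_graph(fps, k=5, exact_limit=10_000)
        approx = knn_graph(fps, k=5, kc=10, exact_limit=1, seed=0)
        shared = set(map(frozenset, exact.edges)) & set(map(frozenset, approx.edges))
        agreement = len(shared) / exact.number_of_edges()
        assert agreement >= 0.95


class TestMinimumSpanningForest:
    @pytest.mark.parametrize("seed", range(5))
    def test_total_weight_matches_scipy_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 100))
        graph = nx.gnp_random_graph(n, 0.2, seed=seed)
        for u, v in graph.edges:
            graph[u][v]["weight"] = float(rng.random())
        forest = minimum_spanning_forest(graph)
        dense = nx.to_numpy_array(graph, weight="weight")
        oracle = scipy_mst(csr_matrix(dense)).toarray().sum()
        mine = sum(d["weight"] for _, _, d in forest.edges(data=True))
        assert mine == pytest.approx(oracle, abs=1e-9)

    def test_spanning_forest_edge_count(self):
        graph = nx.gnp_random_graph(40, 0.05, seed=1)
        for u, v in graph.edges:
            graph[u][v]["weight"] = 1.0
        forest = minimum_spanning_forest(graph)
        n_components = nx.number_connected_components(graph)
        assert forest.number_of_edges() == 40 - n_components


class TestTmapLayout:
    def test_path_graph_mst_is_path(self):
        graph = nx.path_graph(4)
        for u, v in graph.edges:
            graph[u][v]["weight"] = 1.0
        result = tmap_layout(graph)
        assert len(result.edges) == 3
        assert result.coords.shape == (4, 2)

    def test_single_node_at_origin(self):
        graph = nx.Graph()
        graph.add_node(0)
        result = tmap_layout(graph)
        assert np.array_equal(result.coords, np.zeros((1, 2)))

    def test_empty_graph_errors(self):
        with pytest.raises(ValueError):
            tmap_layout(nx.Graph())

    def test_every_molecule_has_coordinates(self):
        fps = random_fps(30, 128, 3)
        result = tmap_layout(knn_graph(fps, k=4))
        assert result.coords.shape == (30, 2)
        assert not np.isnan(result.coords).any()

    def test_deterministic(self):
        fps = random_fps(25, 128, 4)
        a = tmap_layout(knn_graph(fps, k=4))
        b = tmap_layout(knn_graph(fps, k=4))
        assert np.array_equal(a.coords, b.coords)
        assert a.edges == b.edges

    def test_disjoint_bit_clusters_bridge_is_longest(self):
        # two clusters on disjoint bit blocks: every cross edge has distance
        # 1.0, strictly longer than any within-cluster edge
        rng = np.random.default_rng(0)
        fps = np.zeros((40, 128), dtype=np.uint8)
        fps[:20, :64] = rng.random((20, 64)) < 0.5
        fps[20:, 64:] = rng.random((20, 64)) < 0.5
        # k larger than the cluster size forces the graph to bridge
        forest = minimum_spanning_forest(knn_graph(fps, k=25))
        cross = [
            d["weight"] for u, v, d in forest.edges(data=True) if (u < 20) != (v < 20)
        ]
        within = [
            d["weight"] for u, v, d in forest.edges(data=True) if (u < 20) == (v < 20)
        ]
        assert cross
        assert min(cross) > max(within)

    def test_generator_clusters_cross_edges_longer_on_average(
        self, np_like_records, synthetic_like_records
    ):
        mols = [mol(r.raw_smiles) for r in np_like_records[:25]] + [
            mol(r.raw_smiles) for r in synthetic_like_records[:25]
        ]
        fps = fingerprint_matrix(mols, FingerprintSpec("morgan2_1024"))
        forest = minimum_spanning_forest(knn_graph(fps, k=8))
        cross = [
            d["weight"] for u, v, d in forest.edges(data=True) if (u < 25) != (v < 25)
        ]
        within = [
            d["weight"] for u, v, d in forest.edges(data=True) if (u < 25) == (v < 25)
        ]
        assert cross
        assert np.mean(cross) > np.mean(within)


class TestTsne:
    def test_determinism(self):
        fps = random_fps(60, 64, 5)
        a = tsne_embed(fps, perplexity=10, seed=11)
        b = tsne_embed(fps, perplexity=10, seed=11)
        assert np.array_equal(a.coords, b.coords)
        assert a.coords.shape == (60, 2)
        assert not np.isnan(a.coords).any()

    def test_too_small_errors(self):
        with pytest.raises(ValueError):
            tsne_embed(random_fps(4, 64, 0))

    def test_perplexity_reduced_with_warning(self):
        fps = random_fps(10, 64, 1)
        with pytest.warns(UserWarning, match="perplexity reduced"):
            result = tsne_embed(fps, perplexity=40.0, seed=0)
        assert result.params["perplexity"] < 40

    def test_two_clusters_separate(self, np_like_records, synthetic_like_records):
        mols = [mol(r.raw_smiles) for r in np_like_records[:40]] + [
            mol(r.raw_smiles) for r in synthetic_like_records[:40]
        ]
        fps = fingerprint_matrix(mols, FingerprintSpec("morgan2_1024"))
        result = tsne_embed(fps, perplexity=15, n_iter=300, seed=2)
        a, b = result.coords[:40], result.coords[40:]
        intra = np.mean(
            [np.linalg.norm(x - y) for x in a for y in a]
            + [np.linalg.norm(x - y) for x in b for y in b]
        )
        inter = np.mean([np.linalg.norm(x - y) for x in a for y in b])
        assert inter > intra

    def test_distance_matrix_symmetric_zero_diagonal(self):
        fps = random_fps(10, 64, 2)
        dist = tanimoto_distance_matrix(fps)
        assert np.allclose(dist, dist.T)
        assert np.allclose(np.diag(dist), 0.0)
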