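"""Network construction, association normalisation, community detection, pruning."""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from bibliomir import BibRecord, Corpus
from bibliomir.graphs import (
    WeightedGraph,
    collaboration_network,
    cooccurrence_network,
    normalize_association,
    prune_network,
    resolution_clustering,
    walktrap_communities,
)
from bibliomir.keywords import Thesaurus


def planted_block_graph(n_blocks, block_size, p_in=0.8, p_out=0.05, seed=0):
    """Planted-partition graph; node weight = strength (occurrence analog)."""
    rng = np.random.default_rng(seed)
    nodes = [f"n{i:02d}" for i in range(n_blocks * block_size)]
    labels = {n: i // block_size for i, n in enumerate(nodes)}
    g = WeightedGraph(nodes={n: 0.0 for n in nodes})
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            p = p_in if labels[a] == labels[b] else p_out
            if rng.random() < p:
                g.add_edge(a, b, 1.0)
    for n in nodes:
        g.nodes[n] = sum(g.neighbors(n).values()) or 1.0
    return g, labels


def _ari(partition, labels):
    names = sorted(labels)
    return adjusted_rand_score(
        [labels[n] for n in names], [partition.assignment[n] for n in names]
    )


class TestCollaborationNetwork:
    def test_two_country_article(self):
        rec = BibRecord(
            record_id="r", title="t", year=2020,
            authors=[("A", ["Dept, Univ, China"]), ("B", ["Lab, Inst, USA"])],
        )
        g = collaboration_network(Corpus(records=[rec]))
        assert g.nodes == {"China": 1.0, "United States": 1.0}
        assert g.edges == {("China", "United States"): 1.0}

    def test_no_collaboration_means_no_edges(self):
        records = [
            BibRecord(record_id=f"r{i}", title="t", year=2020,
                      authors=[("A", ["Dept, Univ, China"])])
            for i in range(3)
        ]
        g = collaboration_network(Corpus(records=records))
        assert g.edges == {}

    def test_planted_pair_counts_recovered(self, synthetic_corpus, ground_truth):
        g = collaboration_network(synthetic_corpus)
        # brute-force oracle: count articles containing each country pair
        from bibliomir.geo import load_country_aliases, record_author_countries

        aliases = load_country_aliases()
        expected_edges: dict = {}
        for rec in synthetic_corpus:
            countries = sorted(set(record_author_countries(rec, aliases)))
            for i, a in enumerate(countries):
                for b in countries[i + 1 :]:
                    expected_edges[(a, b)] = expected_edges.get((a, b), 0) + 1
        assert {k: v for k, v in g.edges.items()} == {
            k: float(v) for k, v in expected_edges.items()
        }


class TestCooccurrenceNetwork:
    def _corpus_one_article(self, keywords):
        rec = BibRecord(record_id="r", title="t", year=2020,
                        author_keywords=list(keywords), authors=[("A", [])])
        return Corpus(records=[rec])

    def test_full_counting_adds_one_per_pair(self):
        corpus = self._corpus_one_article(["proliferation", "metastasis", "invasion"])
        g = cooccurrence_network(corpus, min_occurrence=1, counting="full")
        assert len(g.edges) == 3
        assert set(g.edges.values()) == {1.0}

    def test_fractional_counting_half_per_pair_at_k3(self):
        corpus = self._corpus_one_article(["proliferation", "metastasis", "invasion"])
        g = cooccurrence_network(corpus, min_occurrence=1, counting="fractional")
        assert set(g.edges.values()) == {0.5}

    def test_fractional_unit_weight_per_keyword_per_article(self, synthetic_corpus, query_thesaurus):
        """Each keyword distributes exactly weight 1 across its pairs per article."""
        from bibliomir.keywords import record_keywords

        g = cooccurrence_network(
            synthetic_corpus, query_thesaurus, min_occurrence=5, counting="fractional"
        )
        kept = set(g.nodes)
        recomputed: dict = {}
        for rec in synthetic_corpus:
            in_article = sorted(record_keywords(rec, query_thesaurus) & kept)
            k = len(in_article)
            if k < 2:
                continue
            for i, a in enumerate(in_article):
                for b in in_article[i + 1 :]:
                    recomputed[(a, b)] = recomputed.get((a, b), 0.0) + 1.0 / (k - 1)
            # per-article unit distribution per keyword
            assert (k - 1) * (1.0 / (k - 1)) == pytest.approx(1.0)
        for key, w in g.edges.items():
            assert w == pytest.approx(recomputed[key])

    def test_threshold_matches_brute_force_frequency_filter(self, synthetic_corpus, query_thesaurus):
        from bibliomir.keywords import keyword_frequencies

        g = cooccurrence_network(synthetic_corpus, query_thesaurus, min_occurrence=5)
        freq = keyword_frequencies(synthetic_corpus, query_thesaurus, top_n=None)
        expected = set(freq[freq["frequency"] >= 5]["keyword"])
        assert set(g.nodes) == expected


class TestAssociationNormalization:
    def test_single_edge_formula(self):
        g = WeightedGraph(nodes={"a": 1.0, "b": 1.0}, edges={("a", "b"): 1.0})
        s = normalize_association(g)
        assert s.edges[("a", "b")] == pytest.approx(2.0)

    def test_uniform_complete_graph_all_equal(self):
        nodes = {c: 2.0 for c in "abcd"}
        g = WeightedGraph(nodes=nodes)
        for i, a in enumerate("abcd"):
            for b in "abcd"[i + 1 :]:
                g.add_edge(a, b, 1.0)
        s = normalize_association(g)
        assert len(set(round(v, 12) for v in s.edges.values())) == 1

    def test_matches_independent_formula_on_random_graph(self):
        g, _ = planted_block_graph(2, 8, seed=11)
        m = g.total_link_weight
        s = normalize_association(g)
        for (a, b), c in g.edges.items():
            assert s.edges[(a, b)] == pytest.approx(2 * m * c / (g.nodes[a] * g.nodes[b]))

    def test_zero_weight_endpoint_rejected(self):
        g = WeightedGraph(nodes={"a": 0.0, "b": 1.0}, edges={("a", "b"): 1.0})
        with pytest.raises(ValueError, match="zero node weight"):
            normalize_association(g)

    def test_support_preserved(self):
        g, _ = planted_block_graph(2, 6, seed=4)
        s = normalize_association(g)
        assert set(s.edges) == set(g.edges)
        assert all(v > 0 for v in s.edges.values())


class TestWalktrap:
    def test_two_disjoint_triangles_two_communities(self):
        g = WeightedGraph(nodes={c: 1.0 for c in "abcdef"})
        for e in [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]:
            g.add_edge(*e)
        part = walktrap_communities(g)
        assert part.n_clusters == 2
        assert part.assignment["a"] == part.assignment["b"] == part.assignment["c"]
        assert part.assignment["d"] == part.assignment["e"] == part.assignment["f"]

    def test_complete_graph_single_community(self):
        g = WeightedGraph(nodes={c: 1.0 for c in "abcde"})
        for i, a in enumerate("abcde"):
            for b in "abcde"[i + 1 :]:
                g.add_edge(a, b)
        assert walktrap_communities(g).n_clusters == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_planted_three_blocks_recovered(self, seed):
        g, labels = planted_block_graph(3, 10, p_in=0.8, p_out=0.05, seed=seed)
        part = walktrap_communities(g)
        assert _ari(part, labels) >= 0.9

    def test_deterministic(self):
        g, _ = planted_block_graph(3, 10, seed=7)
        assert walktrap_communities(g).assignment == walktrap_communities(g).assignment


class TestResolutionClustering:
    def test_gamma_to_zero_connected_graph_single_cluster(self):
        g, _ = planted_block_graph(3, 8, p_in=0.8, p_out=0.1, seed=2)
        part = resolution_clustering(g, resolution=1e-9, min_cluster_size=1, seed=5)
        assert part.n_clusters == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_two_planted_blocks_recovered(self, seed):
        g, labels = planted_block_graph(2, 12, p_in=0.8, p_out=0.05, seed=seed)
        part = resolution_clustering(g, resolution=0.5, min_cluster_size=10, seed=42)
        assert part.n_clusters == 2
        assert _ari(part, labels) >= 0.9

    def test_min_size_merging_flags_residual_when_unmergeable(self):
        g = WeightedGraph(nodes={c: 1.0 for c in "abcdef"})
        for e in [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]:
            g.add_edge(*e)
        part = resolution_clustering(g, resolution=0.5, min_cluster_size=10, seed=1)
        # disjoint triangles cannot merge across components: flagged residual
        assert part.n_clusters == 2
        assert part.residual == set(part.assignment.values())

    def test_min_size_merging_collapses_connected_small_clusters(self):
        g = WeightedGraph(nodes={c: 1.0 for c in "abcdef"})
        for e in [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")]:
            g.add_edge(*e)
        g.add_edge("c", "d", 0.1)  # weak bridge
        part = resolution_clustering(g, resolution=0.5, min_cluster_size=10, seed=1)
        assert part.n_clusters == 1

    def test_seed_reproducible_and_covers_all_nodes(self):
        g, _ = planted_block_graph(3, 10, seed=9)
        p1 = resolution_clustering(g, seed=123, min_cluster_size=1)
        p2 = resolution_clustering(g, seed=123, min_cluster_size=1)
        assert p1.assignment == p2.assignment
        assert set(p1.assignment) == set(g.nodes)


class TestPrune:
    def test_contract_max_nodes_no_isolates(self):
        g, _ = planted_block_graph(5, 7, seed=3)  # 35 nodes
        pruned = prune_network(g, max_nodes=30, min_edges_per_node=1)
        assert len(pruned.nodes) <= 30
        assert all(pruned.degree(n) >= 1 for n in pruned.nodes)

    def test_star_graph_to_two_nodes(self):
        g = WeightedGraph(nodes={"hub": 10.0, "x": 3.0, "y": 2.0, "z": 1.0})
        for leaf in ("x", "y", "z"):
            g.add_edge("hub", leaf, 1.0)
        pruned = prune_network(g, max_nodes=2)
        assert set(pruned.nodes) == {"hub", "x"}
        assert pruned.edges == {("hub", "x"): 1.0}

    def test_compliant_graph_unchanged(self):
        g, _ = planted_block_graph(2, 5, p_in=1.0, p_out=0.5, seed=0)
        pruned = prune_network(g, max_nodes=30, min_edges_per_node=1)
        assert pruned.nodes == g.nodes and pruned.edges == g.edges
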