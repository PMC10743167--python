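"""Interaction-graph construction and MCC hub scoring."""

import math

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from _brute import brute_maximal_cliques, brute_mcc
from evhub import datasets, network
from evhub.simulate import gen_ppi


def _edges_file(tmp_path, rows, header="protein1\tprotein2\tcombined_score"):
    path = tmp_path / "edges.tsv"
    path.write_text(header + "\n" + "\n".join("\t".join(map(str, r)) for r in rows) + "\n")
    return path


class TestReadEdges:
    def test_score_threshold(self, tmp_path):
        path = _edges_file(
            tmp_path,
            [("a", "b", 300), ("b", "c", 400), ("c", "d", 700), ("d", "a", 900)],
        )
        graph = network.read_edges(path, score_min=400)
        assert graph.number_of_edges() == 3
        assert not graph.has_edge("a", "b")

    def test_reversed_duplicate_collapses(self, tmp_path):
        path = _edges_file(tmp_path, [("a", "b", 900), ("b", "a", 900)])
        assert network.read_edges(path).number_of_edges() == 1

    def test_missing_score_column_keeps_all(self, tmp_path, caplog):
        path = _edges_file(tmp_path, [("a", "b"), ("b", "c")], header="protein1\tprotein2")
        with caplog.at_level("WARNING"):
            graph = network.read_edges(path)
        assert graph.number_of_edges() == 2
        assert "combined_score" in caplog.text

    def test_prefix_stripping(self, tmp_path):
        path = _edges_file(tmp_path, [("10090.P1", "10090.P2", 900)])
        graph = network.read_edges(path, strip_prefix="10090.")
        assert set(graph.nodes) == {"P1", "P2"}


class TestMaximalCliques:
    def test_triangle(self):
        cliques = network.maximal_cliques(nx.complete_graph(["a", "b", "c"]))
        assert [set("abc")] == cliques

    def test_path(self):
        cliques = network.maximal_cliques(nx.path_graph(["a", "b", "c"]))
        assert sorted(map(sorted, cliques)) == [["a", "b"], ["b", "c"]]

    def test_node_guard(self):
        with pytest.raises(ValueError, match="guard"):
            network.maximal_cliques(nx.empty_graph(10), max_nodes=5)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_subset_enumeration_oracle(self, seed):
        graph = nx.gnp_random_graph(12, 0.4, seed=seed)
        got = {frozenset(c) for c in network.maximal_cliques(graph)}
        assert got == brute_maximal_cliques(graph)


class TestMccScores:
    def test_triangle_member_scores_two(self):
        scores = network.mcc_scores(nx.complete_graph(3)).set_index("gene")
        assert (scores["mcc"] == math.factorial(2)).all()

    def test_path_center_equals_degree(self):
        scores = network.mcc_scores(nx.path_graph(["a", "b", "c"])).set_index("gene")
        assert scores.loc["b", "mcc"] == 2 == scores.loc["b", "degree"]

    def test_isolated_node_scores_zero(self):
        graph = nx.Graph()
        graph.add_node("lonely")
        graph.add_edge("a", "b")
        scores = network.mcc_scores(graph).set_index("gene")
        assert scores.loc["lonely", "mcc"] == 0

    def test_triangle_free_graph_mcc_equals_degree(self):
        graph = nx.random_tree(20, seed=4) if hasattr(nx, "random_tree") else nx.random_labeled_tree(20, seed=4)
        scores = network.mcc_scores(graph)
        assert (scores["mcc"] == scores["degree"]).all()

    def test_total_mcc_equals_clique_weight_sum(self):
        graph = nx.gnp_random_graph(15, 0.35, seed=9)
        scores = network.mcc_scores(graph)
        expected = sum(
            len(c) * math.factorial(len(c) - 1)
            for c in network.maximal_cliques(graph)
            if len(c) >= 2
        )
        assert scores["mcc"].sum() == expected

    def test_planted_clique_dominates_sparse_background(self):
        graph = gen_ppi(50, 0.05, [6], seed=1)
        scores = network.mcc_scores(graph)
        ranking = network.rank_hubs(scores, top_k=10)
        clique = {f"PC0_{i:02d}" for i in range(6)}
        assert clique <= set(ranking.top_genes)
        oracle = brute_mcc(graph.subgraph(clique))
        assert all(oracle[v] == math.factorial(5) for v in clique)


class TestRankHubs:
    def test_published_candidate_order(self, nanog):
        rows = datasets.GD_CANDIDATES[nanog]
        scores = pd.DataFrame(
            [(g, mcc, deg) for g, mcc, deg, _ in rows], columns=["gene", "mcc", "degree"]
        ).sample(frac=1, random_state=0)  # permutation-invariance included
        ranking = network.rank_hubs(scores, top_k=30, n_candidates=5)
        assert ranking.candidates == ["Trp53", "Hif1a", "Esr1", "Atm", "Cdkn1b"]

    def test_all_equal_scores_order_lexicographically(self):
        scores = pd.DataFrame(
            [("z", 5, 2), ("a", 5, 2), ("m", 5, 2)], columns=["gene", "mcc", "degree"]
        )
        assert network.rank_hubs(scores, top_k=3).top_genes == ["a", "m", "z"]

    def test_degree_breaks_mcc_ties(self):
        scores = pd.DataFrame(
            [("low", 5, 1), ("high", 5, 9)], columns=["gene", "mcc", "degree"]
        )
        assert network.rank_hubs(scores, top_k=2).top_genes == ["high", "low"]

    def test_zero_candidates_still_reports_top(self):
        scores = pd.DataFrame([("a", 2, 1)], columns=["gene", "mcc", "degree"])
        ranking = network.rank_hubs(scores, top_k=1, n_candidates=0)
        assert ranking.candidates == [] and ranking.top_genes == ["a"]

    def test_top_k_above_node_count_warns(self, caplog):
        scores = pd.DataFrame([("a", 2, 1)], columns=["gene", "mcc", "degree"])
        with caplog.at_level("WARNING"):
            ranking = network.rank_hubs(scores, top_k=5)
        assert ranking.top_genes == ["a"] and "top_k" in caplog.text


class TestMirnaHubLinks:
    def test_counts_targets_inside_top_set(self, nanog, reference_maps):
        _, tm = reference_maps[nanog]
        top = list(tm.per_mirna["miR-18a-5p"])[:4]
        links = network.mirna_hub_links(top, tm)
        assert links["miR-18a-5p"] == 4
        assert sum(links.values()) == 4  # disjoint fixture: nobody else hits

    @pytest.mark.parametrize("comparison", datasets.COMPARISONS)
    def test_published_link_counts_recovered(self, comparison, reference_maps):
        # assemble a top set drawing the published number of links from each
        # miRNA's target set; the link counter must recover those numbers and
        # their per-comparison total of 30
        _, tm = reference_maps[comparison]
        summary = datasets.mirna_summary()
        rows = summary[summary["comparison"] == comparison]
        wanted = dict(zip(rows["mirna"], rows["n_top30_links"]))
        top: list[str] = []
        for mirna, k in wanted.items():
            top.extend(sorted(tm.per_mirna[mirna])[:k])
        links = network.mirna_hub_links(top, tm)
        assert links == wanted
        assert sum(links.values()) == 30

    def test_empty_top_set_gives_zero_counts(self, nanog, reference_maps):
        _, tm = reference_maps[nanog]
        links = network.mirna_hub_links([], tm)
        assert set(links.values()) == {0}


def test_sif_export_round_trips_edges(tmp_path):
    graph = gen_ppi(0, 0.0, [3], seed=0)
    graph.add_node("iso")
    path = tmp_path / "g.sif"
    network.write_sif(graph, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 4  # 3 clique edges + 1 isolated node
    assert lines[-1] == "iso"
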