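"""Disease-pair statistics: set overlap, network separation, GO similarity."""

import math
from collections import deque

import networkx as nx
import numpy as np
import pytest

from dgmine.network import (
    GOAnnotationTable,
    InteractionNetwork,
    classify_pair,
    disease_go_similarity,
    go_pair_similarity,
    jaccard_index,
    overlap_coefficient,
    separation_coefficient,
)

PATH_ABC = InteractionNetwork(edges=[("a", "b"), ("b", "c")])


class TestSetMeasures:
    def test_identical_sets_score_one(self):
        s = {"g1", "g2"}
        assert overlap_coefficient(s, s) == 1.0
        assert jaccard_index(s, s) == 1.0

    def test_disjoint_sets_score_zero(self):
        assert overlap_coefficient({"a"}, {"b"}) == 0.0
        assert jaccard_index({"a"}, {"b"}) == 0.0

    def test_worked_three_vs_four_example(self):
        a, b = {"g1", "g2", "g3"}, {"g2", "g3", "g4", "g5"}
        assert overlap_coefficient(a, b) == pytest.approx(2 / 3)
        assert jaccard_index(a, b) == pytest.approx(0.4)

    def test_overlap_dominates_jaccard(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = set(map(str, rng.choice(20, size=rng.integers(1, 10), replace=False)))
            b = set(map(str, rng.choice(20, size=rng.integers(1, 10), replace=False)))
            c, j = overlap_coefficient(a, b), jaccard_index(a, b)
            assert c >= j
            assert (c == 1.0) == (a <= b or b <= a)
            assert (j == 1.0) == (a == b)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            overlap_coefficient(set(), {"a"})
        with pytest.raises(ValueError):
            jaccard_index({"a"}, set())

    def test_four_way_classification(self):
        assert classify_pair({"a"}, {"a"}) == "identical"
        assert classify_pair({"a"}, {"a", "b"}) == "complete_subset"
        assert classify_pair({"a", "b"}, {"a"}) == "complete_subset"
        assert classify_pair({"a"}, {"b"}) == "complete_separation"
        assert classify_pair({"a", "b"}, {"b", "c"}) == "partial_overlap"


class TestSeparation:
    def test_path_graph_endpoints(self):
        res = separation_coefficient({"a"}, {"c"}, PATH_ABC)
        assert (res.d_ab, res.d_aa, res.d_bb, res.s_ab) == (2.0, 0.0, 0.0, 2.0)

    def test_shared_singleton_has_zero_separation(self):
        res = separation_coefficient({"a"}, {"a"}, PATH_ABC)
        assert res.s_ab == 0.0

    def test_identical_endpoint_sets_give_negative_separation(self):
        res = separation_coefficient({"a", "c"}, {"a", "c"}, PATH_ABC)
        assert res.d_ab == 0.0
        assert res.d_aa == res.d_bb == 2.0
        assert res.s_ab == -2.0

    def test_symmetry_in_the_two_sets(self):
        net = InteractionNetwork(edges=[("a", "b"), ("b", "c"), ("c", "d"), ("d", "e")])
        r1 = separation_coefficient({"a", "b"}, {"d", "e"}, net)
        r2 = separation_coefficient({"d", "e"}, {"a", "b"}, net)
        assert r1.s_ab == pytest.approx(r2.s_ab)

    def test_equal_sets_in_network_never_positive(self):
        rng = np.random.default_rng(1)
        for seed in range(10):
            g = nx.gnp_random_graph(12, 0.3, seed=seed)
            g.add_edges_from((i, i + 1) for i in range(11))  # keep it connected
            net = InteractionNetwork(graph=nx.relabel_nodes(g, str))
            genes = set(map(str, rng.choice(12, size=4, replace=False)))
            res = separation_coefficient(genes, genes, net)
            assert res.d_ab == 0.0
            assert res.s_ab <= 0.0

    def test_genes_absent_from_network_are_dropped_and_counted(self):
        res = separation_coefficient({"a", "ghost"}, {"c"}, PATH_ABC)
        assert res.n_dropped == 1
        assert res.s_ab == 2.0

    def test_disconnected_cross_sets_are_an_error(self):
        net = InteractionNetwork(edges=[("a", "b"), ("x", "y")])
        with pytest.raises(ValueError, match="unreachable"):
            separation_coefficient({"a"}, {"x"}, net)

    def test_unreachable_within_set_distance_excluded_and_counted(self):
        # components {a,b} and {x,y}; A spans both, B={a}
        net = InteractionNetwork(edges=[("a", "b"), ("x", "y")])
        res = separation_coefficient({"a", "x"}, {"a"}, net)
        assert res.n_unreachable > 0

    def test_matches_bruteforce_on_random_graphs(self):
        """Independent oracle: hand-written BFS + nearest-neighbor means."""
        rng = np.random.default_rng(77)
        checked = 0
        for seed in range(40):
            g = nx.gnp_random_graph(int(rng.integers(6, 30)), 0.18, seed=seed)
            net = InteractionNetwork(graph=nx.relabel_nodes(g, str))
            nodes = list(map(str, g.nodes))
            a = set(rng.choice(nodes, size=int(rng.integers(1, 5)), replace=False))
            b = set(rng.choice(nodes, size=int(rng.integers(1, 5)), replace=False))
            try:
                res = separation_coefficient(a, b, net)
            except ValueError:
                assert math.isinf(_oracle_d_ab(net.graph, a, b)[0])
                continue
            d_ab, _ = _oracle_d_ab(net.graph, a, b)
            assert res.d_ab == pytest.approx(d_ab)
            assert res.s_ab == pytest.approx(
                d_ab - (_oracle_d_xx(net.graph, a) + _oracle_d_xx(net.graph, b)) / 2
            )
            checked += 1
        assert checked >= 20


def _bfs(adj, src):
    dist = {src: 0}
    q = deque([src])
    while q:
        u = q.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                q.append(v)
    return dist


def _oracle_d_ab(graph, a, b):
    adj = {n: set(graph[n]) for n in graph}
    vals = []
    for src, targets in ((x, b) for x in a):
        d = _bfs(adj, src)
        vals.append(0.0 if src in b else min((d.get(t, math.inf) for t in targets)))
    for src in b:
        d = _bfs(adj, src)
        vals.append(0.0 if src in a else min((d.get(t, math.inf) for t in a)))
    finite = [v for v in vals if math.isfinite(v)]
    if not finite:
        return math.inf, len(vals)
    return sum(finite) / len(finite), len(vals) - len(finite)


def _oracle_d_xx(graph, genes):
    if len(genes) == 1:
        return 0.0
    adj = {n: set(graph[n]) for n in graph}
    vals = []
    for src in genes:
        d = _bfs(adj, src)
        vals.append(min((d.get(t, math.inf) for t in genes if t != src)))
    finite = [v for v in vals if math.isfinite(v)]
    return sum(finite) / len(finite) if finite else 0.0


class TestGoSimilarity:
    GO = GOAnnotationTable(
        [
            ("g1", "GO:1", "BP"),
            ("g2", "GO:1", "BP"),
            ("g1", "GO:2", "BP"),
            ("g2", "GO:2", "BP"),
            ("g3", "GO:2", "BP"),
            ("g4", "GO:2", "BP"),
            ("g3", "GO:3", "MF"),
            ("g4", "GO:3", "MF"),
        ]
    )

    def test_two_gene_shared_term_scores_one(self):
        assert go_pair_similarity("g1", "g2", self.GO, "BP") == 1.0

    def test_most_specific_shared_term_wins(self):
        # g3 and g4 share only GO:2 (n=4) in BP
        assert go_pair_similarity("g3", "g4", self.GO, "BP") == 0.5

    def test_no_shared_term_scores_zero(self):
        assert go_pair_similarity("g1", "g3", self.GO, "MF") == 0.0

    def test_aspects_are_separate(self):
        assert go_pair_similarity("g3", "g4", self.GO, "MF") == 1.0

    def test_disease_similarity_is_mean_over_cross_pairs(self):
        # pairs (g1,g2)=1.0 and (g1,g4)=0.5 -> mean 0.75
        assert disease_go_similarity({"g1"}, {"g2", "g4"}, self.GO, "BP") == pytest.approx(0.75)

    def test_all_pairs_specific_term_gives_one(self):
        go = GOAnnotationTable([("a", "GO:9", "CC"), ("b", "GO:9", "CC")])
        assert disease_go_similarity({"a"}, {"b"}, go, "CC") == 1.0

    def test_unknown_aspect_rejected(self):
        with pytest.raises(ValueError):
            GOAnnotationTable([("a", "GO:9", "XX")])

    def test_tsv_round_trip(self, tmp_path):
        p = tmp_path / "go.tsv"
        self.GO.to_tsv(p)
        back = GOAnnotationTable.from_tsv(p)
        assert back.term_sizes == self.GO.term_sizes


class TestNetworkIO:
    def test_edge_list_round_trip_with_comments(self, tmp_path):
        p = tmp_path / "net.tsv"
        p.write_text("# comment\na\tb\nb\tc\nb\ta\nc\tc\n")
        net = InteractionNetwork.from_tsv(p)
        assert sorted(net.graph.edges) == [("a", "b"), ("b", "c")]  # dups/self-loops gone
        q = tmp_path / "out.tsv"
        net.to_tsv(q)
        assert sorted(InteractionNetwork.from_tsv(q).graph.edges) == sorted(net.graph.edges)
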