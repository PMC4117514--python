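"""The MTRT heuristic: auxiliary graph, separators, scoring, recursion."""

import networkx as nx
import numpy as np
import pytest

from multriplet.multree import parse_newick
from multriplet.mtrt import (
    MTRTConfig,
    build_aux_graph,
    greedy_min_separators,
    mtrt_build,
    partition_components,
    score_separator,
)
from multriplet.triplets import is_consistent, trip, triplet_set

from conftest import random_binary_tree, random_triplet_set


class TestAuxGraph:
    def test_edges_from_cherries(self):
        g = build_aux_graph({trip("a", "b", "c"), trip("c", "d", "e")}, set("abcde"))
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("cd")}
        assert nx.number_connected_components(g) == 3

    def test_empty_set_gives_edgeless_graph(self):
        g = build_aux_graph(set(), {"a", "b", "c"})
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3

    def test_path_is_connected(self):
        g = build_aux_graph({trip("a", "b", "c"), trip("b", "c", "a")}, set("abc"))
        assert nx.is_connected(g)

    def test_label_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            build_aux_graph({trip("a", "b", "z")}, {"a", "b", "c"})


class TestSeparators:
    def test_path_cut_vertex(self):
        g = nx.path_graph(["a", "b", "c"])
        assert greedy_min_separators(g) == [frozenset({"b"})]

    def test_four_cycle(self):
        g = nx.cycle_graph(["a", "b", "c", "d"])
        assert greedy_min_separators(g) == [frozenset("ac"), frozenset("bd")]

    def test_complete_graph_has_no_separator(self):
        assert greedy_min_separators(nx.complete_graph(["a", "b", "c", "d"])) == []

    def test_disconnected_input_rejected(self):
        g = nx.Graph()
        g.add_nodes_from("abc")
        with pytest.raises(ValueError, match="disconnected"):
            greedy_min_separators(g)

    def test_every_separator_disconnects_and_is_minimal(self, rng):
        for rep in range(15):
            n = int(rng.integers(5, 10))
            g = nx.gnp_random_graph(n, 0.45, seed=int(rng.integers(2**31)))
            if not nx.is_connected(g):
                continue
            seps = greedy_min_separators(g)
            if not seps:
                continue
            k = nx.node_connectivity(g)
            for s in seps:
                assert len(s) == k
                rest = g.subgraph(set(g.nodes) - s)
                assert not nx.is_connected(rest)
                for v in s:  # minimality: no proper subset separates
                    smaller = g.subgraph(set(g.nodes) - (s - {v}))
                    assert nx.is_connected(smaller)


class TestPartition:
    def test_three_components_greedy_balance(self):
        x1, x2 = partition_components([{"a", "b"}, {"c", "d"}, {"e"}])
        assert x1 == {"a", "b", "e"}
        assert x2 == {"c", "d"}

    def test_two_components(self):
        assert partition_components([{"x"}, {"y", "z"}]) == ({"y", "z"}, {"x"})

    def test_deterministic_under_reordering(self):
        comps = [{"b"}, {"a"}, {"c"}]
        assert partition_components(comps) == partition_components(comps[::-1])

    def test_single_component_rejected(self):
        with pytest.raises(ValueError):
            partition_components([{"a", "b"}])


class TestScore:
    # fixed instance whose auxiliary graph is the 6-cycle a-b-c-d-e-f
    CYCLE6 = frozenset(
        [
            trip("a", "b", "d"),
            trip("b", "c", "e"),
            trip("c", "d", "f"),
            trip("d", "e", "a"),
            trip("e", "f", "b"),
            trip("f", "a", "c"),
        ]
    )

    def test_singleton_separator_reduces_to_balance_term(self):
        # path graph a-b-c-d-e via a chain of triplets; separator {c}
        chain = {trip("a", "b", "d"), trip("b", "c", "a"), trip("c", "d", "a"),
                 trip("d", "e", "a")}
        labels = set("abcde")
        w = score_separator(frozenset("c"), chain, labels, alpha=2.0)
        # sides {a,b,c} vs {c,d,e}: perfectly balanced, no triplet inside {c}
        assert w == 0.0

    def test_balance_monotonicity(self):
        # on the 6-cycle, antipodal separators split 4/4 (balanced) while
        # offset pairs split 3/5
        balanced = score_separator(frozenset("ad"), self.CYCLE6, set("abcdef"))
        skewed = score_separator(frozenset("ac"), self.CYCLE6, set("abcdef"))
        assert balanced < skewed

    def test_regression_values_on_cycle6(self):
        labels = set("abcdef")
        assert score_separator(frozenset("ad"), self.CYCLE6, labels) == 0.0
        assert score_separator(frozenset("be"), self.CYCLE6, labels) == 0.0
        assert score_separator(frozenset("ac"), self.CYCLE6, labels) == pytest.approx(1 / 3)

    def test_non_separator_rejected(self):
        with pytest.raises(ValueError):
            score_separator(frozenset("a"), self.CYCLE6, set("abcdef"))


class TestBuild:
    def test_single_triplet(self):
        out = mtrt_build({trip("a", "b", "c")}, {"a", "b", "c"})
        assert out.canonical_form() == "((a,b),c)"
        assert out.dup_count() == 0

    def test_conflicting_pair_needs_one_duplication(self):
        trips = {trip("a", "b", "c"), trip("b", "c", "a")}
        out = mtrt_build(trips, {"a", "b", "c"}, check=True)
        assert out.dup_count() == 1
        assert all(is_consistent(t, out) for t in trips)

    def test_dense_encoding_of_balanced_tree(self):
        src = parse_newick("((a,b),(c,d));")
        out = mtrt_build(triplet_set(src), src.label_set())
        assert out.is_isomorphic(src)
        assert out.dup_count() == 0

    def test_empty_triplet_set_gives_caterpillar(self):
        out = mtrt_build(set(), {"c", "a", "b", "d"})
        assert out.canonical_form() == "(((a,b),c),d)"

    def test_singleton_and_pair_label_sets(self):
        assert mtrt_build(set(), {"a"}).to_newick() == "a;"
        assert mtrt_build(set(), {"a", "b"}).canonical_form() == "(a,b)"

    def test_label_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            mtrt_build({trip("a", "b", "z")}, {"a", "b", "c"})

    def test_output_label_set_is_exactly_input(self, rng):
        for rep in range(20):
            labels = [f"s{i}" for i in range(int(rng.integers(3, 8)))]
            trips = random_triplet_set(rng, labels, int(rng.integers(0, 10)))
            out = mtrt_build(trips, labels)
            assert out.label_set() == set(labels)

    def test_output_consistent_with_every_triplet(self, rng):
        for rep in range(200):
            labels = [f"s{i}" for i in range(int(rng.integers(4, 9)))]
            trips = random_triplet_set(rng, labels, int(rng.integers(1, 13)))
            out = mtrt_build(trips, labels)
            assert all(is_consistent(t, out) for t in trips)

    def test_build_reduction_on_dense_encodings(self, rng):
        """With the full triplet encoding of a singly-labeled tree the
        auxiliary graph splits at every level and the heuristic reduces
        to Aho's BUILD: the source tree comes back exactly, dup 0."""
        for n in range(4, 13):
            labels = [f"x{i}" for i in range(n)]
            src = random_binary_tree(labels, rng)
            out = mtrt_build(triplet_set(src), src.label_set())
            assert out.is_isomorphic(src)
            assert out.dup_count() == 0

    def test_deterministic(self, rng):
        labels = [f"s{i}" for i in range(7)]
        trips = random_triplet_set(rng, labels, 12)
        a = mtrt_build(trips, labels)
        b = mtrt_build(set(sorted(trips)), list(reversed(labels)))
        assert a.canonical_form() == b.canonical_form()

    def test_alpha_is_configurable(self):
        # alpha only reweights the separator score; output stays consistent
        trips = TestScore.CYCLE6
        for alpha in (0.5, 2.0, 10.0):
            out = mtrt_build(trips, set("abcdef"), MTRTConfig(alpha=alpha))
            assert all(is_consistent(t, out) for t in trips)
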