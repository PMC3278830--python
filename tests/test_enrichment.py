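"""Permutation statistics: hypergeometric baseline, both nulls, combination,
and the merge score."""

import math

import networkx as nx
import numpy as np
import pytest

from netenrich.annotations import AnnotationSet
from netenrich.enrichment import (
    combine_pvalues,
    empirical_pvalue,
    enrich,
    fisher_tail_pvalue,
    function_randomization_pvalue,
    merge_compare,
    merge_score,
    randomize_network,
    structure_randomization_pvalue,
)
from netenrich.graph import component_size_seq, induced_subgraph


def _letters_graph(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    g.add_edges_from(edges)
    return g


class TestFisherTail:
    def test_exhaustive_example(self):
        # All C(10,4)=210 draws of 4 genes from 10; 55 contain >=3 of the 5
        # interesting genes: C(5,3)*C(5,1) + C(5,4) = 50 + 5.
        assert fisher_tail_pvalue(10, 5, 4, 3) == pytest.approx(55 / 210)

    def test_zero_overlap_is_certain(self):
        assert fisher_tail_pvalue(10, 5, 4, 0) == 1.0

    def test_whole_network_mode_is_one(self):
        # u = c forces c_f = u_f, so every term gets p = 1.
        for u_f in (1, 3, 7):
            assert fisher_tail_pvalue(10, 10, u_f, u_f) == pytest.approx(1.0)

    @pytest.mark.parametrize("args", [(5, 6, 2, 1), (5, 3, 6, 1), (5, 3, 3, 4)])
    def test_precondition_violations_raise(self, args):
        with pytest.raises(ValueError):
            fisher_tail_pvalue(*args)


class TestEmpiricalPvalue:
    def test_grid(self):
        assert empirical_pvalue(0, 100) == 0.0
        assert empirical_pvalue(100, 100) == 1.0
        assert empirical_pvalue(1, 100_000) == pytest.approx(1e-5)

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            empirical_pvalue(-1, 10)
        with pytest.raises(ValueError):
            empirical_pvalue(11, 10)
        with pytest.raises(ValueError):
            empirical_pvalue(0, 0)


class TestFunctionRandomization:
    def test_complete_graph_exact_probability(self):
        # G = K6 over {a..f}, H induced on {a,b,c,d}, f = {a,b}: cs(H_f)=[2];
        # a draw succeeds iff both genes land in C: C(4,2)/C(6,2) = 0.4.
        G = nx.complete_graph(6)
        G = nx.relabel_nodes(G, dict(enumerate("abcdef")))
        H = induced_subgraph(G, set("abcd"))
        iterations = 10_000
        p, observed = function_randomization_pvalue(G, H, {"a", "b"}, iterations, 0)
        assert observed == (2,)
        expected = 6 / 15
        tol = 3 * math.sqrt(expected * (1 - expected) / iterations)
        assert abs(p - expected) <= tol

    def test_edge_free_matches_fisher(self):
        # With no edges anywhere the test reduces to the one-sided Fisher test.
        G = _letters_graph([], nodes=[f"g{i}" for i in range(12)])
        H = _letters_graph([], nodes=[f"g{i}" for i in range(7)])
        genes = {"g0", "g1", "g8", "g9"}
        iterations = 20_000
        p, observed = function_randomization_pvalue(G, H, genes, iterations, 1)
        assert observed == (1, 1)
        expected = fisher_tail_pvalue(12, 7, 4, 2)
        tol = 3 * math.sqrt(expected * (1 - expected) / iterations)
        assert abs(p - expected) <= tol

    def test_empty_observed_cs_gives_one(self):
        G = nx.path_graph(6)
        G = nx.relabel_nodes(G, dict(enumerate("abcdef")))
        H = induced_subgraph(G, {"a", "b"})
        p, observed = function_randomization_pvalue(G, H, {"e", "f"}, 500, 2)
        assert observed == ()
        assert p == 1.0

    def test_no_universal_gene_raises(self):
        G = nx.path_graph(4)
        with pytest.raises(ValueError):
            function_randomization_pvalue(G, G, {"absent"}, 10, 0)

    def test_deterministic_given_seed(self):
        G = nx.gnp_random_graph(15, 0.3, seed=4)
        H = induced_subgraph(G, range(10))
        first = function_randomization_pvalue(G, H, {0, 1, 2, 3}, 2_000, 7)
        second = function_randomization_pvalue(G, H, {0, 1, 2, 3}, 2_000, 7)
        assert first == second

    def test_pvalue_on_grid(self):
        G = nx.gnp_random_graph(15, 0.3, seed=4)
        H = induced_subgraph(G, range(10))
        iterations = 777
        p, _ = function_randomization_pvalue(G, H, {0, 1, 2, 3}, iterations, 5)
        assert (p * iterations) == pytest.approx(round(p * iterations))


class TestRandomizeNetwork:
    families = [
        nx.path_graph(20),
        nx.gnp_random_graph(25, 0.2, seed=1),
        nx.barabasi_albert_graph(25, 2, seed=2),
        nx.complete_graph(7),
    ]

    def test_k_zero_is_identity(self):
        G = nx.gnp_random_graph(20, 0.2, seed=3)
        R = randomize_network(G, k=0, rng_seed=0)
        assert set(R.nodes) == set(G.nodes)
        assert set(map(frozenset, R.edges)) == set(map(frozenset, G.edges))

    @pytest.mark.parametrize("G", families)
    def test_invariants_preserved(self, G):
        for seed in range(10):
            R = randomize_network(G, k=10, rng_seed=seed)
            assert set(R.nodes) == set(G.nodes)
            assert R.number_of_edges() == G.number_of_edges()
            assert dict(R.degree) == dict(G.degree)
            assert not list(nx.selfloop_edges(R))

    def test_two_disjoint_edges_swap_enumeration(self):
        # {a,b},{c,d}: both endpoint pairings give two disjoint edges again,
        # so every randomization is a perfect matching on the same 4 nodes.
        G = _letters_graph([("a", "b"), ("c", "d")])
        matchings = set()
        for seed in range(30):
            R = randomize_network(G, k=10, rng_seed=seed)
            edges = frozenset(frozenset(e) for e in R.edges)
            assert dict(R.degree) == {n: 1 for n in "abcd"}
            matchings.add(edges)
        allowed = {
            frozenset({frozenset("ab"), frozenset("cd")}),
            frozenset({frozenset("ac"), frozenset("bd")}),
            frozenset({frozenset("ad"), frozenset("bc")}),
        }
        assert matchings <= allowed
        assert len(matchings) > 1  # swaps actually happen

    def test_fewer_than_two_edges_unchanged(self):
        G = _letters_graph([("a", "b")], nodes=["c"])
        R = randomize_network(G, k=10, rng_seed=0)
        assert set(map(frozenset, R.edges)) == {frozenset("ab")}

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            randomize_network(nx.path_graph(3), k=-1)


class TestStructureRandomization:
    def test_single_edge_graph_is_certain(self):
        G = _letters_graph([("a", "b")])
        p, observed = structure_randomization_pvalue(
            G, {"a", "b"}, {"a", "b"}, 200, k=10, rng_seed=0
        )
        assert observed == (2,)
        assert p == 1.0

    def test_all_singletons_is_certain(self):
        # No interactions among the annotated genes: any degree-preserving
        # rewiring compares >= the all-singleton sequence.
        G = nx.gnp_random_graph(12, 0.3, seed=5)
        G = nx.relabel_nodes(G, {i: f"g{i}" for i in G.nodes})
        independent = nx.maximal_independent_set(G, seed=1)[:3]
        p, observed = structure_randomization_pvalue(
            G, set(G.nodes), set(independent), 300, k=10, rng_seed=1
        )
        assert observed == (1,) * len(independent)
        assert p == 1.0

    def test_disjoint_from_interesting_set_is_certain(self):
        G = nx.path_graph(6)
        p, observed = structure_randomization_pvalue(
            G, {0, 1, 2}, {4, 5}, 100, k=10, rng_seed=2
        )
        assert observed == ()
        assert p == 1.0

    def test_interesting_genes_outside_universe_raise(self):
        G = nx.path_graph(4)
        with pytest.raises(ValueError):
            structure_randomization_pvalue(G, {0, 99}, {0}, 10, k=1, rng_seed=0)

    def test_observed_cs_override_for_non_induced_interesting_network(self):
        # A non-induced H can make the observed statistic strictly smaller
        # than the induced one, raising the p-value.
        G = _letters_graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")])
        induced_p, _ = structure_randomization_pvalue(
            G, set("abcd"), set("abc"), 300, k=10, rng_seed=3
        )
        sparse_p, _ = structure_randomization_pvalue(
            G, set("abcd"), set("abc"), 300, k=10, rng_seed=3,
            observed_cs=(1, 1, 1),
        )
        assert sparse_p == 1.0
        assert induced_p <= sparse_p


class TestCombineAndMergeScore:
    @pytest.mark.parametrize(
        "pf, ps, expected", [(0.01, 0.2, 0.2), (0.0, 0.0, 0.0), (0.4, 0.4, 0.4)]
    )
    def test_combine_is_max(self, pf, ps, expected):
        assert combine_pvalues(pf, ps) == expected

    def test_combine_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            combine_pvalues(-0.1, 0.5)

    def test_equal_pvalues_score_zero(self):
        assert merge_score(0.05, 0.05, 1e-5) == pytest.approx(0.0)

    def test_zero_floored_before_ratio(self):
        assert merge_score(0.1, 0.0, 1e-5) == pytest.approx(4.0)
        assert merge_score(0.0, 0.0, 1e-5) == pytest.approx(0.0)

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ValueError):
            merge_score(0.1, 0.2, 0.0)


class TestEnrich:
    def _ann(self, terms):
        return AnnotationSet(terms={t: frozenset(g) for t, g in terms.items()})

    def test_whole_network_mode_fisher_is_one_but_connectivity_is_not(
        self, clique_fixture
    ):
        net, ann = clique_fixture
        results = enrich(net, net, ann, iterations=400, k=10, rng_seed=0)
        by_term = {r.term: r for r in results}
        assert all(r.fisher_p == pytest.approx(1.0) for r in results)
        assert by_term["CONNECTED"].p_combined < 1.0
        assert by_term["FRAGMENTED"].p_combined == 1.0

    def test_connected_term_beats_fragmented_at_matched_size(self, clique_fixture):
        net, ann = clique_fixture
        results = {r.term: r for r in enrich(net, net, ann, iterations=400, k=10, rng_seed=1)}
        conn, frag = results["CONNECTED"], results["FRAGMENTED"]
        assert (conn.u_f, conn.c_f) == (frag.u_f, frag.c_f)
        assert conn.p_combined <= frag.p_combined

    def test_deterministic_and_sorted(self, clique_fixture):
        net, ann = clique_fixture
        first = enrich(net, net, ann, iterations=100, k=5, rng_seed=9)
        second = enrich(net, net, ann, iterations=100, k=5, rng_seed=9)
        assert first == second
        keys = [(r.p_combined, r.u_f, r.term) for r in first]
        assert keys == sorted(keys)

    def test_combined_is_max_and_on_grid(self, clique_fixture):
        net, ann = clique_fixture
        iterations = 250
        for r in enrich(net, net, ann, iterations=iterations, k=5, rng_seed=2):
            assert r.p_combined == max(r.p_function, r.p_structure)
            for p in (r.p_function, r.p_structure):
                assert (p * iterations) == pytest.approx(round(p * iterations))
            assert r.p_bh is not None and 0.0 <= r.p_bh <= 1.0

    def test_subgraph_violation_names_offenders(self):
        G = nx.path_graph(5)
        H = nx.Graph([(0, 1), (7, 8)])
        with pytest.raises(ValueError, match="nodes"):
            enrich(G, H, self._ann({"t": {0, 1}}), iterations=10, k=1, rng_seed=0)
        H2 = nx.Graph([(0, 2)])  # nodes present, edge absent from the path
        with pytest.raises(ValueError, match="edges"):
            enrich(G, H2, self._ann({"t": {0, 2}}), iterations=10, k=1, rng_seed=0)

    def test_term_without_universal_genes_skipped(self, caplog):
        G = nx.path_graph(4)
        ann = self._ann({"ghost": {"x"}, "real": {0, 1}})
        results = enrich(G, G, ann, iterations=50, k=2, rng_seed=0)
        assert [r.term for r in results] == ["real"]


class TestMergeCompare:
    def test_empty_removable_set_scores_zero(self, clique_fixture):
        net, ann = clique_fixture
        scores = merge_compare(net, set(), ann, iterations=200, k=5, rng_seed=0)
        assert scores and all(s.score == pytest.approx(0.0) for s in scores)

    def test_disconnecting_edges_yield_positive_score(self, clique_fixture):
        net, ann = clique_fixture
        conn_genes = sorted(ann.terms["CONNECTED"])
        # Remove every clique edge among the connected term's genes: without
        # them the term is fully fragmented, so adding them back helps.
        removable = {
            (a, b) for i, a in enumerate(conn_genes) for b in conn_genes[i + 1:]
        }
        scores = {s.term: s for s in merge_compare(
            net, removable, ann, iterations=400, k=10, rng_seed=0
        )}
        assert scores["CONNECTED"].score > 0
        assert scores["CONNECTED"].p_without > scores["CONNECTED"].p_with
        assert scores["FRAGMENTED"].score == pytest.approx(0.0)

    def test_keep_edges_are_retained(self, clique_fixture):
        net, ann = clique_fixture
        conn_genes = sorted(ann.terms["CONNECTED"])
        removable = {
            (a, b) for i, a in enumerate(conn_genes) for b in conn_genes[i + 1:]
        }
        scores = {s.term: s for s in merge_compare(
            net, removable, ann, iterations=400, k=10, rng_seed=0,
            keep_edges=removable,
        )}
        assert scores["CONNECTED"].score == pytest.approx(0.0)
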