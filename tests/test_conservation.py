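import itertools

import networkx as nx
import numpy as np
import pytest

from hallmarknet.conservation import (find_conserved, induced_edge_count,
                                      permutation_pvalue)
from hallmarknet.mcode import Community
from hallmarknet.util import derive_seed


def make_clique(g, labels):
    for a, b in itertools.combinations(labels, 2):
        g.add_edge(a, b)


class TestInducedEdgeCount:
    def test_disjoint_set_counts_zero(self):
        net = nx.Graph([("a", "b")])
        assert induced_edge_count({"x", "y"}, net) == 0

    def test_complete_graph_counts_all_pairs(self):
        net = nx.complete_graph(4)
        assert induced_edge_count(set(range(4)), net) == 6

    def test_matches_exhaustive_pair_enumeration(self):
        net = nx.relabel_nodes(nx.erdos_renyi_graph(20, 0.3, seed=2),
                               {i: f"n{i:02d}" for i in range(20)})
        rng = np.random.default_rng(0)
        nodes = sorted(net.nodes())
        for _ in range(10):
            genes = set(rng.choice(nodes, size=5, replace=False))
            expected = sum(1 for a, b in itertools.combinations(sorted(genes), 2)
                           if net.has_edge(a, b))
            assert induced_edge_count(genes, net) == expected


class TestPermutationPvalue:
    def test_zero_observed_edges_gives_p_one(self):
        net = nx.Graph([("a", "b"), ("c", "d"), ("e", "f")])
        res = permutation_pvalue({"a", "c", "e"}, net, n_permutations=100, seed=0)
        assert res.observed_edges == 0
        assert res.p_value == 1.0

    def test_unique_clique_in_sparse_network_is_significant(self):
        net = nx.Graph()
        net.add_nodes_from(f"n{i:03d}" for i in range(100))
        make_clique(net, [f"n{i:03d}" for i in range(5)])
        for seed in (0, 1, 7, 123):
            res = permutation_pvalue([f"n{i:03d}" for i in range(5)], net,
                                     n_permutations=1000, seed=seed)
            assert res.p_value <= 0.05

    def test_matches_exhaustive_enumeration_on_small_universe(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d"), ("e", "f")])
        genes = ["a", "b", "c"]
        observed = induced_edge_count(genes, net)
        exact = np.mean([induced_edge_count(s, net) >= observed
                         for s in itertools.combinations(sorted(net.nodes()), 3)])
        res = permutation_pvalue(genes, net, n_permutations=10_000, seed=3)
        se = np.sqrt(exact * (1 - exact) / 10_000)
        assert abs(res.p_value - exact) <= 3 * se

    def test_absent_genes_keep_full_set_size_by_default(self):
        net = nx.Graph([("a", "b"), ("b", "c"), ("a", "c")])
        full = permutation_pvalue({"a", "b", "missing"}, net, n_permutations=500, seed=1)
        assert full.n_genes_present == 2
        shrunk = permutation_pvalue({"a", "b", "missing"}, net, n_permutations=500,
                                    seed=1, shrink_to_present=True)
        # size-2 random sets have fewer chances to hit an edge than size-3 sets
        assert shrunk.exceed_count <= full.exceed_count

    def test_set_larger_than_universe_rejected(self):
        net = nx.Graph([("a", "b")])
        with pytest.raises(ValueError, match="universe"):
            permutation_pvalue({"a", "b", "c"}, net, n_permutations=10, seed=0)

    def test_p_nonincreasing_in_observed_edges(self):
        # adding an edge inside the community cannot raise p for fixed draws
        base = nx.relabel_nodes(nx.erdos_renyi_graph(30, 0.1, seed=5),
                                {i: f"n{i:02d}" for i in range(30)})
        genes = [f"n{i:02d}" for i in range(6)]
        for missing in itertools.combinations(genes, 2):
            if base.has_edge(*missing):
                continue
            denser = base.copy()
            denser.add_edge(*missing)
            p0 = permutation_pvalue(genes, base, n_permutations=400, seed=9).p_value
            p1 = permutation_pvalue(genes, denser, n_permutations=400, seed=9).p_value
            assert p1 <= p0 + 1e-12
            break

    def test_pseudo_pvalue_never_zero(self):
        net = nx.Graph()
        net.add_nodes_from(f"n{i:03d}" for i in range(100))
        make_clique(net, [f"n{i:03d}" for i in range(6)])
        res = permutation_pvalue([f"n{i:03d}" for i in range(6)], net,
                                 n_permutations=200, seed=0)
        assert res.p_value == 0.0
        assert res.pseudo_p_value == pytest.approx(1 / 201)


class TestFindConserved:
    def _networks(self, clique_sizes_by_cohort):
        networks = {}
        for cohort, sizes in clique_sizes_by_cohort.items():
            net = nx.Graph()
            net.add_nodes_from(f"n{i:03d}" for i in range(60))
            for label, size in sizes:
                make_clique(net, [f"{label}{i}" for i in range(size)])
            networks[cohort] = net
        return networks

    def test_small_community_never_conserved(self):
        networks = self._networks({"A": [("q", 4)], "B": [("q", 4)], "C": [("q", 4)]})
        comm = Community(genes=tuple(f"q{i}" for i in range(4)), seed="q0", score=4.0)
        results = find_conserved([comm], networks, seed_cohort="A", min_size=5,
                                 n_permutations=200, seed=0)
        assert all(e.p_value == 0.0 for e in results[0].per_cohort.values())
        assert not results[0].is_conserved

    def test_conserved_iff_significant_in_every_nonseed_cohort(self):
        networks = self._networks({
            "A": [("q", 6), ("z", 6)], "B": [("q", 6)], "C": [("q", 6)]})
        everywhere = Community(genes=tuple(f"q{i}" for i in range(6)), seed="q0", score=6.0)
        seed_only = Community(genes=tuple(f"z{i}" for i in range(6)), seed="z0", score=6.0)
        results = find_conserved([everywhere, seed_only], networks, seed_cohort="A",
                                 n_permutations=500, seed=1)
        assert results[0].is_conserved
        assert not results[1].is_conserved  # dense only in the seed cohort

    def test_conserved_at_alpha_stays_conserved_at_larger_alpha(self):
        networks = self._networks({"A": [("q", 6)], "B": [("q", 6)], "C": [("q", 6)]})
        comm = Community(genes=tuple(f"q{i}" for i in range(6)), seed="q0", score=6.0)
        strict = find_conserved([comm], networks, seed_cohort="A", alpha=0.05,
                                n_permutations=300, seed=2)
        loose = find_conserved([comm], networks, seed_cohort="A", alpha=0.2,
                               n_permutations=300, seed=2)
        assert strict[0].is_conserved <= loose[0].is_conserved

    def test_adding_communities_leaves_existing_draws_unchanged(self):
        networks = self._networks({"A": [("q", 6)], "B": [("q", 6)]})
        c1 = Community(genes=tuple(f"q{i}" for i in range(6)), seed="q0", score=6.0)
        c2 = Community(genes=("n000", "n001", "n002", "n003", "n004"), seed="n000", score=0.0)
        alone = find_conserved([c1], networks, seed_cohort="A", n_permutations=300, seed=5)
        together = find_conserved([c1, c2], networks, seed_cohort="A",
                                  n_permutations=300, seed=5)
        assert alone[0].per_cohort == together[0].per_cohort

    def test_needs_two_cohorts(self):
        networks = self._networks({"A": [("q", 6)]})
        with pytest.raises(ValueError, match="2 cohort"):
            find_conserved([], networks, seed_cohort="A")


def test_derive_seed_is_stable_and_bounded():
    s = derive_seed(42, "conservation", "cohort1")
    assert s == derive_seed(42, "conservation", "cohort1")
    assert 0 <= s < 2**31
    assert s != derive_seed(42, "conservation", "cohort2")
    assert s != derive_seed(43, "conservation", "cohort1")
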