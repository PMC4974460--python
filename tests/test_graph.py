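"""Hubs, communities, maximal cliques and cross-cell comparisons."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from dbpnet.cooperation import merge_scores
from dbpnet.graph import (Clique, centrality_ranking, compare_networks,
                          detect_communities, maximal_cliques,
                          merge_bins_to_sites, rank_cliques,
                          rank_loci_by_binding, shared_clique_sites,
                          specific_cliques)
from dbpnet.layout import GenomeLayout
from dbpnet.signal import EnrichmentMatrix


class TestCentrality:
    def test_star_hub_ranked_first(self):
        g = nx.star_graph(5)
        df = centrality_ranking(g)
        assert df.index[0] == 0
        assert df.loc[0, "degree_rank"] == 1.0
        assert df.loc[0, "eigenvector_rank"] == 1.0

    def test_path_middle_node_top(self):
        g = nx.path_graph(3)
        df = centrality_ranking(g)
        assert df.index[0] == 1

    def test_eigenvector_matches_dense_eigendecomposition(self, rng):
        g = nx.gnp_random_graph(8, 0.5, seed=5)
        df = centrality_ranking(g)
        comp = max(nx.connected_components(g), key=len)
        nodes = sorted(comp)
        A = nx.to_numpy_array(g.subgraph(nodes), nodelist=nodes)
        w, V = np.linalg.eigh(A)
        v = np.abs(V[:, np.argmax(w)])
        v = v / np.linalg.norm(v)
        for i, n in enumerate(nodes):
            assert df.loc[n, "eigenvector"] == pytest.approx(v[i], abs=1e-6)

    def test_empty_network_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            centrality_ranking(nx.Graph())


class TestCommunities:
    def test_two_triangles_modularity_half(self):
        g = nx.Graph([(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        comm = detect_communities(g)
        assert len(comm.groups) == 2
        # by hand: Q = 2 * (3/6 - (6/12)^2) = 1/2
        assert comm.modularity == pytest.approx(0.5)

    def test_complete_graph_single_community(self):
        comm = detect_communities(nx.complete_graph(6))
        assert len(comm.groups) == 1

    def test_planted_two_blocks_recovered(self):
        rng = np.random.default_rng(7)
        g = nx.Graph()
        g.add_nodes_from(range(20))
        for i, j in itertools.combinations(range(20), 2):
            same = (i < 10) == (j < 10)
            if rng.random() < (0.9 if same else 0.05):
                g.add_edge(i, j)
        comm = detect_communities(g)
        membership = comm.membership()
        blocks = [{membership[i] for i in range(10)},
                  {membership[i] for i in range(10, 20)}]
        assert all(len(b) == 1 for b in blocks)
        assert blocks[0] != blocks[1]

    def test_partition_covers_all_nodes(self, std_network):
        net, _ = std_network
        comm = detect_communities(net)
        members = [n for grp in comm.groups for n in grp]
        assert sorted(members) == sorted(net.nodes())
        assert comm.modularity >= 0.0  # at least the singleton partition


def _bruteforce_maximal_cliques(g, min_size):
    nodes = sorted(g.nodes())
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(g.has_edge(a, b) for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    return {frozenset(c) for c in cliques
            if not any(c < other for other in cliques)}


class TestCliques:
    def test_triangle_and_square(self):
        tri = nx.complete_graph(3)
        assert [c.members for c in maximal_cliques(tri)] == [(0, 1, 2)]
        square = nx.cycle_graph(4)
        assert maximal_cliques(square) == []

    @pytest.mark.parametrize("seed", range(12))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        g = nx.gnp_random_graph(n, 0.45, seed=seed)
        got = {frozenset(c.members) for c in maximal_cliques(g, min_size=3)}
        assert got == _bruteforce_maximal_cliques(g, 3)

    def test_every_clique_is_complete_in_network(self, std_network):
        net, _ = std_network
        for c in maximal_cliques(net, min_size=2):
            for a, b in itertools.combinations(c.members, 2):
                assert net.has_edge(a, b)


class TestRankCliques:
    def _pairs(self, names, mat):
        df = pd.DataFrame(mat, index=names, columns=names)
        return merge_scores(df, df)

    def test_higher_mean_score_ranks_first(self):
        names = list("abcdef")
        m = np.full((6, 6), 0.5)
        for i, j in itertools.combinations(range(3), 2):
            m[i, j] = m[j, i] = 0.9
        np.fill_diagonal(m, 1.0)
        pairs = self._pairs(names, m)
        cliques = [Clique(members=("a", "b", "c")),
                   Clique(members=("d", "e", "f"))]
        ranked = rank_cliques(cliques, pairs)
        assert ranked[0].members == ("a", "b", "c")
        assert ranked[0].rank == 1
        assert ranked[0].mean_merged == pytest.approx(0.9)

    def test_mean_matches_bruteforce(self, rng):
        names = list("abcd")
        a = rng.uniform(0, 1, (4, 4))
        m = (a + a.T) / 2
        np.fill_diagonal(m, 1.0)
        pairs = self._pairs(names, m)
        ranked = rank_cliques([Clique(members=("a", "b", "d"))], pairs)
        expected = np.mean([max(m[0, 1], m[0, 1]), m[0, 3], m[1, 3]])
        expected = np.mean([m[0, 1], m[0, 3], m[1, 3]])
        assert ranked[0].mean_merged == pytest.approx(expected)

    def test_missing_pair_rejected(self):
        pairs = self._pairs(["a", "b"], np.eye(2))
        with pytest.raises(KeyError):
            rank_cliques([Clique(members=("a", "x"))], pairs)


class TestCompareNetworks:
    def test_set_algebra(self):
        a = nx.Graph([("x", "y"), ("y", "z"), ("x", "z")])
        b = nx.Graph([("x", "y"), ("y", "w")])
        b.add_node("z")
        cmp = compare_networks(a, b)
        assert cmp["common"] == {frozenset(("x", "y"))}
        # restricted to shared nodes {x, y, z}: yz and xz are A-specific
        assert cmp["A_specific"] == {frozenset(("y", "z")),
                                     frozenset(("x", "z"))}
        assert cmp["B_specific"] == set()
        assert len(cmp["common"]) + len(cmp["A_specific"]) == 3

    def test_identical_and_disjoint(self):
        a = nx.Graph([("x", "y"), ("y", "z")])
        assert compare_networks(a, a.copy())["A_specific"] == set()
        b = nx.Graph()
        b.add_nodes_from(["x", "y", "z"])
        b.add_edge("x", "z")
        assert compare_networks(a, b)["common"] == set()

    def test_no_shared_nodes_rejected(self):
        with pytest.raises(ValueError, match="share no nodes"):
            compare_networks(nx.Graph([("a", "b")]), nx.Graph([("c", "d")]))

    def test_specific_cliques(self):
        a = nx.complete_graph(["x", "y", "z"])
        b = nx.Graph()
        b.add_nodes_from(["x", "y", "z"])
        out = specific_cliques(a, b)
        assert [c.members for c in out["A_specific"]] == [("x", "y", "z")]
        assert out["B_specific"] == [] and out["common"] == []
        same = specific_cliques(a, a.copy())
        assert same["A_specific"] == [] and same["B_specific"] == []
        assert [c.members for c in same["common"]] == [("x", "y", "z")]


class TestSharedSites:
    def _matrix(self, layout, score_rows, names):
        scores = np.asarray(score_rows, dtype=float)
        return EnrichmentMatrix(dbps=names, bin_ids=np.arange(scores.shape[1]),
                                scores=scores, layout=layout)

    def test_identical_binding_fraction_one(self, tiny_layout):
        rows = np.zeros((2, tiny_layout.n_bins))
        rows[:, [2, 3, 8]] = 3.0
        names = ["A", "B"]
        mat = self._matrix(tiny_layout, rows, names)
        out = shared_clique_sites(Clique(members=("A", "B")), mat, mat)
        assert out["fraction"] == 1.0
        # bins 2,3 merge into one site; bin 8 is its own site
        assert len(out["sitesA"]) == 2

    def test_disjoint_binding_zero_shared(self, tiny_layout):
        a = np.zeros((2, tiny_layout.n_bins))
        a[:, 2] = 3.0
        b = np.zeros((2, tiny_layout.n_bins))
        b[:, 9] = 3.0
        names = ["A", "B"]
        out = shared_clique_sites(
            Clique(members=("A", "B")),
            self._matrix(tiny_layout, a, names),
            self._matrix(tiny_layout, b, names))
        assert out["shared"] == 0

    def test_sites_do_not_cross_chromosomes(self, tiny_layout):
        # bins 11 (chr1 end) and 12 (chr2 start) are adjacent ids but
        # different chromosomes
        sites = merge_bins_to_sites(np.array([10, 11, 12]), tiny_layout)
        assert len(sites) == 2
        assert sites[0][0] != sites[1][0]


class TestRankLoci:
    def test_ordering_and_truncation(self, tiny_layout, rng):
        scores = np.zeros((4, tiny_layout.n_bins))
        scores[:, 5] = 2.0            # bound by 4 DBPs
        scores[:2, 9] = 2.0           # bound by 2
        scores[0, 1] = 9.0            # bound by 1, high score
        mat = EnrichmentMatrix(dbps=list("abcd"),
                               bin_ids=np.arange(tiny_layout.n_bins),
                               scores=scores, layout=tiny_layout)
        df = rank_loci_by_binding(mat, top_n=2)
        assert df["bin_id"].tolist() == [5, 9]
        full = rank_loci_by_binding(mat, top_n=3)
        assert full["bin_id"].tolist() == [5, 9, 1]

    def test_all_zero_matrix_empty(self, tiny_layout):
        mat = EnrichmentMatrix(dbps=["a", "b"],
                               bin_ids=np.arange(tiny_layout.n_bins),
                               scores=np.zeros((2, tiny_layout.n_bins)),
                               layout=tiny_layout)
        with pytest.warns(UserWarning, match="available"):
            df = rank_loci_by_binding(mat, top_n=5)
        assert df.empty
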