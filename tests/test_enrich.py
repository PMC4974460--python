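"""PPI overlap, randomisation p-values, clique co-binding and variant
enrichment."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dbpnet.cooperation import LoopSet
from dbpnet.enrich import (clique_cobinding, compare_categories,
                           gwas_enrichment, ppi_overlap, ppi_pvalue)
from dbpnet.graph import Clique
from dbpnet.signal import EnrichmentMatrix


def _ppi(edges):
    return nx.Graph(edges)


class TestPPIOverlap:
    def test_direct_indirect_neither(self):
        net = nx.Graph([("a", "b"), ("a", "c"), ("b", "d")])
        ppi = _ppi([("A", "B"), ("A", "M"), ("C", "M")])
        labels = ppi_overlap(net, ppi).set_index(["dbpA", "dbpB"])["label"]
        assert labels[("a", "b")] == "direct"
        assert labels[("a", "c")] == "indirect"   # via M
        assert labels[("b", "d")] == "neither"

    def test_partition_identity(self, rng):
        # direct + indirect + neither always covers every edge exactly once
        net = nx.gnp_random_graph(8, 0.4, seed=3)
        net = nx.relabel_nodes(net, {i: f"p{i}" for i in range(8)})
        ppi = nx.gnp_random_graph(12, 0.3, seed=4)
        ppi = nx.relabel_nodes(ppi, {i: f"P{i}" for i in range(12)})
        df = ppi_overlap(net, ppi)
        assert len(df) == net.number_of_edges()
        assert set(df["label"]) <= {"direct", "indirect", "neither"}

    def test_bruteforce_neighbourhood_oracle(self, rng):
        net = nx.gnp_random_graph(6, 0.5, seed=9)
        net = nx.relabel_nodes(net, {i: f"G{i}" for i in range(6)})
        ppi = nx.gnp_random_graph(6, 0.4, seed=10)
        ppi = nx.relabel_nodes(ppi, {i: f"G{i}" for i in range(6)})
        df = ppi_overlap(net, ppi).set_index(["dbpA", "dbpB"])["label"]
        for (a, b), label in df.items():
            if ppi.has_edge(a, b):
                expected = "direct"
            elif a in ppi and b in ppi and any(
                    ppi.has_edge(a, m) and ppi.has_edge(b, m)
                    for m in ppi if m not in (a, b)):
                expected = "indirect"
            else:
                expected = "neither"
            assert label == expected

    def test_empty_ppi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            ppi_overlap(nx.Graph([("a", "b")]), nx.Graph())


class TestPPIPvalue:
    def test_pvalue_floor_when_observed_tops_null(self):
        # the observed pair is the only PPI edge; random relabelings rarely hit it
        net = nx.Graph([("a", "b")])
        ppi = _ppi([("A", "B")])
        ppi.add_nodes_from([f"N{i}" for i in range(20)])
        res = ppi_pvalue(net, ppi, reps=500, seed=0)
        assert res["direct"].pvalue >= 1 / 501
        assert res["direct"].observed == 1

    def test_pvalue_near_one_when_observed_below_null(self):
        # network edge absent from a dense PPI: every relabeling scores >= 0
        ppi = nx.complete_graph(10)
        ppi = nx.relabel_nodes(ppi, {i: f"P{i}" for i in range(10)})
        net = nx.Graph([("x", "y")])   # unmapped names -> observed 0
        res = ppi_pvalue(net, ppi, reps=300, seed=0)
        assert res["direct"].pvalue == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        # small enough to enumerate every ordered relabeling exactly
        net = nx.Graph([("a", "b"), ("b", "c")])
        ppi = _ppi([("P0", "P1"), ("P1", "P2"), ("P2", "P3"), ("P3", "P4")])
        ppi.add_node("P5")
        nodes = sorted(net.nodes())
        ppi_edges = {frozenset(e) for e in ppi.edges()}
        neigh = {n: frozenset(ppi[n]) for n in ppi}
        obs = {"direct": 0, "indirect": 0}

        def count(labels):
            lab = dict(zip(nodes, labels))
            d = i = 0
            for a, b in net.edges():
                if frozenset((lab[a], lab[b])) in ppi_edges:
                    d += 1
                elif neigh.get(lab[a], frozenset()) & neigh.get(lab[b], frozenset()) \
                        - {lab[a], lab[b]}:
                    i += 1
            return d, i

        exact_d = []
        exact_i = []
        for perm in itertools.permutations(sorted(ppi.nodes()), len(nodes)):
            d, i = count(perm)
            exact_d.append(d)
            exact_i.append(i)
        obs_d, obs_i = count(["P0", "P1", "P2"])
        # ppi_pvalue's observed labels come from the network's own names; use
        # a network named exactly after PPI proteins so the statistic matches
        net2 = nx.relabel_nodes(net, {"a": "P0", "b": "P1", "c": "P2"})
        res = ppi_pvalue(net2, ppi, reps=20_000, seed=5)
        p_exact_d = np.mean(np.array(exact_d) >= obs_d)
        p_exact_i = np.mean(np.array(exact_i) >= obs_i)
        assert res["direct"].pvalue == pytest.approx(p_exact_d, abs=0.02)
        assert res["indirect"].pvalue == pytest.approx(p_exact_i, abs=0.02)

    def test_null_calibration_valid(self):
        # on data generated under the null, P(p <= alpha) <= alpha up to
        # sampling error (empirical p-values are discrete, hence conservative)
        ppi = nx.gnp_random_graph(15, 0.3, seed=2)
        ppi = nx.relabel_nodes(ppi, {i: f"P{i}" for i in range(15)})
        rng = np.random.default_rng(0)
        prot = np.array(sorted(ppi.nodes()), dtype=object)
        pvals = []
        for _ in range(200):
            lab = prot[rng.choice(len(prot), size=3, replace=False)]
            net = nx.Graph([(lab[0], lab[1]), (lab[1], lab[2])])
            res = ppi_pvalue(net, ppi, reps=200, seed=int(rng.integers(2**31)))
            pvals.append(res["direct"].pvalue)
        pvals = np.asarray(pvals)
        for alpha in (0.05, 0.1, 0.25, 0.5):
            reject = (pvals <= alpha).mean()
            margin = 3 * np.sqrt(alpha * (1 - alpha) / len(pvals))
            assert reject <= alpha + margin


def _toy_matrix(tiny_layout, rows, names):
    rows = np.asarray(rows, dtype=float)
    return EnrichmentMatrix(dbps=names, bin_ids=np.arange(rows.shape[1]),
                            scores=rows, layout=tiny_layout)


def _toy_loops():
    # two loops on chr1 of the 12-bin tiny layout: anchors 2 bins wide
    return LoopSet(np.array(["chr1", "chr1"], dtype=object),
                   np.array([0, 1000]), np.array([2000, 3000]),
                   np.array(["chr1", "chr1"], dtype=object),
                   np.array([8000, 9000]), np.array([10000, 11000]))


class TestCliqueCobinding:
    def test_disjoint_members_zero_shared(self, tiny_layout):
        rows = np.zeros((4, tiny_layout.n_bins))
        rows[0, 0] = rows[1, 5] = 3.0
        mat = _toy_matrix(tiny_layout, rows, list("abcd"))
        res = clique_cobinding(Clique(members=("a", "b")), mat, _toy_loops(),
                               n_samples=50, seed=0)
        assert res["shared_fraction"].observed == 0.0

    def test_matches_bruteforce_resampling(self, tiny_layout, rng):
        rows = (rng.random((5, tiny_layout.n_bins)) < 0.3) * 3.0
        names = list("abcde")
        mat = _toy_matrix(tiny_layout, rows, names)
        loops = _toy_loops()
        res = clique_cobinding(Clique(members=("a", "b")), mat, loops,
                               n_samples=200, seed=77)
        # independent re-draw with the same seed stream
        bound = rows > 0
        rng2 = np.random.default_rng(77)
        fracs = []
        for _ in range(200):
            idx = rng2.choice(5, size=2, replace=False)
            allb = bound[idx[0]] & bound[idx[1]]
            anyb = bound[idx[0]] | bound[idx[1]]
            fracs.append(allb.sum() / anyb.sum() if anyb.sum() else 0.0)
        obs = (bound[0] & bound[1]).sum() / (bound[0] | bound[1]).sum()
        assert res["shared_fraction"].observed == pytest.approx(obs)
        assert res["shared_fraction"].null_mean == pytest.approx(np.mean(fracs))
        expected_p = (1 + sum(f >= obs for f in fracs)) / 201
        assert res["shared_fraction"].pvalue == pytest.approx(expected_p)

    def test_oversized_clique_rejected(self, tiny_layout):
        mat = _toy_matrix(tiny_layout, np.zeros((2, tiny_layout.n_bins)),
                          ["a", "b"])
        with pytest.raises(ValueError, match="larger"):
            clique_cobinding(Clique(members=("a", "b", "c")), mat,
                             _toy_loops(), n_samples=10)


class TestGWASEnrichment:
    def _setup(self, tiny_layout):
        rows = np.zeros((2, tiny_layout.n_bins))
        rows[0, [0, 1, 8, 9]] = 3.0       # A: in both loop-anchor regions
        rows[1, [0, 1, 8, 9, 5]] = 3.0    # B: same plus a private site
        return _toy_matrix(tiny_layout, rows, ["A", "B"]), _toy_loops()

    def test_uniform_variants_ratio_one(self, tiny_layout):
        mat, loops = self._setup(tiny_layout)
        # a variant in every single bin: fg% = bg% = 100%
        variants = pd.DataFrame({
            "chrom": ["chr1"] * 12 + ["chr2"] * 8,
            "pos": [i * 1000 + 500 for i in range(12)]
                   + [i * 1000 + 500 for i in range(8)]})
        for label in ("1D-dominant", "3D-dominant", "1D-3D"):
            assert gwas_enrichment(("A", "B"), label, mat, loops,
                                   variants) == pytest.approx(1.0)

    def test_foreground_background_disjoint_and_guard(self, tiny_layout):
        mat, loops = self._setup(tiny_layout)
        # variants only inside the co-bound anchors: background % is 0
        variants = pd.DataFrame({"chrom": ["chr1"], "pos": [501]})
        assert np.isnan(gwas_enrichment(("A", "B"), "1D-dominant", mat,
                                        loops, variants))

    def test_hand_enumerated_ratio(self, tiny_layout):
        mat, loops = self._setup(tiny_layout)
        # 1D foreground: co-bound bins {0,1,8,9} -> sites (0-1) and (8-9);
        # background: B's private bin 5 -> one site.
        # variant in bin 0 (fg) and bin 5 (bg): fg% = 1/2, bg% = 1/1
        variants = pd.DataFrame({"chrom": ["chr1", "chr1"],
                                 "pos": [100, 5100]})
        ratio = gwas_enrichment(("A", "B"), "1D-dominant", mat, loops,
                                variants)
        assert ratio == pytest.approx(0.5)

    def test_unknown_class_rejected(self, tiny_layout):
        mat, loops = self._setup(tiny_layout)
        with pytest.raises(ValueError, match="class"):
            gwas_enrichment(("A", "B"), "bogus", mat, loops,
                            pd.DataFrame({"chrom": [], "pos": []}))


class TestCompareCategories:
    def test_identical_distributions_p_near_one(self):
        vals = [1.0, 1.0, 1.0, 1.0]
        out = compare_categories({"1D-dominant": vals}, vals)
        assert out["1D-dominant"] == 1.0

    def test_separated_groups_significant(self):
        hi = list(np.linspace(10, 12, 10))
        lo = list(np.linspace(1, 2, 10))
        out = compare_categories({"3D-dominant": hi}, lo)
        # complete separation of n=10 vs 10: U = 100, p far below 0.001
        u = stats.mannwhitneyu(hi, lo).statistic
        assert u == 100
        assert out["3D-dominant"] < 1e-3

    def test_nan_ratios_dropped(self):
        out = compare_categories(
            {"1D-3D": [5.0, 6.0, float("nan"), 7.0]}, [1.0, 1.1, 0.9])
        assert out["1D-3D"] < 0.2
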