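"""Topology of the cooperation network: hubs, communities, cliques and
cross-cell-type comparisons.

Hubs are ranked by the average of degree and eigenvector-centrality ranks.
Communities come from greedy modularity maximisation (Clauset-Newman-Moore)
on the unweighted graph. Maximal cliques — candidate protein complexes —
are enumerated exactly (Bron-Kerbosch with pivoting) and ranked by the mean
pairwise merged correlation of their members.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .cooperation import PairScoreTable
from .signal import EnrichmentMatrix

__all__ = [
    "centrality_ranking",
    "detect_communities",
    "maximal_cliques",
    "rank_cliques",
    "compare_networks",
    "specific_cliques",
    "shared_clique_sites",
    "rank_loci_by_binding",
    "Community",
    "Clique",
]


def centrality_ranking(net: nx.Graph) -> pd.DataFrame:
    """Degree and eigenvector centrality with averaged ranks per node.

    Eigenvector centrality is computed on the largest connected component
    (the principal adjacency eigenvector); nodes outside it get centrality 0
    and therefore rank last. Ranks are descending with ties averaged.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    deg = dict(net.degree())
    eig = {n: 0.0 for n in net}
    if net.number_of_edges() > 0:
        nodes = sorted(max(nx.connected_components(net), key=len))
        A = nx.to_numpy_array(net.subgraph(nodes), nodelist=nodes)
        w, V = np.linalg.eigh(A)
        v = np.abs(V[:, np.argmax(w)])
        v = v / np.linalg.norm(v)
        eig.update(dict(zip(nodes, v)))
    df = pd.DataFrame({
        "degree": pd.Series(deg, dtype=float),
        "eigenvector": pd.Series(eig, dtype=float),
    })
    df["degree_rank"] = df["degree"].rank(ascending=False, method="average")
    df["eigenvector_rank"] = df["eigenvector"].rank(ascending=False,
                                                    method="average")
    df["average_rank"] = (df["degree_rank"] + df["eigenvector_rank"]) / 2.0
    return df.sort_values("average_rank")


@dataclass
class Community:
    """A node partition with its modularity score."""

    groups: list[frozenset]
    modularity: float

    def membership(self) -> dict:
        return {n: i for i, grp in enumerate(self.groups) for n in grp}


def detect_communities(net: nx.Graph, weighted: bool = False) -> Community:
    """Greedy modularity maximisation on the (by default unweighted) graph."""
    if net.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes for community detection")
    weight = "merged" if weighted else None
    if net.number_of_edges() == 0:
        groups = [frozenset([n]) for n in net]
        return Community(groups=groups, modularity=0.0)
    groups = [frozenset(c) for c in
              nx.community.greedy_modularity_communities(net, weight=weight)]
    q = nx.community.modularity(net, groups, weight=weight)
    return Community(groups=groups, modularity=float(q))


@dataclass
class Clique:
    """A complete subgraph with its mean pairwise correlation scores."""

    members: tuple[str, ...]
    mean_merged: float = float("nan")
    mean_corr_1d: float = float("nan")
    mean_corr_3d: float = float("nan")
    rank: int | None = field(default=None, compare=False)

    def __len__(self) -> int:
        return len(self.members)


def maximal_cliques(net: nx.Graph, min_size: int = 3) -> list[Clique]:
    """All maximal cliques with at least ``min_size`` members.

    Exact enumeration via Bron-Kerbosch with pivoting; returned in a
    deterministic order (size descending, then lexicographic members).
    """
    cliques = [Clique(members=tuple(sorted(c)))
               for c in nx.find_cliques(net) if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), c.members))
    return cliques


def rank_cliques(cliques: list[Clique], pairs: PairScoreTable) -> list[Clique]:
    """Sort cliques by mean pairwise merged correlation, descending.

    Ties break by size (larger first) then lexicographic member order.
    """
    out = []
    for c in cliques:
        ms, c1, c3 = [], [], []
        for i, a in enumerate(c.members):
            for b in c.members[i + 1:]:
                if a not in pairs.merged.index or b not in pairs.merged.columns:
                    raise KeyError(f"pair ({a}, {b}) missing from score table")
                ms.append(float(pairs.merged.loc[a, b]))
                c1.append(float(pairs.corr1d.loc[a, b]))
                c3.append(float(pairs.corr3d.loc[a, b]))
        out.append(Clique(members=c.members, mean_merged=float(np.mean(ms)),
                          mean_corr_1d=float(np.mean(c1)),
                          mean_corr_3d=float(np.mean(c3))))
    out.sort(key=lambda c: (-c.mean_merged, -len(c.members), c.members))
    for r, c in enumerate(out, 1):
        c.rank = r
    return out


def _edge_set(net: nx.Graph, nodes: set) -> set[frozenset]:
    return {frozenset((a, b)) for a, b in net.edges()
            if a in nodes and b in nodes}


def compare_networks(netA: nx.Graph, netB: nx.Graph) -> dict:
    """Common and cell-type-specific edges over the shared node set."""
    shared = set(netA.nodes()) & set(netB.nodes())
    if not shared:
        raise ValueError("networks share no nodes")
    ea, eb = _edge_set(netA, shared), _edge_set(netB, shared)
    return {
        "shared_nodes": shared,
        "common": ea & eb,
        "A_specific": ea - eb,
        "B_specific": eb - ea,
    }


def specific_cliques(netA: nx.Graph, netB: nx.Graph,
                     min_size: int = 3) -> dict[str, list[Clique]]:
    """Maximal cliques made entirely of cell-type-specific (or common) edges."""
    cmp = compare_networks(netA, netB)

    def subgraph(edges: set[frozenset]) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(cmp["shared_nodes"])
        g.add_edges_from(tuple(e) for e in edges)
        return g

    return {
        "A_specific": maximal_cliques(subgraph(cmp["A_specific"]), min_size),
        "B_specific": maximal_cliques(subgraph(cmp["B_specific"]), min_size),
        "common": maximal_cliques(subgraph(cmp["common"]), min_size),
    }


def _cobound_sites(members, matrix: EnrichmentMatrix) -> list[tuple[str, int, int]]:
    """Maximal runs of adjacent retained bins bound by every member."""
    rows = [matrix.scores[matrix.dbp_index(m)] > 0 for m in members]
    all_bound = np.logical_and.reduce(rows)
    bins = matrix.bin_ids[all_bound]
    return merge_bins_to_sites(bins, matrix.layout)


def merge_bins_to_sites(bins: np.ndarray, layout) -> list[tuple[str, int, int]]:
    """Merge sorted global bin ids into maximal runs of adjacent bins."""
    sites = []
    if len(bins) == 0:
        return sites
    bins = np.sort(bins)
    run_start = bins[0]
    prev = bins[0]
    for b in bins[1:]:
        if b == prev + 1:
            prev = b
            continue
        sites.append((run_start, prev))
        run_start = prev = b
    sites.append((run_start, prev))
    out = []
    for s, e in sites:
        chrom, start, _ = layout.bin_interval(int(s))
        chrom2, _, end = layout.bin_interval(int(e))
        if chrom != chrom2:  # run crossed a chromosome boundary: split
            mid = int(s)
            while layout.bin_interval(mid)[0] == chrom and mid < int(e):
                mid += 1
            out.extend(merge_bins_to_sites(np.arange(s, mid), layout))
            out.extend(merge_bins_to_sites(np.arange(mid, e + 1), layout))
            continue
        out.append((chrom, start, end))
    return out


def shared_clique_sites(clique: Clique, matrixA: EnrichmentMatrix,
                        matrixB: EnrichmentMatrix) -> dict:
    """Sites co-bound by every clique member, and their cross-cell overlap.

    A "site" is a maximal run of adjacent 1-kb bins bound by all members.
    The shared count is the number of A sites overlapping any B site; the
    fraction uses cell A as the reference.
    """
    sitesA = _cobound_sites(clique.members, matrixA)
    sitesB = _cobound_sites(clique.members, matrixB)

    def overlaps(s, others):
        c, a0, a1 = s
        return any(c == oc and a0 < o1 and o0 < a1 for oc, o0, o1 in others)

    shared = sum(1 for s in sitesA if overlaps(s, sitesB))
    return {
        "sitesA": sitesA,
        "sitesB": sitesB,
        "shared": shared,
        "fraction": shared / len(sitesA) if sitesA else float("nan"),
    }


def rank_loci_by_binding(matrix: EnrichmentMatrix, top_n: int = 5000) -> pd.DataFrame:
    """Rank bins by how many DBPs bind them; emit the top loci.

    Ties break by total enrichment score, then genomic coordinate. Loci with
    zero binders are excluded. Intended as input for external GO tooling.
    """
    import warnings as _w

    n_bound = (matrix.scores > 0).sum(axis=0)
    total = matrix.scores.sum(axis=0)
    keep = n_bound > 0
    rows = []
    for b, nb, t in zip(matrix.bin_ids[keep], n_bound[keep], total[keep]):
        chrom, start, end = matrix.layout.bin_interval(int(b))
        rows.append((chrom, start, end, int(b), int(nb), float(t)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "bin_id",
                                     "n_dbps", "total_score"])
    df = df.sort_values(["n_dbps", "total_score", "chrom", "start"],
                        ascending=[False, False, True, True],
                        kind="mergesort").reset_index(drop=True)
    if top_n > len(df):
        _w.warn(f"requested top {top_n} loci but only {len(df)} available")
    return df.head(top_n)


def write_loci_bed(df: pd.DataFrame, path: str) -> None:
    df[["chrom", "start", "end", "bin_id", "n_dbps"]].to_csv(
        path, sep="\t", header=False, index=False)
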