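"""Statistical support for the cooperation network: overlap with known
protein-protein interactions, clique co-binding enrichment against random
protein sets, and disease-variant enrichment by cooperation class.

All randomisation tests report empirical p-values with the add-one rule
p = (1 + #{null >= observed}) / (replicates + 1), so p is floored at
1/(replicates+1) and never exactly zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .cooperation import LoopSet
from .graph import Clique, merge_bins_to_sites
from .signal import EnrichmentMatrix

__all__ = [
    "ppi_overlap",
    "ppi_pvalue",
    "clique_cobinding",
    "gwas_enrichment",
    "compare_categories",
    "EnrichmentResult",
]


@dataclass
class EnrichmentResult:
    """Observed statistic versus a randomisation null."""

    observed: float
    null_mean: float
    fold: float
    pvalue: float
    n_null: int
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "observed": self.observed, "null_mean": self.null_mean,
            "fold": self.fold, "pvalue": self.pvalue,
            "n_null": self.n_null, "seed": self.seed,
        }


def _fold(observed: float, null_mean: float) -> float:
    return observed / null_mean if null_mean > 0 else float("nan")


def ppi_overlap(net: nx.Graph, ppi: nx.Graph) -> pd.DataFrame:
    """Label each cooperation edge direct / indirect / neither against a PPI.

    Direct: the pair itself is a PPI edge. Indirect: some third protein in
    the PPI interacts with both. Node identifiers are matched uppercase;
    edges with an unmapped endpoint can only be labelled 'neither'.
    """
    if ppi.number_of_edges() == 0:
        raise ValueError("empty PPI network")
    rows = []
    for a, b in net.edges():
        ua, ub = a.upper(), b.upper()
        if ppi.has_edge(ua, ub):
            label = "direct"
        elif ua in ppi and ub in ppi and (
                set(ppi[ua]) & set(ppi[ub]) - {ua, ub}):
            label = "indirect"
        else:
            label = "neither"
        rows.append((a, b, label, ua in ppi, ub in ppi))
    return pd.DataFrame(rows, columns=["dbpA", "dbpB", "label",
                                       "A_mapped", "B_mapped"])


def _count_labels(edges, ppi_edges: set, neighbors: dict) -> tuple[int, int]:
    direct = indirect = 0
    for a, b in edges:
        if frozenset((a, b)) in ppi_edges:
            direct += 1
        elif (neighbors.get(a, frozenset()) & neighbors.get(b, frozenset())
              - {a, b}):
            indirect += 1
    return direct, indirect


def ppi_pvalue(net: nx.Graph, ppi: nx.Graph, reps: int = 100_000,
               seed: int | None = None) -> dict[str, EnrichmentResult]:
    """Significance of direct/indirect PPI overlap by node relabelling.

    Each replicate replaces the network's nodes with proteins drawn
    uniformly without replacement from the PPI network (topology preserved)
    and recounts direct and indirect edges.
    """
    if reps < 100:
        warnings.warn(f"only {reps} randomisation replicates; p-values coarse")
    proteins = sorted(ppi.nodes())
    nodes = sorted(net.nodes())
    if len(proteins) < len(nodes):
        raise ValueError("PPI network smaller than the cooperation node set")
    ppi_edges = {frozenset(e) for e in ppi.edges()}
    neighbors = {n: frozenset(ppi[n]) for n in ppi}
    edges = [(a.upper(), b.upper()) for a, b in net.edges()]
    obs_d, obs_i = _count_labels(edges, ppi_edges, neighbors)

    rng = np.random.default_rng(seed)
    edge_idx = [(nodes.index(a), nodes.index(b)) for a, b in net.edges()]
    null_d = np.empty(reps, dtype=np.int64)
    null_i = np.empty(reps, dtype=np.int64)
    prot_arr = np.array(proteins, dtype=object)
    for r in range(reps):
        lab = prot_arr[rng.choice(len(prot_arr), size=len(nodes), replace=False)]
        d, i = _count_labels([(lab[x], lab[y]) for x, y in edge_idx],
                             ppi_edges, neighbors)
        null_d[r] = d
        null_i[r] = i
    out = {}
    for key, obs, null in (("direct", obs_d, null_d), ("indirect", obs_i, null_i)):
        p = (1 + int((null >= obs).sum())) / (reps + 1)
        out[key] = EnrichmentResult(observed=float(obs),
                                    null_mean=float(null.mean()),
                                    fold=_fold(obs, null.mean()),
                                    pvalue=p, n_null=reps, seed=seed)
    return out


def _anchor_bin_sets(loops: LoopSet, layout) -> list[tuple[set, set]]:
    out = []
    for i in range(len(loops)):
        b1 = set(layout.bins_overlapping(loops.chrom1[i], int(loops.start1[i]),
                                         int(loops.end1[i])).tolist())
        b2 = set(layout.bins_overlapping(loops.chrom2[i], int(loops.start2[i]),
                                         int(loops.end2[i])).tolist())
        out.append((b1, b2))
    return out


def clique_cobinding(clique: Clique, matrix: EnrichmentMatrix, loops: LoopSet,
                     n_samples: int = 50_000,
                     seed: int | None = None) -> dict[str, EnrichmentResult]:
    """Co-binding of a clique's members versus random same-size DBP sets.

    Statistic 'shared_fraction': bins bound by every member divided by bins
    bound by any member. Statistic 'loops_hit': loops with at least one
    anchor overlapping a co-bound site. The null redraws the member set
    uniformly from the analysed DBP panel.
    """
    k = len(clique.members)
    if k > len(matrix.dbps):
        raise ValueError("clique larger than the available DBP panel")
    bound = matrix.scores > 0  # (n_dbps, n_bins)
    anchor_bins = _anchor_bin_sets(loops, matrix.layout)
    retained = {int(b): i for i, b in enumerate(matrix.bin_ids)}
    anchor_cols = [
        ({retained[b] for b in b1 if b in retained},
         {retained[b] for b in b2 if b in retained})
        for b1, b2 in anchor_bins
    ]

    def stats_for(idx: np.ndarray) -> tuple[float, int]:
        allb = np.logical_and.reduce(bound[idx])
        anyb = np.logical_or.reduce(bound[idx])
        n_any = int(anyb.sum())
        frac = float(allb.sum()) / n_any if n_any else 0.0
        shared_cols = set(np.flatnonzero(allb).tolist())
        hits = sum(1 for c1, c2 in anchor_cols
                   if (shared_cols & c1) or (shared_cols & c2))
        return frac, hits

    member_idx = np.array([matrix.dbp_index(m) for m in clique.members])
    obs_frac, obs_hits = stats_for(member_idx)

    rng = np.random.default_rng(seed)
    null_frac = np.empty(n_samples)
    null_hits = np.empty(n_samples)
    for r in range(n_samples):
        idx = rng.choice(len(matrix.dbps), size=k, replace=False)
        null_frac[r], null_hits[r] = stats_for(idx)
    out = {}
    for key, obs, null in (("shared_fraction", obs_frac, null_frac),
                           ("loops_hit", float(obs_hits), null_hits)):
        p = (1 + int((null >= obs).sum())) / (n_samples + 1)
        out[key] = EnrichmentResult(observed=obs, null_mean=float(null.mean()),
                                    fold=_fold(obs, float(null.mean())),
                                    pvalue=p, n_null=n_samples, seed=seed)
    return out


def _variant_bins(variants: pd.DataFrame, layout) -> set[int]:
    out = set()
    for chrom, pos in zip(variants["chrom"], variants["pos"]):
        if chrom not in layout.chroms:
            continue
        p0 = int(pos) - 1  # 1-based point -> 0-based
        if 0 <= p0 < layout.lengths[layout.chroms.index(chrom)]:
            out.add(layout.bin_index(chrom, p0))
    return out


def _site_hit_fraction(site_bins: np.ndarray, layout, vbins: set[int]) -> float:
    sites = merge_bins_to_sites(site_bins, layout)
    if not sites:
        return float("nan")
    # a site contains a variant iff any of its bins holds one
    runs = []
    bins_sorted = np.sort(site_bins)
    start = prev = bins_sorted[0]
    for b in bins_sorted[1:]:
        if b == prev + 1:
            prev = b
            continue
        runs.append((start, prev))
        start = prev = b
    runs.append((start, prev))
    hit = sum(1 for s, e in runs if any(b in vbins for b in range(s, e + 1)))
    return hit / len(runs)


def gwas_enrichment(pair: tuple[str, str], class_label: str,
                    matrix: EnrichmentMatrix, loops: LoopSet,
                    variants: pd.DataFrame) -> float:
    """Disease-variant enrichment of a cooperative pair's foreground sites.

    Foreground depends on the cooperation class: 1D-dominant pairs use
    co-bound sites; 3D-dominant pairs use either protein's sites inside
    loops whose two anchors are bound by the two proteins respectively;
    1D-3D pairs use sites in loops where both anchors carry both proteins.
    Background is always the remaining sites of either protein. The ratio
    of the foreground and background percentages of variant-containing
    sites is returned, or NaN when either side is empty or the background
    percentage is zero.
    """
    if class_label not in ("1D-dominant", "3D-dominant", "1D-3D"):
        raise ValueError(f"unknown cooperation class {class_label!r}")
    a, b = pair
    ba = matrix.scores[matrix.dbp_index(a)] > 0
    bb = matrix.scores[matrix.dbp_index(b)] > 0
    col_to_bin = matrix.bin_ids
    retained = {int(v): i for i, v in enumerate(col_to_bin)}
    anchor_cols = [
        ({retained[x] for x in s1 if x in retained},
         {retained[x] for x in s2 if x in retained})
        for s1, s2 in _anchor_bin_sets(loops, matrix.layout)
    ]

    either = ba | bb
    if class_label == "1D-dominant":
        fg_cols = np.flatnonzero(ba & bb)
    else:
        cols_a = set(np.flatnonzero(ba).tolist())
        cols_b = set(np.flatnonzero(bb).tolist())
        fg = set()
        for c1, c2 in anchor_cols:
            if class_label == "3D-dominant":
                cross = ((cols_a & c1) and (cols_b & c2)) or \
                        ((cols_a & c2) and (cols_b & c1))
                if cross:
                    fg |= (cols_a | cols_b) & (c1 | c2)
            else:  # 1D-3D: both anchors carry both proteins
                if (cols_a & c1) and (cols_b & c1) and \
                        (cols_a & c2) and (cols_b & c2):
                    fg |= (cols_a | cols_b) & (c1 | c2)
        fg_cols = np.array(sorted(fg), dtype=np.int64)
    fg_mask = np.zeros(len(either), dtype=bool)
    fg_mask[fg_cols] = True
    bg_cols = np.flatnonzero(either & ~fg_mask)
    if len(fg_cols) == 0 or len(bg_cols) == 0:
        return float("nan")

    vbins = _variant_bins(variants, matrix.layout)
    fg_pct = _site_hit_fraction(col_to_bin[fg_cols], matrix.layout, vbins)
    bg_pct = _site_hit_fraction(col_to_bin[bg_cols], matrix.layout, vbins)
    if not np.isfinite(bg_pct) or bg_pct == 0:
        return float("nan")
    return fg_pct / bg_pct


def compare_categories(ratios_by_class: dict[str, list[float]],
                       ratios_uncooperative: list[float]) -> dict[str, float]:
    """Two-sided Mann-Whitney U p-value per class vs uncooperative pairs.

    Uses the normal approximation with tie correction. All-identical inputs
    give p = 1.
    """
    out = {}
    ref = np.asarray([r for r in ratios_uncooperative if np.isfinite(r)])
    for label, vals in ratios_by_class.items():
        x = np.asarray([v for v in vals if np.isfinite(v)])
        if len(x) < 2 or len(ref) < 2:
            raise ValueError(f"need at least 2 finite ratios per group ({label})")
        if np.all(x == x[0]) and np.all(ref == x[0]):
            out[label] = 1.0
            continue
        res = stats.mannwhitneyu(x, ref, alternative="two-sided",
                                 method="asymptotic")
        out[label] = float(res.pvalue)
    return out
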