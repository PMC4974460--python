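"""Desk-scale synthetic data with planted, known cooperation structure.

The generator emulates the statistical structure the analysis assumes:
each protein binds a sparse set of 1-kb bins with heavy-tailed (gamma)
enrichment over a flat Poisson read background; 1D-cooperative pairs share
linear binding sites with a set co-binding probability; 3D-cooperative
pairs occupy the two opposite 5-kb anchors of dedicated chromatin loops.
Everything is reproducible from a single mandatory seed, and the planted
truth (pairs, modes, per-protein site bins) is returned alongside the data
so every pipeline stage can be checked against it.

What it does not emulate: read mappability structure, fragment-length
effects, copy-number artefacts and the empirical enrichment distribution of
real ChIP-seq; recovery results on fixtures demonstrate correctness of the
inference, not performance on real data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cooperation import LoopSet
from .layout import BinnedTrack, GenomeLayout, ReadSet
from .signal import call_peaks, compute_rpkm, count_reads, local_lambda

__all__ = ["FixtureSpec", "FixtureTruth", "Fixture", "make_fixture",
           "make_ppi_fixture", "make_variant_fixture", "fixture_score_tracks",
           "write_fixture"]

READ_LEN = 50


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic data set.

    Defaults give a 2-chromosome, 2-Mb toy genome (2,000 bins), 20 proteins,
    one planted 1D-only and one planted 3D-only pair with strong effects,
    and 300 loops, so a full pipeline run finishes in seconds.
    """

    chroms: tuple[str, ...] = ("chrS1", "chrS2")
    lengths: tuple[int, ...] = (2_000_000, 2_000_000)
    bin_size: int = 1000
    n_dbps: int = 20
    planted: tuple[tuple[int, int, str], ...] = ((0, 1, "1D"), (2, 3, "3D"))
    co_binding: float = 0.9
    effect_size: float = 8.0
    background_rate: float = 0.03
    base_depth: float = 5.0
    n_loops: int = 300
    loops_per_pair: int = 100
    shared_pool: int = 100
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.co_binding <= 1 or not 0 <= self.background_rate <= 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        for i, j, mode in self.planted:
            if mode not in ("1D", "3D", "both"):
                raise ValueError(f"unknown planted mode {mode!r}")
            if i == j or max(i, j) >= self.n_dbps:
                raise ValueError("planted pair indices out of range")

    def dbp_names(self) -> list[str]:
        return [f"DBP{i:02d}" for i in range(self.n_dbps)]

    def layout(self) -> GenomeLayout:
        return GenomeLayout(self.chroms, self.lengths, self.bin_size)


@dataclass
class FixtureTruth:
    """Planted cooperation and per-protein true binding bins."""

    planted: list[tuple[str, str, str]]
    sites: dict[str, list[int]]
    shared_bins: dict[str, list[int]]
    pair_loops: dict[str, list[int]]

    def planted_pairs(self) -> list[tuple[str, str]]:
        return [(a, b) for a, b, _ in self.planted]


@dataclass
class Fixture:
    spec: FixtureSpec
    layout: GenomeLayout
    reads: dict[str, ReadSet]
    loops: LoopSet
    truth: FixtureTruth
    site_intensity: dict[str, dict[int, float]] = field(repr=False,
                                                        default_factory=dict)


def _make_loops(spec: FixtureSpec, layout: GenomeLayout,
                rng: np.random.Generator) -> LoopSet:
    """Loops with disjoint 5-kb anchors drawn from a per-chromosome grid.

    Anchors never overlap each other, so a binding site sits inside at most
    one anchor and planted 3D signal cannot leak between loops.
    """
    anchor = 5 * spec.bin_size
    slots = []  # (chrom, start) anchor-grid positions
    for ci, c in enumerate(spec.chroms):
        n_slots = spec.lengths[ci] // anchor
        slots.extend((c, k * anchor) for k in range(n_slots))
    if 2 * spec.n_loops > len(slots):
        raise ValueError("genome too small for this many disjoint anchors")
    # intra-chromosomal pairing: shuffle slots per chromosome, pair them up
    c1, s1, c2, s2 = [], [], [], []
    per_chrom = {c: [s for cc, s in slots if cc == c] for c in spec.chroms}
    want = spec.n_loops
    for c in spec.chroms:
        take = min(want - len(s1), len(per_chrom[c]) // 2)
        chosen = rng.choice(per_chrom[c], size=2 * take, replace=False)
        for k in range(take):
            a, b = int(chosen[2 * k]), int(chosen[2 * k + 1])
            if a > b:
                a, b = b, a
            c1.append(c); s1.append(a)
            c2.append(c); s2.append(b)
    if len(s1) < spec.n_loops:
        raise ValueError("could not place all loops with disjoint anchors")
    s1, s2 = np.array(s1), np.array(s2)
    return LoopSet(np.array(c1, dtype=object), s1, s1 + anchor,
                   np.array(c2, dtype=object), s2, s2 + anchor)


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Generate reads, loops and truth for one synthetic study."""
    rng = np.random.default_rng(spec.seed)
    layout = spec.layout()
    n_bins = layout.n_bins
    names = spec.dbp_names()
    loops = _make_loops(spec, layout, rng)

    sites: dict[str, set[int]] = {n: set() for n in names}
    # planted sites carry a site-level intensity shared by the pair:
    # cooperating proteins bind the same locus with proportional strengths
    planted_gamma: dict[str, dict[int, float]] = {n: {} for n in names}
    shared_bins: dict[str, list[int]] = {}
    pair_loops: dict[str, list[int]] = {}

    # independent background sites per protein
    for n in names:
        bg = np.flatnonzero(rng.random(n_bins) < spec.background_rate)
        sites[n].update(bg.tolist())

    # planted 1D co-binding: a shared pool both partners sample densely
    free_loops = list(range(spec.n_loops))
    for i, j, mode in spec.planted:
        a, b = names[i], names[j]
        key = f"{a}-{b}"
        if mode in ("1D", "both"):
            pool = rng.choice(n_bins, size=spec.shared_pool, replace=False)
            hit_a = pool[rng.random(len(pool)) < spec.co_binding]
            hit_b = pool[rng.random(len(pool)) < spec.co_binding]
            pool_gamma = {int(s): rng.gamma(2.0, spec.effect_size / 2.0)
                          for s in pool}
            sites[a].update(hit_a.tolist())
            sites[b].update(hit_b.tolist())
            for n, hits in ((a, hit_a), (b, hit_b)):
                for s in hits:
                    planted_gamma[n][int(s)] = pool_gamma[int(s)] * \
                        rng.lognormal(0.0, 0.25)
            shared_bins[key] = sorted(set(hit_a.tolist()) & set(hit_b.tolist()))
        if mode in ("3D", "both"):
            take = min(spec.loops_per_pair, len(free_loops))
            chosen = [free_loops.pop(int(rng.integers(len(free_loops))))
                      for _ in range(take)]
            used = []
            for li in chosen:
                if rng.random() >= spec.co_binding:
                    continue
                b1 = layout.bins_overlapping(loops.chrom1[li],
                                             int(loops.start1[li]),
                                             int(loops.end1[li]))
                b2 = layout.bins_overlapping(loops.chrom2[li],
                                             int(loops.start2[li]),
                                             int(loops.end2[li]))
                g_loop = rng.gamma(2.0, spec.effect_size / 2.0)
                sa, sb = int(rng.choice(b1)), int(rng.choice(b2))
                sites[a].add(sa)
                sites[b].add(sb)
                planted_gamma[a][sa] = g_loop * rng.lognormal(0.0, 0.25)
                planted_gamma[b][sb] = g_loop * rng.lognormal(0.0, 0.25)
                used.append(li)
            pair_loops[key] = sorted(used)

    # per-bin read intensity: flat base depth, gamma-boosted at sites
    reads: dict[str, ReadSet] = {}
    site_intensity: dict[str, dict[int, float]] = {}
    bin_starts = np.concatenate(
        [np.arange(layout.chrom_n_bins(c)) * spec.bin_size
         for c in spec.chroms])
    bin_chrom = np.concatenate(
        [np.full(layout.chrom_n_bins(c), c, dtype=object)
         for c in spec.chroms])
    for n in names:
        lam = np.full(n_bins, spec.base_depth)
        boosts = {}
        for s in sorted(sites[n]):
            # heavy-tailed enrichment with a floor so every site is callable
            g = planted_gamma[n].get(
                s, rng.gamma(shape=2.0, scale=spec.effect_size / 2.0))
            lam[s] = spec.base_depth * max(g, 3.0)
            boosts[s] = float(lam[s])
        site_intensity[n] = boosts
        counts = rng.poisson(lam)
        total = int(counts.sum())
        bin_of_read = np.repeat(np.arange(n_bins), counts)
        offset = rng.integers(0, spec.bin_size - READ_LEN,
                              size=total)
        starts = bin_starts[bin_of_read] + offset
        reads[n] = ReadSet(chrom=bin_chrom[bin_of_read], start=starts,
                           end=starts + READ_LEN,
                           strand=np.where(rng.random(total) < 0.5, "+", "-"))

    truth = FixtureTruth(
        planted=[(names[i], names[j], mode) for i, j, mode in spec.planted],
        sites={n: sorted(s) for n, s in sites.items()},
        shared_bins=shared_bins,
        pair_loops=pair_loops,
    )
    return Fixture(spec=spec, layout=layout, reads=reads, loops=loops,
                   truth=truth, site_intensity=site_intensity)


def fixture_score_tracks(fixture: Fixture, p_cutoff: float = 0.01
                         ) -> tuple[list[BinnedTrack], list]:
    """Run the signal stage on a fixture: per-DBP enrichment score tracks."""
    tracks, calls = [], []
    for name, rs in fixture.reads.items():
        rpkm = compute_rpkm(rs, fixture.layout)
        lam = local_lambda(rpkm, fixture.layout)
        counts = count_reads(rs, fixture.layout)
        pc = call_peaks(rpkm, counts, lam, total_reads=rs.total,
                        p_cutoff=p_cutoff, name=name)
        calls.append(pc)
        tracks.append(pc.score_track())
    return tracks, calls


def make_ppi_fixture(truth: FixtureTruth, fraction_direct: float,
                     seed: int = 0, n_decoy_proteins: int = 30,
                     n_decoy_edges: int = 60,
                     hub: str | None = None) -> nx.Graph:
    """PPI network containing a set fraction of the planted pairs.

    The remaining graph is random decoy edges among decoy proteins and the
    fixture's proteins. With ``hub`` set, the named protein is connected to
    every planted-pair member, so planted pairs absent as direct edges are
    still reachable through a shared neighbour (indirect).
    """
    if not 0 <= fraction_direct <= 1:
        raise ValueError("fraction_direct must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    g = nx.Graph()
    proteins = sorted(truth.sites) + [f"DECOY{i:02d}"
                                      for i in range(n_decoy_proteins)]
    g.add_nodes_from(p.upper() for p in proteins)
    for a, b in truth.planted_pairs():
        if rng.random() < fraction_direct:
            g.add_edge(a.upper(), b.upper())
    if hub is not None:
        for a, b in truth.planted_pairs():
            g.add_edge(hub.upper(), a.upper())
            g.add_edge(hub.upper(), b.upper())
    arr = np.array(sorted(g.nodes()), dtype=object)
    made = 0
    while made < n_decoy_edges:
        x, y = arr[rng.integers(len(arr), size=2)]
        if x == y or g.has_edge(x, y):
            continue
        planted = {frozenset((a.upper(), b.upper()))
                   for a, b in truth.planted_pairs()}
        if frozenset((x, y)) in planted:
            continue
        g.add_edge(x, y)
        made += 1
    return g


def make_variant_fixture(truth: FixtureTruth, layout: GenomeLayout,
                         enrichment_fold: float = 5.0,
                         background_density: float = 0.05,
                         seed: int = 0) -> pd.DataFrame:
    """Variant positions denser inside planted co-bound sites.

    ``background_density`` is the expected variant count per background bin;
    bins inside planted shared sites get ``enrichment_fold`` times that
    density. Returns a GWAS-like table with 1-based positions.
    """
    if enrichment_fold < 1:
        raise ValueError("enrichment_fold must be >= 1")
    rng = np.random.default_rng(seed)
    lam = np.full(layout.n_bins, background_density)
    target = sorted({b for bins in truth.shared_bins.values() for b in bins})
    lam[target] = background_density * enrichment_fold
    counts = rng.poisson(lam)
    rows = []
    for b in np.flatnonzero(counts):
        chrom, start, end = layout.bin_interval(int(b))
        for _ in range(counts[b]):
            rows.append((chrom, int(rng.integers(start, end)) + 1))
    return pd.DataFrame(rows, columns=["chrom", "pos"])


def write_fixture(fixture: Fixture, outdir: str,
                  ppi: nx.Graph | None = None,
                  variants: pd.DataFrame | None = None) -> None:
    """Write a fixture in the dialects the pipeline reads.

    Emits per-DBP BED read files, a BEDPE loop list, a chrom.sizes file,
    a truth JSON and optionally a BioGRID-like PPI TSV and a GWAS-like
    variant TSV.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, rs in fixture.reads.items():
        strands = rs.strand if rs.strand is not None else ["."] * len(rs)
        with open(out / f"{name}.bed", "w") as fh:
            for c, s, e, st in zip(rs.chrom, rs.start, rs.end, strands):
                fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")
    fixture.loops.to_frame().to_csv(out / "loops.bedpe", sep="\t",
                                    index=False, header=False)
    with open(out / "chrom.sizes", "w") as fh:
        for c, l in zip(fixture.spec.chroms, fixture.spec.lengths):
            fh.write(f"{c}\t{l}\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(asdict(fixture.truth), fh, indent=1)
    if ppi is not None:
        pd.DataFrame(sorted(tuple(sorted(e)) for e in ppi.edges()),
                     columns=["Official Symbol Interactor A",
                              "Official Symbol Interactor B"]
                     ).to_csv(out / "ppi.tsv", sep="\t", index=False)
    if variants is not None:
        variants.rename(columns={"chrom": "CHR_ID", "pos": "CHR_POS"}
                        ).to_csv(out / "gwas.tsv", sep="\t", index=False)
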