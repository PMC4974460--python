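# dbpnet

Networks of cooperating DNA-binding proteins (DBPs) from ChIP-seq signal and
Hi-C chromatin loops.

Transcription factors, architectural proteins and histone marks rarely act
alone: they co-occupy nearby loci on the linear genome (**1D cooperation**)
and they meet across the two anchors of chromatin loops that bring distal
loci into spatial contact (**3D cooperation**). `dbpnet` integrates per-DBP
aligned-read tracks with loop calls to quantify both kinds of cooperation
for every protein pair, infers a sparse network of direct associations with
a Gaussian graphical model, and analyses that network's hubs, communities
and cliques — candidate protein complexes, including those that may mediate
loop formation. It is aimed at regulatory-genomics analysts with ChIP-seq
compendia (e.g. ENCODE-style panels) and 5-kb-resolution Hi-C loop lists
for the same cell type.

## The model

1. **Signal.** Each chromosome is tiled into 1-kb bins; per-DBP read counts
   are depth-normalised to RPKM. A bin is a peak when its raw count is
   improbable (Poisson upper tail, P ≤ 0.01) under a MACS-style local
   background λ_local = max{λ_BG, λ_14k, λ_24k}. Peak bins score their fold
   enrichment RPKM/λ_local; all other bins score 0. Bins whose score s.d.
   across DBPs is < 1 are dropped.
2. **Pair scores.** The 1D score of a pair is the Spearman correlation of
   their enrichment scores over retained bins. For the 3D score, each loop
   anchor is scored as the max enrichment over its 1-kb bins; per loop, the
   anchor where protein A is stronger is A's *primary binding locus* and B
   is read on the opposite anchor; the Spearman correlation of these
   primary-locus scores across loops is the 3D score. The two matrices are
   merged entrywise by keeping the larger score.
3. **Network.** The graphical lasso (penalty ρ = 0.3) estimates a sparse
   precision matrix Σ⁻¹ from the merged correlation matrix; a nonzero
   entry means conditional dependence, i.e. an edge. Edges with
   non-positive merged correlation are removed, and each edge is classified
   **1D-dominant**, **3D-dominant** or **1D–3D** by comparing its two
   scores with a 0.3 cutoff. A shuffled-track null run at the same penalty
   should (and does) return zero edges.
4. **Analysis & statistics.** Hubs by averaged degree/eigenvector ranks;
   communities by greedy modularity maximisation; maximal cliques ranked by
   mean pairwise correlation; cross-cell-type edge/clique comparison; PPI
   overlap with randomisation p-values; clique co-binding against random
   DBP sets; GWAS-variant enrichment of cooperative binding sites.

A self-contained simulation benchmark validates the inference core:
Erdős–Rényi truth graphs G(n, p = 0.2), covariances with nonzero entries
exactly on edges, multivariate-Gaussian samples, partial-correlation edge
ranking, ROC/AUC scoring (with an optional nonparanormal/copula transform
for non-Gaussian data, and a reader for GeneNetWeaver-style expression
benchmarks).

## Worked example

No external data is needed — the fixture generator emits a toy study with a
planted 1D-cooperating pair (DBP00–DBP01) and a planted 3D pair
(DBP02–DBP03) over a 2×2-Mb genome with 300 loops:

```sh
dbpnet fixtures --seed 11 --out fx
# config.yaml: reads, chrom_sizes, loops, ppi paths + out_dir/seed
dbpnet run --config config.yaml
head -3 run/edges.tsv
```

```
dbpA    dbpB    corr1d    corr3d    merged    partial_corr    class
DBP00   DBP01   0.384174  0.004373  0.384174  0.082142        1D-dominant
DBP02   DBP03   -0.047853 0.456795  0.456795  0.156795        3D-dominant
```

Exactly the two planted pairs are recovered: the shared-site pair has a 1D
score of 0.38 against a near-zero 3D score (1D-dominant), the
opposite-anchor pair the reverse (3D-dominant), and no decoy pair enters
the network. The run directory also holds `pair_scores.tsv` (all pairs with
z-scores), `centrality.tsv`, `communities.tsv`, `cliques.json`,
`top_loci.bed`, per-DBP `.narrowPeak` files and a `manifest.json` with
parameters, seed and input checksums. With the fixture's PPI table, the
planted edges are recovered as direct interactions far above the
node-relabelling null (`ppi_enrichment.json`: fold 16.7, empirical
P ≈ 0.005 at 2,000 replicates).

The simulation benchmark:

```sh
dbpnet benchmark --sizes 50:500,100:1000 --reps 10 --seed 7 --out auc.tsv
# mean AUC 0.961 over 20 replicates -> auc.tsv
```

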