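# Methods

This note documents the models and procedures implemented in `dbpnet`, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic fixtures do and do not demonstrate.

## Signal model

Reads are assigned to 1-kb bins by their midpoint (a `5prime` mode is
available; no fragment extension or shifting is performed). Coverage is
normalised to RPKM: count / (bin-length-kb × total-reads/10⁶), so the last,
possibly short, bin of each chromosome is handled by its true length.

The local background follows the MACS scheme without an input control: all
λ components come from the ChIP sample itself. λ_BG is the genome-wide mean
RPKM; λ_14k and λ_24k are sliding-window means centred on each bin. Windows
are converted to an odd bin count via half-width = round(window / bin_size
/ 2) (15 and 25 bins at the defaults), and are truncated at chromosome
boundaries rather than padded — edge bins average over fewer neighbours.
λ_local is the per-bin maximum of the three components, which makes it a
conservative background wherever signal is locally elevated.

The Poisson peak test runs in count units: the RPKM-scale λ_local is
converted to an expected count per bin (λ × total/10⁶ × bin-kb) and the
p-value is the upper tail P(X ≥ count). The cutoff (default 0.01) is
deliberately loose to keep broad, moderate enrichments; no multiple-testing
correction is applied, because the p-values feed a correlation analysis
rather than a peak catalogue. Enrichment scores are fold enrichment
(RPKM/λ_local) on peak bins and exactly zero elsewhere; a bin with
λ_local = 0 and no reads scores 0.

The variance filter drops bins whose score s.d. across proteins (sample
s.d., n−1 denominator) is below 1.0. This removes both uninformative
all-zero bins and artefact regions where every track is uniformly high
(low-mappability pile-ups behave this way). The retained-bin set is by
construction independent of protein ordering.

## Pair scores

1D: Spearman correlation (average ranks on ties) of the two proteins'
scores over retained bins. A constant vector yields a correlation of 0 with
a warning rather than NaN, so downstream matrices stay numeric.

3D: anchors are scored with *pre-filter* score tracks (the s.d. filter is
defined on the genome-wide bin set used for 1D; anchor maxima are a
different population and filtering them would silently zero loops). The
primary-binding-locus rule is asymmetric in who selects the anchor, so both
orderings are computed and combined — by maximum by default (`selector`
also offers `mean` and `first`), treating cooperation as
orientation-agnostic. Argmax ties (typically 0 vs 0) break to anchor1 for
determinism; this is the one place the rule is not invariant to a global
anchor-label swap, which otherwise holds exactly. Loops where both proteins
score zero on both anchors are retained: zeros carry rank information and
dropping them would inflate correlations among sparsely bound proteins.

Merging keeps the larger of the 1D and 3D scores per entry. z-scores
standardise each score over all off-diagonal pair entries of its matrix.

## Network inference

The graphical lasso (penalty 0.3, tolerance 10⁻⁴, up to 200 iterations) is
fitted directly on the merged Spearman-based correlation matrix, following
the stated pipeline order; the 2·sin(π·ρ/6) rank-to-linear correction is
available behind `rank_correction=True` for the statistically cleaner
variant. Entrywise maxima of two correlation matrices need not be positive
semi-definite, so the input first passes an eigenvalue-clipping projection
(floor 10⁻⁶, rescaled to unit diagonal); already-PD matrices pass through
untouched. The penalty of 0.3 mirrors the coverage argument for real DBP
panels (few pairs exceed 0.3); no cross-validated penalty selection is
offered.

Edges require |precision| > 10⁻⁸ (absorbing solver noise) and a positive
merged correlation — negative conditional associations are not interpreted
as cooperation. Classification: 1D-dominant / 3D-dominant / 1D–3D by which
scores exceed the 0.3 cutoff; edges with neither score above it remain
`unclassified`. Two counting identities follow and are enforced by test:
labels partition the edge set, and |1D-dominant| + |1D–3D| equals the
number of edges with a 1D score above the cutoff (symmetrically for 3D).

The false-discovery control permutes each protein's bin scores
independently (seeded), destroying co-binding while preserving marginals,
and reruns the full path at production settings; the expected and observed
outcome on fixtures is an empty network.

The nonparanormal (copula) transform maps each sample column through its
Winsorised empirical CDF to standard-normal quantiles, with truncation
δ_n = 1/(4 n^{1/4} √(π log n)). It operates on sample-level data (the
benchmark path and raw-score analyses); it is not applied to the merged
correlation matrix, which is already rank-based.

## Network analysis

Eigenvector centrality is the principal eigenvector of the adjacency of the
largest connected component, computed densely (panels are ≤ a few hundred
nodes); nodes outside the component score 0 and rank last. Ranks are
descending with ties averaged; the hub score is the mean of the degree and
eigenvector ranks. Communities use greedy modularity maximisation
(Clauset–Newman–Moore) on the unweighted graph (a weighted variant is a
flag); maximal cliques use Bron–Kerbosch with pivoting — exact enumeration,
verified against exhaustive subset search up to 12 nodes. Cliques need ≥ 3
members (2-cliques are just edges) and rank by mean pairwise merged
correlation, ties by size then lexicographic members. Cross-cell
comparisons restrict both networks to shared nodes first; cell-type-specific
cliques are maximal cliques of the subgraph of edges present in exactly one
network. "Sites" are maximal runs of adjacent qualifying 1-kb bins, never
crossing chromosome boundaries.

## Enrichment statistics

All randomisation tests use the add-one empirical p-value
(1 + #{null ≥ obs})/(reps + 1), floored at 1/(reps+1). PPI overlap labels
each edge direct (the pair is a PPI edge), indirect (a shared PPI
neighbour exists) or neither; the null relabels network nodes with
uniformly drawn PPI proteins without replacement, preserving topology.
The default of 10⁵ replicates is a desk-scale stand-in for the 10⁹-scale
runs feasible on a cluster; the flag raises it. Clique co-binding compares
the clique's shared-peak fraction and loop overlap against random same-size
protein sets (default 50,000 samples). GWAS enrichment builds
class-specific foregrounds (1D: co-bound sites; 3D: either protein's sites
inside loops whose two anchors are bound by the two proteins respectively;
1D–3D: sites in loops where both anchors carry both proteins), with the
background always the remaining sites of either protein — disjoint from the
foreground by construction. A variant is contained in a site when its
1-based position falls in the site's half-open interval; loop overlap
requires one anchor by default. Ratios with an empty side or a zero
background percentage are flagged NaN rather than guessed. Class-versus-
uncooperative comparisons use the two-sided Mann–Whitney U test (normal
approximation with tie correction); degenerate all-identical inputs return
p = 1. Genome builds are assumed consistent across inputs; no liftover.

## Simulation benchmark

Truth graphs are G(n, p = 0.2). The covariance has entries of 0.25 exactly
on edges and unit diagonal; if its smallest eigenvalue falls below 0.1 the
matrix is inflated by (0.1 − λ_min)·I and rescaled, preserving the zero
pattern. The strength 0.25 is a package choice (exposed in the API): the
repair shrinks the effective off-diagonal as density grows, which keeps the
recovery problem non-trivial at both benchmark sizes. Samples are zero-mean
Gaussian via Cholesky with a seeded generator (bit-reproducible). Edges are
ranked by |partial correlation| from a nearly unpenalised graphical-lasso
fit (penalty 0.01; pseudo-inverse fallback on solver failure). ROC counts
follow the predicted-versus-true edge definitions (TP: predicted and true;
FP: predicted only; FN: true only; TN: neither), with tied scores grouped
at one threshold; the trapezoidal AUC equals the normalised Mann–Whitney
statistic, which the tests assert exactly. The standard configuration is
10 replicates at n = 50/m = 500 and 10 at n = 100/m = 1,000; it completes
in seconds and yields a mean AUC ≈ 0.96 at these defaults. GeneNetWeaver-
style network/expression file pairs can be scored through the same path
with the copula transform enabled.

## Synthetic fixtures

The generator emulates the statistical structure the analysis assumes, at
desk scale (2 chromosomes × 2 Mb, 1-kb bins, 20 proteins, 300 loops,
seconds per run). Background binding sites are uniform (rate 0.03/bin) with
gamma-distributed enrichment (shape 2, mean = effect size 8, floored so
every site is callable) over a flat Poisson read background (5 reads/bin).
Planted 1D pairs sample a 100-bin shared pool with co-binding probability
0.9; planted 3D pairs occupy the two opposite anchors of up to 100 dedicated
loops. Co-bound sites share a per-site intensity with lognormal
protein-specific noise (σ = 0.25): cooperating proteins bind the same locus
with proportional, not independent, strengths. Loop anchors sit on a
disjoint 5-kb grid, so 3D signal cannot leak between loops. Companion
generators emit a BioGRID-like PPI with a configurable fraction of planted
pairs as direct edges, and a GWAS-like variant table with fold-elevated
density inside planted co-bound sites.

Not emulated: mappability structure, fragment-length effects, copy-number
artefacts, inter-loop correlation, or the empirical enrichment distribution
of real ChIP-seq. Passing recovery tests therefore demonstrates correctness
of the inference chain under its own assumptions, not expected performance
on real data.

## Reproducibility

Every stochastic component takes an explicit seed; the pipeline derives
per-stage seeds from one global seed by hashing the stage name, so stages
are independently reproducible. Each run writes a manifest with parameter
values, the seed, per-stage status and input checksums. Identical config
and seed give bit-identical outputs.

## Known limitations

- Loops are consumed, not called; only intra-panel cooperation is visible.
- The glasso penalty and classification cutoff are fixed constants;
  sensible for ~100-protein panels but not validated for very small ones.
- The 3D statistic treats loops as exchangeable observations; shared
  anchors between real loops mildly violate independence.
- Degraded 1D-only mode (no loop file) leaves 3D scores absent and can
  only label edges 1D-dominant or unclassified.
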