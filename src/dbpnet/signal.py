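"""ChIP-seq signal processing: binned coverage, local Poisson background,
peak calling and the variance-filtered enrichment matrix.

The model follows the MACS peak-calling scheme without an input control:
reads are counted into 1-kb bins and depth-normalised to RPKM; the local
background rate at each bin is the maximum of the genome-wide mean RPKM and
sliding-window means over ~14-kb and ~24-kb windows centred on the bin;
a bin is a peak when its raw read count is improbably high under a Poisson
null with that local rate. Enrichment scores are fold enrichment
(RPKM / lambda_local) on peak bins and exactly zero elsewhere. Bins whose
score standard deviation across proteins is small carry no co-binding
information (or reflect artefacts) and are removed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .layout import BinnedTrack, GenomeLayout, ReadSet, UnknownChromosomeError

__all__ = [
    "compute_rpkm",
    "count_reads",
    "local_lambda",
    "call_peaks",
    "build_enrichment_matrix",
    "LocalLambda",
    "PeakCall",
    "EnrichmentMatrix",
]


def count_reads(reads: ReadSet, layout: GenomeLayout,
                assign: str = "midpoint") -> np.ndarray:
    """Raw per-bin read counts; each read is assigned to a single bin.

    ``assign`` chooses the representative coordinate: the read midpoint
    (default) or its 5' end (start for +, end-1 for -).
    """
    if assign not in ("midpoint", "5prime"):
        raise ValueError(f"unknown read assignment {assign!r}")
    counts = np.zeros(layout.n_bins, dtype=np.int64)
    chrom_idx = {c: i for i, c in enumerate(layout.chroms)}
    unknown = set(np.unique(reads.chrom)) - set(layout.chroms)
    if unknown:
        raise UnknownChromosomeError(
            f"reads on chromosomes absent from layout: {sorted(unknown)}")
    if assign == "midpoint":
        pos = (reads.start + reads.end) // 2
    else:
        pos = reads.start.copy()
        if reads.strand is not None:
            minus = reads.strand == "-"
            pos[minus] = reads.end[minus] - 1
    ci = np.fromiter((chrom_idx[c] for c in reads.chrom), dtype=np.int64,
                     count=len(reads))
    lengths = np.asarray(layout.lengths)[ci]
    pos = np.minimum(pos, lengths - 1)
    global_bin = layout._offsets[ci] + pos // layout.bin_size
    np.add.at(counts, global_bin, 1)
    return counts


def compute_rpkm(reads: ReadSet, layout: GenomeLayout,
                 assign: str = "midpoint") -> BinnedTrack:
    """Reads Per Kilobase per Million mapped reads, per bin.

    RPKM(bin) = count(bin) / (bin_length_kb * total_reads / 1e6).
    """
    if reads.total == 0 or len(reads) == 0:
        raise ValueError("read set has zero mapped reads")
    counts = count_reads(reads, layout, assign=assign)
    rpkm = counts / (layout.bin_lengths_kb() * reads.total / 1e6)
    return BinnedTrack(name="rpkm", values=rpkm, layout=layout)


@dataclass
class LocalLambda:
    """Per-bin local background rate and its three components (RPKM units)."""

    lam_bg: float
    lam_w1: np.ndarray
    lam_w2: np.ndarray
    lam_local: np.ndarray
    windows: tuple[int, int]


def _sliding_mean(values: np.ndarray, half: int) -> np.ndarray:
    # centred moving average, truncated at array edges
    n = len(values)
    c = np.concatenate([[0.0], np.cumsum(values)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (c[hi] - c[lo]) / (hi - lo)


def local_lambda(track: BinnedTrack, layout: GenomeLayout,
                 windows: tuple[int, int] = (14000, 24000)) -> LocalLambda:
    """MACS-style local background: max of genome-wide and windowed means.

    Windows are converted to an odd bin count centred on the target bin
    (half-width = round(window / bin_size / 2)); sliding means are truncated
    at chromosome boundaries rather than padded.
    """
    for w in windows:
        if w < layout.bin_size:
            raise ValueError(f"window {w} smaller than bin size {layout.bin_size}")
    lam_bg = float(track.values.mean())
    comps = []
    for w in windows:
        half = int(round(w / layout.bin_size / 2))
        out = np.empty_like(track.values)
        for _, sl in layout.chrom_slices():
            out[sl] = _sliding_mean(track.values[sl], half)
        comps.append(out)
    lam_local = np.maximum(lam_bg, np.maximum(comps[0], comps[1]))
    return LocalLambda(lam_bg=lam_bg, lam_w1=comps[0], lam_w2=comps[1],
                       lam_local=lam_local, windows=tuple(windows))


@dataclass
class PeakCall:
    """Per-bin peak flags, fold enrichments and Poisson p-values.

    ``scores`` holds the ChIP-seq enrichment score: fold enrichment on peak
    bins, zero elsewhere.
    """

    name: str
    layout: GenomeLayout
    is_peak: np.ndarray
    fold_enrichment: np.ndarray
    pvalue: np.ndarray

    @property
    def scores(self) -> np.ndarray:
        return np.where(self.is_peak, self.fold_enrichment, 0.0)

    def score_track(self) -> BinnedTrack:
        return BinnedTrack(name=self.name, values=self.scores, layout=self.layout)


def call_peaks(track: BinnedTrack, counts: np.ndarray, lam: LocalLambda,
               total_reads: int, p_cutoff: float = 0.01,
               name: str = "dbp") -> PeakCall:
    """Poisson peak test per bin with fold enrichment over lambda_local.

    The RPKM-scale background rate is converted to an expected raw count
    (lambda_RPKM * total_reads/1e6 * bin_kb) so the Poisson test runs in
    count units. The p-value is the upper tail P(X >= count); a bin is a
    peak when p <= p_cutoff.
    """
    counts = np.asarray(counts)
    if counts.shape != track.values.shape or lam.lam_local.shape != counts.shape:
        raise ValueError("track, counts and lambda must share one bin grid")
    mu = lam.lam_local * (total_reads / 1e6) * track.layout.bin_lengths_kb()
    # P(X >= k | mu) = sf(k-1); k=0 gives p=1
    pval = stats.poisson.sf(counts - 1, mu)
    pval = np.where(counts == 0, 1.0, pval)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(lam.lam_local > 0, track.values / lam.lam_local, 0.0)
    fold = np.where((lam.lam_local == 0) & (counts > 0), np.inf, fold)
    is_peak = pval <= p_cutoff
    return PeakCall(name=name, layout=track.layout, is_peak=is_peak,
                    fold_enrichment=fold, pvalue=pval)


@dataclass
class EnrichmentMatrix:
    """DBP x retained-bin matrix of enrichment scores after variance filtering."""

    dbps: list[str]
    bin_ids: np.ndarray
    scores: np.ndarray  # shape (n_dbps, n_retained_bins)
    layout: GenomeLayout

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.scores.T, index=self.bin_ids, columns=self.dbps)

    def dbp_index(self, name: str) -> int:
        return self.dbps.index(name)

    def bound_bins(self, name: str) -> np.ndarray:
        """Global ids of retained bins with a nonzero score for ``name``."""
        return self.bin_ids[self.scores[self.dbp_index(name)] > 0]


def build_enrichment_matrix(peakcalls: list[PeakCall],
                            min_sd: float = 1.0) -> EnrichmentMatrix:
    """Stack per-DBP score tracks and drop low-variance bins.

    A bin is retained when the sample (n-1) standard deviation of its scores
    across DBPs is at least ``min_sd``; this removes uninformative bins and
    artefact regions where all proteins score alike.
    """
    if len(peakcalls) < 2:
        raise ValueError("need at least 2 DBPs for the variance filter")
    layout = peakcalls[0].layout
    for pc in peakcalls:
        if pc.layout is not layout and pc.layout != layout:
            raise ValueError("all peak calls must share one genome layout")
    scores = np.vstack([pc.scores for pc in peakcalls])
    finite = np.isfinite(scores)
    if not finite.all():
        warnings.warn("infinite fold enrichments clipped to per-DBP max finite value")
        for row in scores:
            bad = ~np.isfinite(row)
            if bad.any():
                row[bad] = row[np.isfinite(row)].max(initial=0.0)
    sd = scores.std(axis=0, ddof=1)
    keep = sd >= min_sd
    return EnrichmentMatrix(
        dbps=[pc.name for pc in peakcalls],
        bin_ids=np.flatnonzero(keep).astype(np.int64),
        scores=scores[:, keep],
        layout=layout,
    )
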