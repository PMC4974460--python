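"""Genome coordinate bookkeeping: fixed-width bins over named chromosomes.

All coordinates are 0-based half-open. Chromosomes are tiled left to right
with ``bin_size``-bp bins; the last bin of a chromosome may be shorter.
Bins carry a single global integer index across the genome, in chromosome
order, which the rest of the package uses as the bin identifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GenomeLayout", "ReadSet", "BinnedTrack"]


@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names, lengths and the bin grid laid over them."""

    chroms: tuple[str, ...]
    lengths: tuple[int, ...]
    bin_size: int = 1000
    _offsets: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.chroms) != len(self.lengths):
            raise ValueError("chroms and lengths differ in length")
        if len(self.chroms) != len(set(self.chroms)):
            raise ValueError("duplicate chromosome names")
        if any(l <= 0 for l in self.lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.bin_size <= 0:
            raise ValueError("bin_size must be positive")
        nbins = [-(-l // self.bin_size) for l in self.lengths]
        offsets = np.concatenate([[0], np.cumsum(nbins)])
        object.__setattr__(self, "_offsets", offsets)

    @classmethod
    def from_chrom_sizes(cls, path: str, bin_size: int = 1000) -> "GenomeLayout":
        """Read a UCSC-style two-column chrom.sizes file."""
        chroms, lengths = [], []
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith("#"):
                    continue
                name, size = line.split()[:2]
                chroms.append(name)
                lengths.append(int(size))
        return cls(tuple(chroms), tuple(lengths), bin_size)

    @property
    def n_bins(self) -> int:
        return int(self._offsets[-1])

    def chrom_n_bins(self, chrom: str) -> int:
        i = self.chroms.index(chrom)
        return int(self._offsets[i + 1] - self._offsets[i])

    def chrom_offset(self, chrom: str) -> int:
        return int(self._offsets[self.chroms.index(chrom)])

    def chrom_slices(self) -> list[tuple[str, slice]]:
        """Per-chromosome slices into any genome-wide bin vector."""
        return [
            (c, slice(int(self._offsets[i]), int(self._offsets[i + 1])))
            for i, c in enumerate(self.chroms)
        ]

    def bin_index(self, chrom: str, pos: int) -> int:
        """Global index of the bin containing 0-based position ``pos``."""
        i = self.chroms.index(chrom)
        if not 0 <= pos < self.lengths[i]:
            raise ValueError(f"position {pos} outside {chrom}")
        return int(self._offsets[i] + pos // self.bin_size)

    def bins_overlapping(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Global indices of bins overlapping [start, end) on ``chrom``."""
        i = self.chroms.index(chrom)
        if start < 0 or end <= start:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        lo = start // self.bin_size
        hi = -(-end // self.bin_size)
        hi = min(hi, int(self._offsets[i + 1] - self._offsets[i]))
        lo = min(lo, hi)
        return np.arange(self._offsets[i] + lo, self._offsets[i] + hi, dtype=np.int64)

    def bin_interval(self, index: int) -> tuple[str, int, int]:
        """(chrom, start, end) of the bin with global index ``index``."""
        if not 0 <= index < self.n_bins:
            raise IndexError(index)
        i = int(np.searchsorted(self._offsets, index, side="right") - 1)
        local = index - int(self._offsets[i])
        start = local * self.bin_size
        end = min(start + self.bin_size, self.lengths[i])
        return self.chroms[i], start, end

    def bin_lengths_kb(self) -> np.ndarray:
        """Per-bin lengths in kilobases (last bin of a chromosome may be short)."""
        out = np.full(self.n_bins, self.bin_size / 1000.0)
        for i, (c, sl) in enumerate(self.chrom_slices()):
            last = self.lengths[i] - (self.chrom_n_bins(c) - 1) * self.bin_size
            out[sl.stop - 1] = last / 1000.0
        return out


class UnknownChromosomeError(ValueError):
    """A read maps to a chromosome absent from the genome layout."""


@dataclass
class ReadSet:
    """Aligned read intervals for one ChIP-seq experiment.

    ``total`` is the total mapped read count used for depth normalisation;
    it defaults to the number of stored reads but may be larger when reads
    were pre-filtered.
    """

    chrom: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray | None = None
    total: int | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if np.any(self.start >= self.end):
            raise ValueError("reads must satisfy start < end")
        if self.total is None:
            self.total = len(self.start)
        elif self.total < len(self.start):
            raise ValueError("total mapped reads below stored read count")

    def __len__(self) -> int:
        return len(self.start)


@dataclass
class BinnedTrack:
    """A genome-wide per-bin value vector (RPKM or enrichment) for one DBP."""

    name: str
    values: np.ndarray
    layout: GenomeLayout

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.layout.n_bins,):
            raise ValueError(
                f"track length {self.values.shape} != bin count {self.layout.n_bins}"
            )
        if np.any(self.values < 0):
            raise ValueError("track values must be non-negative")
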