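"""Pairwise 1D and 3D cooperation scores for DNA-binding proteins.

The 1D score of a DBP pair is the Spearman correlation of their enrichment
scores over the variance-filtered genomic bins: proteins that co-occur at
nearby loci on the linear genome correlate strongly. The 3D score captures
co-occurrence at the two *anchors* of chromatin loops: for each loop the
anchor where protein A is more enriched is taken as A's primary binding
locus, protein B is scored on the opposite anchor, and the Spearman
correlation of these primary-locus scores across loops measures 3D
cooperation. The two matrices are merged entrywise by keeping the larger
score, which is the input to the graphical model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .layout import BinnedTrack, GenomeLayout
from .signal import EnrichmentMatrix

__all__ = [
    "LoopSet",
    "AnchorScoreTable",
    "PairScoreTable",
    "corr_1d",
    "anchor_scores",
    "corr_3d",
    "corr_3d_matrix",
    "merge_scores",
]


@dataclass
class LoopSet:
    """Chromatin loops: paired anchor intervals (nominally 5 kb wide)."""

    chrom1: np.ndarray
    start1: np.ndarray
    end1: np.ndarray
    chrom2: np.ndarray
    start2: np.ndarray
    end2: np.ndarray

    def __post_init__(self) -> None:
        for a in ("start1", "end1", "start2", "end2"):
            setattr(self, a, np.asarray(getattr(self, a), dtype=np.int64))
        self.chrom1 = np.asarray(self.chrom1, dtype=object)
        self.chrom2 = np.asarray(self.chrom2, dtype=object)
        if np.any(self.start1 >= self.end1) or np.any(self.start2 >= self.end2):
            raise ValueError("loop anchors must satisfy start < end")
        same = (self.chrom1 == self.chrom2) & (self.start1 == self.start2) \
            & (self.end1 == self.end2)
        if np.any(same):
            raise ValueError("the two anchors of a loop must be distinct")

    def __len__(self) -> int:
        return len(self.start1)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LoopSet":
        return cls(df["chrom1"].to_numpy(), df["start1"].to_numpy(),
                   df["end1"].to_numpy(), df["chrom2"].to_numpy(),
                   df["start2"].to_numpy(), df["end2"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "chrom1": self.chrom1, "start1": self.start1, "end1": self.end1,
            "chrom2": self.chrom2, "start2": self.start2, "end2": self.end2,
        })

    def swapped(self) -> "LoopSet":
        """Loop set with anchor1/anchor2 labels exchanged on every loop."""
        return LoopSet(self.chrom2, self.start2, self.end2,
                       self.chrom1, self.start1, self.end1)


@dataclass
class AnchorScoreTable:
    """Enrichment score of every DBP on both anchors of every loop.

    ``scores`` has shape (n_dbps, n_loops, 2); the score of an anchor is the
    maximum enrichment score over the 1-kb bins it overlaps.
    """

    dbps: list[str]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if self.scores.ndim != 3 or self.scores.shape[2] != 2:
            raise ValueError("anchor scores must have shape (dbps, loops, 2)")
        if np.any(self.scores < 0):
            raise ValueError("anchor scores must be non-negative")

    def for_dbp(self, name: str) -> np.ndarray:
        return self.scores[self.dbps.index(name)]


def anchor_scores(tracks: list[BinnedTrack], loops: LoopSet) -> AnchorScoreTable:
    """Score every loop anchor as the max enrichment over its 1-kb bins.

    Uses the pre-variance-filter score tracks; an anchor overlapping no bin
    with signal scores 0.
    """
    layout = tracks[0].layout
    n = len(loops)
    bins1 = [layout.bins_overlapping(loops.chrom1[i], int(loops.start1[i]),
                                     int(loops.end1[i])) for i in range(n)]
    bins2 = [layout.bins_overlapping(loops.chrom2[i], int(loops.start2[i]),
                                     int(loops.end2[i])) for i in range(n)]
    out = np.zeros((len(tracks), n, 2))
    for d, tr in enumerate(tracks):
        v = tr.values
        out[d, :, 0] = [v[b].max() if len(b) else 0.0 for b in bins1]
        out[d, :, 1] = [v[b].max() if len(b) else 0.0 for b in bins2]
    return AnchorScoreTable(dbps=[t.name for t in tracks], scores=out)


def _spearman(x: np.ndarray, y: np.ndarray, context: str) -> float:
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn(f"constant vector in {context}; correlation set to 0")
        return 0.0
    r = stats.spearmanr(x, y).statistic
    return float(r) if np.isfinite(r) else 0.0


def corr_1d(matrix: EnrichmentMatrix) -> pd.DataFrame:
    """Spearman correlation of enrichment scores over retained bins, all pairs."""
    if matrix.scores.shape[1] < 2:
        raise ValueError("need at least 2 retained bins for 1D correlation")
    df = matrix.to_frame()
    constant = df.nunique() == 1
    if constant.any():
        warnings.warn(
            f"constant score vectors for {list(df.columns[constant])}; "
            "their correlations set to 0")
    corr = df.corr(method="spearman")
    corr[constant] = 0.0
    corr.loc[constant] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    return corr


def corr_3d(pair: tuple[str, str], table: AnchorScoreTable,
            selector: str = "max") -> float:
    """3D correlation of one DBP pair via the primary-binding-locus rule.

    For each loop, the selecting protein's primary anchor is the one where
    its own score is larger (ties break to anchor1); the partner is scored
    on the opposite anchor. The rule is asymmetric in who selects, so it is
    evaluated for both orderings and combined per ``selector``:
    'max' (default), 'mean', or 'first' (A selects).
    """
    a_name, b_name = pair
    a = table.for_dbp(a_name)
    b = table.for_dbp(b_name)
    if a.shape[0] < 2:
        raise ValueError("need at least 2 loops for 3D correlation")

    def one_way(sel: np.ndarray, oth: np.ndarray) -> float:
        prim = np.argmax(sel, axis=1)  # ties -> anchor1 (argmax first max)
        rows = np.arange(len(prim))
        return _spearman(sel[rows, prim], oth[rows, 1 - prim], "corr_3d")

    r_ab = one_way(a, b)
    if selector == "first":
        return r_ab
    r_ba = one_way(b, a)
    if selector == "max":
        return max(r_ab, r_ba)
    if selector == "mean":
        return (r_ab + r_ba) / 2.0
    raise ValueError(f"unknown selector {selector!r}")


def corr_3d_matrix(table: AnchorScoreTable, selector: str = "max") -> pd.DataFrame:
    """3D correlation for every unordered DBP pair."""
    names = table.dbps
    n = len(names)
    out = np.eye(n)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i in range(n):
            for j in range(i + 1, n):
                r = corr_3d((names[i], names[j]), table, selector=selector)
                out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=names, columns=names)


@dataclass
class PairScoreTable:
    """Per-pair 1D, 3D and merged correlation scores with z-scores.

    Square symmetric frames indexed by DBP name. z-scores standardise each
    score over the population of all off-diagonal pair entries.
    """

    dbps: list[str]
    corr1d: pd.DataFrame
    corr3d: pd.DataFrame
    merged: pd.DataFrame
    z1d: pd.DataFrame
    z3d: pd.DataFrame

    def pair(self, a: str, b: str) -> dict[str, float]:
        return {
            "corr_1d": float(self.corr1d.loc[a, b]),
            "corr_3d": float(self.corr3d.loc[a, b]),
            "merged": float(self.merged.loc[a, b]),
            "z_1d": float(self.z1d.loc[a, b]),
            "z_3d": float(self.z3d.loc[a, b]),
        }

    def to_long(self) -> pd.DataFrame:
        rows = []
        for i, a in enumerate(self.dbps):
            for b in self.dbps[i + 1:]:
                rows.append({"dbpA": a, "dbpB": b, **self.pair(a, b)})
        return pd.DataFrame(rows)

    def write(self, path: str) -> None:
        self.to_long().to_csv(path, sep="\t", index=False)


def _zscore_offdiag(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy()
    mask = ~np.eye(len(df), dtype=bool)
    pop = vals[mask]
    mu, sd = pop.mean(), pop.std(ddof=1)
    if sd == 0:
        z = np.zeros_like(vals)
    else:
        z = (vals - mu) / sd
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def merge_scores(c1d: pd.DataFrame, c3d: pd.DataFrame) -> PairScoreTable:
    """Keep the larger of the 1D and 3D scores at each entry; add z-scores."""
    if list(c1d.index) != list(c3d.index) or list(c1d.columns) != list(c3d.columns):
        raise ValueError("1D and 3D matrices must index the same DBP set")
    merged = pd.DataFrame(np.maximum(c1d.to_numpy(), c3d.to_numpy()),
                          index=c1d.index, columns=c1d.columns)
    np.fill_diagonal(merged.values, 1.0)
    return PairScoreTable(
        dbps=list(c1d.index),
        corr1d=c1d, corr3d=c3d, merged=merged,
        z1d=_zscore_offdiag(c1d), z3d=_zscore_offdiag(c3d),
    )
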