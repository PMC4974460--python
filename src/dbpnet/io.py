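"""Readers and writers for the text formats the pipeline consumes and emits.

Supported inputs: BED6/tagAlign read intervals (optionally gzipped),
BEDPE-style loop lists in the Rao et al. 5-kb dialect, BioGRID tab-delimited
protein-protein interaction tables, and GWAS-catalog variant TSVs.
Outputs: narrowPeak peak calls, bin-score matrices, pair-score and edge
tables.
"""

from __future__ import annotations

import gzip
from typing import IO

import numpy as np
import pandas as pd
import networkx as nx

from .layout import GenomeLayout, ReadSet

__all__ = [
    "read_bed_reads",
    "read_bedpe_loops",
    "read_biogrid",
    "read_gwas_variants",
    "write_narrowpeak",
    "write_score_matrix",
]


def _open_text(path: str) -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_bed_reads(path: str, total: int | None = None) -> ReadSet:
    """Load read intervals from a BED6/tagAlign file (gzip allowed)."""
    with _open_text(path) as fh:
        df = pd.read_csv(
            fh, sep="\t", header=None, comment="#",
            usecols=[0, 1, 2], names=["chrom", "start", "end"],
            dtype={0: str, 1: np.int64, 2: np.int64},
        )
    strand = None
    try:
        with _open_text(path) as fh:
            s = pd.read_csv(fh, sep="\t", header=None, comment="#", usecols=[5],
                            names=["strand"], dtype=str)
        strand = s["strand"].to_numpy()
    except (ValueError, IndexError, pd.errors.ParserError):
        pass
    return ReadSet(df["chrom"].to_numpy(), df["start"].to_numpy(),
                   df["end"].to_numpy(), strand=strand, total=total)


class MalformedLoopError(ValueError):
    """A loop record could not be parsed; carries the 1-based line number."""

    def __init__(self, lineno: int, line: str):
        self.lineno = lineno
        super().__init__(f"malformed loop record at line {lineno}: {line.rstrip()!r}")


def read_bedpe_loops(path: str) -> pd.DataFrame:
    """Parse a BEDPE-like loop list into a six-column DataFrame.

    Columns beyond the six anchor coordinates are ignored; header lines
    (starting with '#', 'chr1\\t' headers, or any line whose coordinate
    fields are not integers on the first line) are tolerated.
    """
    rows = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 6:
                raise MalformedLoopError(lineno, line)
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]),
                             parts[3], int(parts[4]), int(parts[5])))
            except ValueError:
                if lineno == 1:  # header line, e.g. Rao et al. column names
                    continue
                raise MalformedLoopError(lineno, line) from None
    df = pd.DataFrame(rows, columns=["chrom1", "start1", "end1",
                                     "chrom2", "start2", "end2"])
    bad = (df["start1"] >= df["end1"]) | (df["start2"] >= df["end2"])
    if bad.any():
        raise MalformedLoopError(int(np.flatnonzero(bad)[0]) + 1, "invalid interval")
    return df


def read_biogrid(path: str) -> nx.Graph:
    """Load a BioGRID tab-delimited PPI table as an undirected graph.

    Accepts either the official-symbol columns of BioGRID tab formats or a
    plain two-column edge list. Identifiers are uppercased; self-loops are
    dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c for c in df.columns if "official symbol" in c.lower()]
    if len(cols) >= 2:
        a, b = df[cols[0]], df[cols[1]]
    elif df.shape[1] >= 2:
        a, b = df.iloc[:, 0], df.iloc[:, 1]
    else:
        raise ValueError("PPI table needs at least two columns")
    g = nx.Graph()
    for x, y in zip(a.str.upper(), b.str.upper()):
        if pd.isna(x) or pd.isna(y) or x == y:
            continue
        g.add_edge(x, y)
    return g


def read_gwas_variants(path: str) -> pd.DataFrame:
    """Load variant positions from a GWAS-catalog TSV or a 2-column file.

    Returns a DataFrame with 'chrom' and 'pos' (1-based) columns. Rows with
    missing or non-numeric positions are dropped.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "CHR_ID" in df.columns and "CHR_POS" in df.columns:
        out = df[["CHR_ID", "CHR_POS"]].rename(
            columns={"CHR_ID": "chrom", "CHR_POS": "pos"})
    elif df.shape[1] >= 2:
        out = df.iloc[:, :2].set_axis(["chrom", "pos"], axis=1)
    else:
        raise ValueError("variant table needs CHR_ID/CHR_POS or two columns")
    out = out.dropna()
    out = out[out["pos"].str.fullmatch(r"\d+")]
    out = out.assign(pos=out["pos"].astype(np.int64))
    return out.reset_index(drop=True)


def write_narrowpeak(path: str, peakcall, name: str = "peak") -> None:
    """Write called peak bins in narrowPeak layout (one row per peak bin)."""
    layout = peakcall.layout
    with open(path, "w") as fh:
        k = 0
        for idx in np.flatnonzero(peakcall.is_peak):
            chrom, start, end = layout.bin_interval(int(idx))
            k += 1
            p = peakcall.pvalue[idx]
            mlogp = 999.0 if p <= 0 else float(-np.log10(p))
            fh.write(
                f"{chrom}\t{start}\t{end}\t{name}_{k}\t0\t.\t"
                f"{peakcall.fold_enrichment[idx]:.4f}\t{mlogp:.4f}\t-1\t-1\n"
            )


def write_score_matrix(path: str, matrix) -> None:
    """Write an enrichment matrix as TSV: bin_id rows, DBP columns."""
    matrix.to_frame().to_csv(path, sep="\t", index_label="bin_id")
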