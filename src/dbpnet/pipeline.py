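"""End-to-end pipeline orchestration with a config file and a manifest.

Stages: signal (binning, peak calling, variance filter) -> cooperation
(1D/3D pair scores) -> network (graphical lasso, edge classification) ->
analysis (hubs, communities, cliques) -> enrichment (PPI overlap, optional
GWAS). Every run writes a manifest recording parameter values, the seed,
per-stage status and input checksums, which suffices to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import io as dio
from .cooperation import LoopSet
from .fixtures import fixture_score_tracks  # noqa: F401  (re-export convenience)
from .graph import (centrality_ranking, detect_communities, maximal_cliques,
                    rank_cliques, rank_loci_by_binding, write_loci_bed)
from .layout import GenomeLayout
from .network import network_from_tracks
from .signal import (build_enrichment_matrix, call_peaks, compute_rpkm,
                     count_reads, local_lambda)

log = logging.getLogger("dbpnet")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    reads: dict[str, str]          # DBP name -> BED path
    chrom_sizes: str
    loops: str | None = None
    ppi: str | None = None
    gwas: str | None = None
    out_dir: str = "dbpnet_run"
    bin_size: int = 1000
    p_cutoff: float = 0.01
    min_sd: float = 1.0
    penalty: float = 0.3
    class_cutoff: float = 0.3
    min_clique: int = 3
    selector: str = "max"
    reps: int = 10_000
    seed: int = 0
    read_assign: str = "midpoint"

    def __post_init__(self):
        if not (0 < self.p_cutoff <= 1):
            raise ValueError("p_cutoff must lie in (0, 1]")
        if self.penalty < 0 or self.min_sd < 0 or self.class_cutoff < 0:
            raise ValueError("thresholds must be non-negative")

    @classmethod
    def from_yaml(cls, path: str, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        """Derive a per-stage seed from the global one (stable hash)."""
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


def _checksum(path: str) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": {k: v for k, v in asdict(config).items()
                       if k != "reads"},
        "inputs": {},
        "seed": config.seed,
        "stages": [],
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    for name, path in config.reads.items():
        manifest["inputs"][name] = {"path": str(path), "md5": _checksum(path)}
    for key in ("chrom_sizes", "loops", "ppi", "gwas"):
        p = getattr(config, key)
        if p:
            manifest["inputs"][key] = {"path": str(p), "md5": _checksum(p)}

    def stage(name):
        def deco(fn):
            def run(*a, **kw):
                log.info("stage %s started", name)
                t0 = time.time()
                try:
                    r = fn(*a, **kw)
                except Exception as e:
                    manifest["stages"].append(
                        {"name": name, "status": "failed", "error": str(e)})
                    (out / "manifest.json").write_text(
                        json.dumps(manifest, indent=1, default=str))
                    raise StageError(name, e) from e
                manifest["stages"].append(
                    {"name": name, "status": "ok",
                     "seconds": round(time.time() - t0, 2)})
                log.info("stage %s done (%.1fs)", name, time.time() - t0)
                return r
            return run
        return deco

    @stage("signal")
    def do_signal():
        layout = GenomeLayout.from_chrom_sizes(config.chrom_sizes,
                                               config.bin_size)
        tracks, calls = [], []
        for name, path in config.reads.items():
            rs = dio.read_bed_reads(path)
            rpkm = compute_rpkm(rs, layout, assign=config.read_assign)
            lam = local_lambda(rpkm, layout)
            counts = count_reads(rs, layout, assign=config.read_assign)
            pc = call_peaks(rpkm, counts, lam, total_reads=rs.total,
                            p_cutoff=config.p_cutoff, name=name)
            dio.write_narrowpeak(out / f"{name}.narrowPeak", pc, name=name)
            calls.append(pc)
            tracks.append(pc.score_track())
        matrix = build_enrichment_matrix(calls, min_sd=config.min_sd)
        dio.write_score_matrix(out / "enrichment_matrix.tsv", matrix)
        return layout, tracks, matrix

    @stage("cooperation+network")
    def do_network(layout, tracks):
        loops = None
        if config.loops:
            loops = LoopSet.from_frame(dio.read_bedpe_loops(config.loops))
        else:
            log.warning("no loop file: running in 1D-only degraded mode; "
                        "3D scores reported as absent")
        net, pairs = network_from_tracks(
            tracks, layout, loops, penalty=config.penalty,
            cutoff=config.class_cutoff, min_sd=config.min_sd,
            selector=config.selector)
        pairs.write(out / "pair_scores.tsv")
        with open(out / "edges.tsv", "w") as fh:
            fh.write("dbpA\tdbpB\tcorr1d\tcorr3d\tmerged\tpartial_corr\tclass\n")
            for a, b, d in sorted(net.edges(data=True)):
                fh.write(f"{a}\t{b}\t{d['corr_1d']:.6f}\t{d['corr_3d']:.6f}\t"
                         f"{d['merged']:.6f}\t{d['partial_corr']:.6f}\t"
                         f"{d['label']}\n")
        return net, pairs, loops

    @stage("analysis")
    def do_analysis(net, pairs):
        if net.number_of_nodes() and net.number_of_edges():
            centrality_ranking(net).to_csv(out / "centrality.tsv", sep="\t")
            comm = detect_communities(net)
            with open(out / "communities.tsv", "w") as fh:
                fh.write("node\tcommunity\n")
                for n, c in sorted(comm.membership().items()):
                    fh.write(f"{n}\t{c}\n")
            cliques = rank_cliques(maximal_cliques(net, config.min_clique),
                                   pairs)
            with open(out / "cliques.json", "w") as fh:
                json.dump([{"members": c.members, "rank": c.rank,
                            "mean_merged": c.mean_merged,
                            "mean_corr_1d": c.mean_corr_1d,
                            "mean_corr_3d": c.mean_corr_3d}
                           for c in cliques], fh, indent=1)
        else:
            log.warning("network empty; skipping topology outputs")

    @stage("loci")
    def do_loci(matrix):
        df = rank_loci_by_binding(matrix, top_n=5000)
        write_loci_bed(df, out / "top_loci.bed")

    @stage("enrichment")
    def do_enrichment(net):
        if not config.ppi or net.number_of_edges() == 0:
            return
        from .enrich import ppi_overlap, ppi_pvalue
        ppi = dio.read_biogrid(config.ppi)
        ppi_overlap(net, ppi).to_csv(out / "ppi_labels.tsv", sep="\t",
                                     index=False)
        res = ppi_pvalue(net, ppi, reps=config.reps,
                         seed=config.stage_seed("ppi"))
        with open(out / "ppi_enrichment.json", "w") as fh:
            json.dump({k: v.to_dict() for k, v in res.items()}, fh, indent=1)

    layout, tracks, matrix = do_signal()
    net, pairs, loops = do_network(layout, tracks)
    do_analysis(net, pairs)
    do_loci(matrix)
    do_enrichment(net)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                  default=str))
    return out
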