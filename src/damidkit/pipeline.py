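"""End-to-end workflow: digest -> QC -> profile -> segment -> call LADs.

``run_pipeline`` wires the stages together, writes every intermediate as a
plain-text file next to the final LAD calls, and stamps a provenance JSON
(config hash, seed, parameters) so any output can be re-derived.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import io, qc
from .digest import build_bin_map, build_fragment_map, fragment_size_stats
from .lads import call_lads
from .profiles import count_reads, log2_ratio, quantile_normalize, smooth
from .segment import CBSParams, cbs_segment

log = logging.getLogger("damidkit")


@dataclass
class PipelineConfig:
    """All stage parameters with their defaults, plus input/output paths."""

    fasta: str = ""
    lmnb1: str = ""
    dam: str = ""
    gaps: str | None = None
    outdir: str = "damid_out"
    bin_size: int | None = None  # None = DpnI fragments
    mapq_min: int = qc.DEFAULT_MAPQ_MIN
    excluded_chroms: tuple[str, ...] = tuple(sorted(qc.DEFAULT_MITO_NAMES))
    min_clean_reads: int = qc.DEFAULT_MIN_CLEAN_READS
    count_mode: str = "overlap"
    pseudocount: float = 1.0
    smooth_n: int = 20
    quantile_norm: bool = True
    smooth_before_norm: bool = False
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    tau: float = 0.0
    merge_dist: int = 5000
    min_size: int = 10000
    seed: int = 7

    def __post_init__(self):
        if self.count_mode not in ("overlap", "midpoint"):
            raise ValueError("count_mode must be 'overlap' or 'midpoint'")
        if self.smooth_n < 0:
            raise ValueError("smooth_n must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        CBSParams(self.alpha, max(self.n_perm, 100), self.min_width, self.seed)
        if self.min_size < 0 or self.merge_dist < 0:
            raise ValueError("min_size and merge_dist must be >= 0")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    fragment_stats: dict
    reports: dict
    lads: "object"
    segments: "object"
    profile: "object"
    outputs: dict = field(default_factory=dict)


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    genome = _stage("digest")(io.read_fasta)(config.fasta)
    if config.bin_size:
        fmap = build_bin_map(genome, config.bin_size)
    else:
        fmap = build_fragment_map(genome)
    # excluded contigs (mitochondria by default) carry no usable signal
    # after QC; keep them out of the quantitation coordinate system
    kept_chroms = [c for c in fmap.chroms if c not in set(config.excluded_chroms)]
    if kept_chroms != fmap.chroms:
        fmap = fmap.subset(kept_chroms)
    io.fragment_map_to_bed(fmap, outdir / "fragments.bed")
    outputs["fragments"] = str(outdir / "fragments.bed")
    fstats = fragment_size_stats(fmap)

    reports = {}
    tracks = {}
    for sample, path in (("lmnb1", config.lmnb1), ("dam", config.dam)):
        aln = _stage("qc")(io.read_alignments)(path)
        filtered, report = qc.filter_alignments(
            aln, mapq_min=config.mapq_min,
            excluded_chroms=set(config.excluded_chroms), sample=sample,
        )
        qc.qc_depth_check(report, min_clean_reads=config.min_clean_reads)
        io.write_json(report.as_dict(), outdir / f"qc_{sample}.json")
        outputs[f"qc_{sample}"] = str(outdir / f"qc_{sample}.json")
        reports[sample] = report
        tracks[sample] = _stage("profile")(count_reads)(
            fmap, filtered, mode=config.count_mode, sample=sample
        )

    profile = _stage("profile")(log2_ratio)(
        tracks["lmnb1"], tracks["dam"], pseudocount=config.pseudocount
    )
    if config.smooth_before_norm and config.smooth_n:
        profile = smooth(profile, config.smooth_n)
    if config.quantile_norm:
        profile = quantile_normalize([profile])[0]
    if not config.smooth_before_norm and config.smooth_n:
        profile = smooth(profile, config.smooth_n)
    io.write_bedgraph(fmap, profile.values, outdir / "profile.bedGraph")
    outputs["profile"] = str(outdir / "profile.bedGraph")

    params = CBSParams(config.alpha, max(config.n_perm, 100), config.min_width,
                       config.seed)
    segments = _stage("segment")(cbs_segment)(profile, params)
    seg_df = segments.to_dataframe()
    io.write_bed(seg_df, outdir / "segments.bed")
    outputs["segments"] = str(outdir / "segments.bed")

    gaps = io.read_bed(config.gaps) if config.gaps else None
    ladset = _stage("call-lads")(call_lads)(
        segments, gaps, tau=config.tau, max_gap=config.merge_dist,
        min_size=config.min_size,
    )
    if ladset.intervals.empty:
        log.warning("no LADs called with the current parameters")
    io.write_bed(ladset.intervals, outdir / "lads.bed")
    outputs["lads"] = str(outdir / "lads.bed")

    provenance = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "fragment_stats": fstats,
        "qc": {s: r.as_dict() for s, r in reports.items()},
        "lad_provenance": ladset.provenance,
        "n_lads": len(ladset),
        "lad_bp": ladset.total_bp,
        "outputs": outputs,
    }
    io.write_json(provenance, outdir / "provenance.json")
    outputs["provenance"] = str(outdir / "provenance.json")

    return PipelineResult(
        fragment_stats=fstats,
        reports=reports,
        lads=ladset,
        segments=segments,
        profile=profile,
        outputs=outputs,
    )
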