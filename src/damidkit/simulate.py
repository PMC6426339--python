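"""Synthetic DamID experiments with known ground truth.

The generator follows the physical chain of the assay rather than drawing
log-ratios directly: a random genome is digested in silico, LADs are placed
as genomic blocks, every internal GATC site is methylated with a
probability given by its lamina-contact probability (LaminB1-Dam sample)
or by a uniform accessibility constant (Dam-only sample), a fragment
becomes an amplifiable template only when BOTH flanking sites are
methylated (the DpnI/DpnII selection), and reads are drawn per amplifiable
fragment from a Poisson law with mitochondrial contaminant reads injected
on a dedicated chrM contig.  This exercises every pipeline stage, produces
realistic zero-count fragments, and makes truth recovery measurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .digest import FragmentMap, GenomeIndex, build_fragment_map

__all__ = [
    "SimParams",
    "SimTruth",
    "AmpliconSet",
    "simulate_genome",
    "simulate_lads",
    "simulate_methylation_and_amplicons",
    "simulate_reads",
    "simulate_experiment",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_LAD_SEPARATION = 20_000  # minimum bp between placed LADs
_PLACEMENT_ATTEMPTS = 200_000


@dataclass
class SimParams:
    """Study conditions for a synthetic DamID experiment.

    ``enrichment`` is the log2 read-rate boost applied to LaminB1
    amplifiable fragments inside LADs on top of the methylation-level
    amplicon selection; the contact probabilities (0.9 inside LADs, 0.1
    outside) govern which fragments can amplify at all.
    """

    genome_length: int = 40_000_000  # total autosomal bp
    n_chromosomes: int = 4
    lad_coverage: float = 0.4
    lad_min_len: int = 30_000
    lad_max_len: int = 2_000_000  # log-uniform length law over [min, max]
    enrichment: float = 2.0  # log2 in-LAD LaminB1 rate boost
    reads_per_sample: int = 2_000_000
    chrm_fraction: float = 0.15
    read_length: int = 90
    chrm_length: int = 16_000
    p_contact_in: float = 0.9
    p_contact_out: float = 0.1
    dam_accessibility: float = 0.95
    dam_accessibility_in_lads: float | None = None  # optional dip, e.g. 0.3
    rng_seed: int = 0

    def __post_init__(self):
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not 0 <= self.lad_coverage <= 0.6:
            raise ValueError("lad_coverage must be in [0, 0.6]")
        if not 0 <= self.chrm_fraction < 1:
            raise ValueError("chrm_fraction must be in [0, 1)")
        if self.enrichment <= 0:
            raise ValueError("enrichment must be positive")
        if not 0 < self.lad_min_len <= self.lad_max_len:
            raise ValueError("bad LAD length bounds")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic per-stage generator derived from the base seed."""
        stage_key = sum(ord(c) for c in stage)
        return np.random.default_rng(
            np.random.SeedSequence(entropy=self.rng_seed, spawn_key=(stage_key,))
        )


@dataclass
class SimTruth:
    """Ground-truth LAD intervals and the contact-probability model."""

    lads: pd.DataFrame  # chrom, start, end; disjoint, sorted
    params: SimParams

    def in_lad(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Boolean: is each position inside a true LAD?"""
        sel = self.lads[self.lads["chrom"] == chrom]
        out = np.zeros(len(positions), dtype=bool)
        if sel.empty:
            return out
        starts = sel["start"].to_numpy()
        ends = sel["end"].to_numpy()
        idx = np.searchsorted(starts, positions, side="right") - 1
        valid = idx >= 0
        out[valid] = positions[valid] < ends[idx[valid]]
        return out

    def contact_prob(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        inside = self.in_lad(chrom, np.asarray(positions))
        return np.where(inside, self.params.p_contact_in, self.params.p_contact_out)

    def fragment_in_lad(self, fmap: FragmentMap) -> np.ndarray:
        """Per-fragment LAD membership by midpoint, genome order."""
        out = np.zeros(fmap.n_fragments, dtype=bool)
        for chrom in fmap.chroms:
            sl = fmap.chrom_slice(chrom)
            mid = (fmap.starts[chrom] + fmap.ends[chrom]) // 2
            out[sl] = self.in_lad(chrom, mid)
        return out

    @property
    def total_bp(self) -> int:
        if self.lads.empty:
            return 0
        return int((self.lads["end"] - self.lads["start"]).sum())


@dataclass
class AmpliconSet:
    """Amplifiable (PCR-competent) fragments for one sample."""

    fmap: FragmentMap
    amplifiable: np.ndarray  # bool per fragment
    sample: str = ""

    def lengths(self) -> np.ndarray:
        return self.fmap.lengths()[self.amplifiable]

    def size_histogram(self, bins=None) -> tuple[np.ndarray, np.ndarray]:
        lengths = self.lengths()
        if bins is None:
            bins = np.arange(0, max(int(lengths.max()) + 100, 200), 100)
        return np.histogram(lengths, bins=bins)

    def mass_fraction(self, lo: int, hi: int) -> float:
        """Fraction of amplifiable base pairs carried by fragments in [lo, hi]."""
        lengths = self.lengths()
        if lengths.sum() == 0:
            return 0.0
        in_band = lengths[(lengths >= lo) & (lengths <= hi)]
        return float(in_band.sum() / lengths.sum())


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def simulate_genome(params: SimParams, rng: np.random.Generator | None = None) -> GenomeIndex:
    """i.i.d.-uniform ACGT genome plus a small chrM contig.

    GATC density is ~1/256 per position, giving a fragment-length law close
    to the mammalian DpnI map's shape at a median of ~177 bp.
    """
    rng = rng if rng is not None else params.stage_rng("genome")
    n = params.n_chromosomes
    per_chrom = params.genome_length // n
    seqs = {}
    for i in range(n):
        length = per_chrom if i < n - 1 else params.genome_length - per_chrom * (n - 1)
        seqs[f"chr{i + 1}"] = _random_sequence(rng, length)
    seqs["chrM"] = _random_sequence(rng, params.chrm_length)
    return GenomeIndex(seqs)


def simulate_lads(
    params: SimParams, genome: GenomeIndex, rng: np.random.Generator | None = None
) -> SimTruth:
    """Place disjoint LAD blocks until the coverage target is reached.

    Lengths are log-uniform over [lad_min_len, lad_max_len]; placed LADs
    keep a minimum separation so truth intervals stay distinct through the
    merge step of LAD calling.  Raises when the target is unreachable
    within a bounded number of attempts.
    """
    rng = rng if rng is not None else params.stage_rng("lads")
    autosomes = [c for c in genome.chroms if c != "chrM"]
    lengths = {c: len(genome[c]) for c in autosomes}
    total = sum(lengths.values())
    target = params.lad_coverage * total
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in autosomes}
    covered = 0
    attempts = 0
    chrom_weights = np.array([lengths[c] for c in autosomes], dtype=float)
    chrom_weights /= chrom_weights.sum()
    while covered < target:
        if attempts >= _PLACEMENT_ATTEMPTS:
            raise RuntimeError(
                f"could not reach LAD coverage {params.lad_coverage} after "
                f"{attempts} attempts (reached {covered / total:.3f})"
            )
        attempts += 1
        lad_len = int(
            np.exp(rng.uniform(np.log(params.lad_min_len), np.log(params.lad_max_len)))
        )
        chrom = autosomes[rng.choice(len(autosomes), p=chrom_weights)]
        if lad_len >= lengths[chrom]:
            continue
        start = int(rng.integers(0, lengths[chrom] - lad_len))
        end = start + lad_len
        ok = all(
            end + _LAD_SEPARATION <= s or start >= e + _LAD_SEPARATION
            for s, e in placed[chrom]
        )
        if not ok:
            continue
        placed[chrom].append((start, end))
        covered += lad_len
    rows = [
        (c, s, e) for c in autosomes for s, e in sorted(placed[c])
    ]
    lads = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return SimTruth(lads=lads, params=params)


def simulate_methylation_and_amplicons(
    truth: SimTruth,
    fmap: FragmentMap,
    params: SimParams,
    rng_lmnb1: np.random.Generator | None = None,
    rng_dam: np.random.Generator | None = None,
) -> dict[str, AmpliconSet]:
    """Methylate GATC sites per sample and select amplifiable fragments.

    Each internal cut site is methylated independently: in the LaminB1-Dam
    sample with its positional lamina-contact probability, in the Dam-only
    sample with the accessibility constant (optionally dipped inside LADs,
    peripheral chromatin being less accessible to free Dam).  A fragment is
    an amplifiable template iff both flanking sites are methylated --
    terminal fragments and the chrM contig never amplify (contaminant
    mitochondrial reads are injected separately).
    """
    rngs = {
        "lmnb1": rng_lmnb1 if rng_lmnb1 is not None else params.stage_rng("meth-lmnb1"),
        "dam": rng_dam if rng_dam is not None else params.stage_rng("meth-dam"),
    }
    out = {}
    for sample, rng in rngs.items():
        amp = np.zeros(fmap.n_fragments, dtype=bool)
        for chrom in fmap.chroms:
            if chrom == "chrM":
                continue
            sites = fmap.starts[chrom][1:]  # internal cut positions
            nf = len(fmap.starts[chrom])
            if len(sites) == 0:
                continue
            if sample == "lmnb1":
                p = truth.contact_prob(chrom, sites)
            else:
                p = np.full(len(sites), params.dam_accessibility)
                if params.dam_accessibility_in_lads is not None:
                    inside = truth.in_lad(chrom, sites)
                    p = np.where(inside, params.dam_accessibility_in_lads, p)
            meth = rng.random(len(sites)) < p
            frag_amp = np.zeros(nf, dtype=bool)
            if nf >= 3:
                frag_amp[1:-1] = meth[:-1] & meth[1:]
            sl = fmap.chrom_slice(chrom)
            amp[sl] = frag_amp
        out[sample] = AmpliconSet(fmap=fmap, amplifiable=amp, sample=sample)
    return out


def simulate_reads(
    truth: SimTruth,
    fmap: FragmentMap,
    amplicons: dict[str, AmpliconSet],
    params: SimParams,
    rngs: dict[str, np.random.Generator] | None = None,
) -> tuple[dict[str, pd.DataFrame], dict]:
    """Draw per-sample reads and inject mitochondrial contamination.

    Per fragment the read count is Poisson with mean proportional to
    amplifiable-indicator x fragment length (x the in-LAD enrichment boost
    for the LaminB1 sample); read start positions are uniform within the
    fragment.  ``chrm_fraction`` of each sample's reads land uniformly on
    chrM.  Output alignment tables are coordinate-sorted with mapq 60.
    """
    if rngs is None:
        rngs = {s: params.stage_rng(f"reads-{s}") for s in ("lmnb1", "dam")}
    frag_lengths = fmap.lengths()
    in_lad = truth.fragment_in_lad(fmap)
    chrom_of = np.concatenate(
        [np.full(len(fmap.starts[c]), i) for i, c in enumerate(fmap.chroms)]
    )
    gstart = np.concatenate([fmap.starts[c] for c in fmap.chroms])
    chrom_names = np.array(fmap.chroms)
    chrom_len = np.array([fmap.chrom_length(c) for c in fmap.chroms])

    streams: dict[str, pd.DataFrame] = {}
    report: dict = {"samples": {}}
    for sample, rng in rngs.items():
        amp = amplicons[sample].amplifiable
        w = amp * frag_lengths.astype(float)
        if sample == "lmnb1":
            w = w * np.where(in_lad, 2.0 ** params.enrichment, 1.0)
        n_reads = params.reads_per_sample
        n_chrm = int(rng.binomial(n_reads, params.chrm_fraction)) if n_reads else 0
        n_gen = n_reads - n_chrm
        parts = []
        wsum = w.sum()
        if n_gen > 0 and wsum > 0:
            lam = n_gen * w / wsum
            counts = rng.poisson(lam)
            idx = np.repeat(np.arange(fmap.n_fragments), counts)
            offs = np.floor(rng.random(len(idx)) * frag_lengths[idx]).astype(np.int64)
            starts = gstart[idx] + offs
            ci = chrom_of[idx]
            ends = np.minimum(starts + params.read_length, chrom_len[ci])
            parts.append(
                pd.DataFrame(
                    {"chrom": chrom_names[ci], "start": starts, "end": ends,
                     "mapq": 60, "flag": 0}
                )
            )
        if n_chrm > 0:
            span = max(params.chrm_length - params.read_length, 1)
            ms = rng.integers(0, span, size=n_chrm)
            parts.append(
                pd.DataFrame(
                    {"chrom": "chrM", "start": ms,
                     "end": np.minimum(ms + params.read_length, params.chrm_length),
                     "mapq": 60, "flag": 0}
                )
            )
        if parts:
            df = pd.concat(parts, ignore_index=True)
            df = df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        else:
            df = pd.DataFrame(columns=["chrom", "start", "end", "mapq", "flag"])
        streams[sample] = df
        report["samples"][sample] = {
            "n_reads": len(df),
            "n_chrM_injected": n_chrm,
            "n_genomic": len(df) - n_chrm,
        }
    report["lad_bp"] = truth.total_bp
    report["n_lads"] = len(truth.lads)
    return streams, report


@dataclass
class SimExperiment:
    genome: GenomeIndex
    fmap: FragmentMap
    truth: SimTruth
    amplicons: dict[str, AmpliconSet]
    reads: dict[str, pd.DataFrame]
    report: dict


def simulate_experiment(params: SimParams) -> SimExperiment:
    """Run the whole generator chain deterministically from ``rng_seed``."""
    genome = simulate_genome(params)
    fmap = build_fragment_map(genome)
    truth = simulate_lads(params, genome)
    amplicons = simulate_methylation_and_amplicons(truth, fmap, params)
    reads, report = simulate_reads(truth, fmap, amplicons, params)
    return SimExperiment(genome, fmap, truth, amplicons, reads, report)
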