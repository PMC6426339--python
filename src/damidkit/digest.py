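"""In-silico DpnI digestion: GATC motif finding, fragment maps and fixed-size bins.

DamID quantitation happens on the intervals between adjacent GATC sites
("DpnI fragments"), so everything downstream of the raw genome is indexed by
the fragment map built here.  Coordinates are 0-based, half-open (BED
convention) throughout.  DpnI cleaves GA^TC leaving blunt ends, so the cut
coordinate is ``motif_start + 2``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

_GATC = re.compile("GATC")

__all__ = [
    "GenomeIndex",
    "FragmentMap",
    "find_gatc_sites",
    "build_fragment_map",
    "build_bin_map",
    "fragment_size_stats",
]


class GenomeIndex:
    """Reference genome held in memory as upper-case sequences.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to nucleotide sequence (A/C/G/T/N; lower
        case accepted and upper-cased, i.e. soft-masking is ignored).
    """

    def __init__(self, sequences: dict[str, str]):
        if not sequences:
            raise ValueError("GenomeIndex requires at least one chromosome")
        self.sequences: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} has zero length")
            self.sequences[name] = seq.upper()

    @property
    def chroms(self) -> list[str]:
        return list(self.sequences)

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __eq__(self, other) -> bool:
        return isinstance(other, GenomeIndex) and self.sequences == other.sequences


@dataclass
class FragmentMap:
    """Ordered, disjoint intervals partitioning each chromosome.

    ``starts[chrom]`` / ``ends[chrom]`` are int64 arrays; per chromosome the
    intervals are sorted, disjoint and tile exactly ``[0, chrom_length)``.
    Fragment ids are implicit: the global index of a fragment in chromosome
    order (``chroms`` order, then position), strictly increasing genome-wide.
    """

    chroms: list[str]
    starts: dict[str, np.ndarray]
    ends: dict[str, np.ndarray]
    mode: str = "dpnI"  # "dpnI" | "fixed_bin"
    bin_size: int | None = None
    _offsets: dict[str, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        off = 0
        self._offsets = {}
        for c in self.chroms:
            s = np.asarray(self.starts[c], dtype=np.int64)
            e = np.asarray(self.ends[c], dtype=np.int64)
            if len(s) != len(e) or len(s) == 0:
                raise ValueError(f"bad fragment arrays for {c}")
            if s[0] != 0 or np.any(e <= s) or np.any(s[1:] != e[:-1]):
                raise ValueError(f"fragments on {c} do not tile the chromosome")
            self.starts[c], self.ends[c] = s, e
            self._offsets[c] = off
            off += len(s)
        self._n = off

    @property
    def n_fragments(self) -> int:
        return self._n

    def chrom_length(self, chrom: str) -> int:
        return int(self.ends[chrom][-1])

    def offset(self, chrom: str) -> int:
        """Global index of the first fragment on ``chrom``."""
        return self._offsets[chrom]

    def chrom_slice(self, chrom: str) -> slice:
        lo = self._offsets[chrom]
        return slice(lo, lo + len(self.starts[chrom]))

    def lengths(self) -> np.ndarray:
        """Fragment lengths (bp), genome order."""
        return np.concatenate([self.ends[c] - self.starts[c] for c in self.chroms])

    def subset(self, chroms: list[str]) -> "FragmentMap":
        """Restrict to the given chromosomes (e.g. dropping contaminant
        contigs before quantitation); fragment ids are renumbered."""
        keep = [c for c in self.chroms if c in set(chroms)]
        if not keep:
            raise ValueError("subset would remove every chromosome")
        return FragmentMap(
            keep,
            {c: self.starts[c].copy() for c in keep},
            {c: self.ends[c].copy() for c in keep},
            mode=self.mode,
            bin_size=self.bin_size,
        )

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in self.chroms:
            frames.append(
                pd.DataFrame({"chrom": c, "start": self.starts[c], "end": self.ends[c]})
            )
        df = pd.concat(frames, ignore_index=True)
        df["fragment_id"] = np.arange(len(df))
        return df

    def __eq__(self, other) -> bool:
        if not isinstance(other, FragmentMap) or self.chroms != other.chroms:
            return False
        return all(
            np.array_equal(self.starts[c], other.starts[c])
            and np.array_equal(self.ends[c], other.ends[c])
            for c in self.chroms
        )


def find_gatc_sites(sequence: str) -> list[int]:
    """Return 0-based start positions of every GATC motif.

    Matching is case-insensitive; motifs containing N never match.  GATC
    cannot overlap itself, so a simple scan finds all occurrences.
    """
    return [m.start() for m in _GATC.finditer(sequence.upper())]


def build_fragment_map(genome: GenomeIndex) -> FragmentMap:
    """Digest a genome at every GATC into the DpnI fragment map.

    Cut positions are ``motif_start + 2`` (blunt GA^TC cleavage); fragments
    are the intervals between consecutive cuts plus the two terminal
    intervals.  A chromosome with no GATC yields a single fragment.
    """
    starts, ends = {}, {}
    for chrom in genome.chroms:
        seq = genome[chrom]
        cuts = np.array([p + 2 for p in find_gatc_sites(seq)], dtype=np.int64)
        bounds = np.concatenate([[0], cuts, [len(seq)]])
        starts[chrom] = bounds[:-1]
        ends[chrom] = bounds[1:]
    return FragmentMap(genome.chroms, starts, ends, mode="dpnI")


def build_bin_map(genome: GenomeIndex, bin_size: int) -> FragmentMap:
    """Partition each chromosome into consecutive fixed-size bins.

    The final bin is truncated at the chromosome end.  An alternative
    coordinate system to DpnI fragments; 2–5 kb is a reasonable default
    range for DamID.
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    starts, ends = {}, {}
    for chrom in genome.chroms:
        length = len(genome[chrom])
        s = np.arange(0, length, bin_size, dtype=np.int64)
        e = np.minimum(s + bin_size, length)
        starts[chrom], ends[chrom] = s, e
    return FragmentMap(genome.chroms, starts, ends, mode="fixed_bin", bin_size=bin_size)


def fragment_size_stats(fmap: FragmentMap, size_threshold: int = 3000) -> dict:
    """Genome-wide fragment length statistics.

    Returns median, 95th percentile, the fraction of fragments strictly
    under ``size_threshold`` bp, and the fragment count.
    """
    lengths = fmap.lengths()
    if lengths.size == 0:
        raise ValueError("empty fragment map")
    return {
        "median": float(np.median(lengths)),
        "p95": float(np.percentile(lengths, 95)),
        "fraction_under_threshold": float(np.mean(lengths < size_threshold)),
        "n_fragments": int(lengths.size),
    }
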