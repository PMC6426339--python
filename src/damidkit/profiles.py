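"""Per-fragment count and log2(LaminB1-Dam/Dam-only) ratio tracks.

Counts are normalized within each sample to the proportion of that sample's
filtered reads overlapping each fragment; the signal is the log2 ratio of
the two normalized tracks (with a pseudocount so zero-count fragments stay
finite), optionally quantile-normalized across profiles and smoothed with a
centered running mean over fragments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .digest import FragmentMap

log = logging.getLogger("damidkit")

__all__ = [
    "CountTrack",
    "RatioProfile",
    "count_reads",
    "normalize_counts",
    "log2_ratio",
    "quantile_normalize",
    "smooth",
]


@dataclass
class CountTrack:
    """Raw per-fragment read counts for one sample."""

    fmap: FragmentMap
    counts: np.ndarray  # int64, one entry per fragment, genome order
    total_filtered_reads: int
    sample: str = ""
    n_skipped: int = 0  # reads on contigs absent from the fragment map

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != self.fmap.n_fragments:
            raise ValueError("count vector length does not match fragment map")
        if (self.counts < 0).any():
            raise ValueError("negative counts")


@dataclass
class RatioProfile:
    """Per-fragment log2 ratio values on a fragment map.

    ``smoothing_n`` records the smoothing window already applied (0 = raw);
    ``quantile_normalized`` whether the values went through quantile
    normalization.
    """

    fmap: FragmentMap
    values: np.ndarray
    smoothing_n: int = 0
    quantile_normalized: bool = False
    sample: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.fmap.n_fragments:
            raise ValueError("value vector length does not match fragment map")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite values in ratio profile")

    def chrom_values(self, chrom: str) -> np.ndarray:
        return self.values[self.fmap.chrom_slice(chrom)]


def count_reads(
    fmap: FragmentMap, alignments: pd.DataFrame, mode: str = "overlap",
    sample: str = "",
) -> CountTrack:
    """Count filtered reads per fragment.

    ``overlap`` mode increments every fragment a read overlaps by >=1 bp
    (the native DamID accounting); ``midpoint`` increments only the fragment
    containing the read midpoint.  Reads on contigs absent from the map are
    tallied as skipped, not fatal.
    """
    if mode not in ("overlap", "midpoint"):
        raise ValueError(f"unknown counting mode {mode!r}")
    counts = np.zeros(fmap.n_fragments, dtype=np.int64)
    n_used = 0
    n_skipped = 0
    for chrom, group in alignments.groupby("chrom", sort=False):
        if chrom not in fmap.starts:
            n_skipped += len(group)
            continue
        starts = fmap.starts[chrom]
        L = fmap.chrom_length(chrom)
        off = fmap.offset(chrom)
        rs = np.clip(group["start"].to_numpy(np.int64), 0, L - 1)
        re_ = np.clip(group["end"].to_numpy(np.int64), 1, L)
        if mode == "midpoint":
            mid = (rs + re_) // 2
            idx = np.searchsorted(starts, mid, side="right") - 1
            np.add.at(counts, off + idx, 1)
        else:
            i0 = np.searchsorted(starts, rs, side="right") - 1
            i1 = np.searchsorted(starts, re_ - 1, side="right") - 1
            # range-increment via difference array
            n = len(starts)
            diff = np.zeros(n + 1, dtype=np.int64)
            np.add.at(diff, i0, 1)
            np.add.at(diff, i1 + 1, -1)
            counts[off : off + n] += np.cumsum(diff[:-1])
        n_used += len(group)
    if n_skipped:
        log.warning("count_reads: %d reads on contigs absent from the fragment map",
                    n_skipped)
    return CountTrack(fmap, counts, total_filtered_reads=n_used, sample=sample,
                      n_skipped=n_skipped)


def normalize_counts(track: CountTrack) -> np.ndarray:
    """Per-fragment proportion of the sample's total filtered reads.

    In overlap mode a read spanning several fragments contributes to each,
    so the proportions may sum to more than 1 by design.
    """
    if track.total_filtered_reads <= 0:
        raise ValueError("cannot normalize a track with zero total reads")
    return track.counts / track.total_filtered_reads


def log2_ratio(lmnb1: CountTrack, dam: CountTrack, pseudocount: float = 1.0) -> RatioProfile:
    """log2 of the LaminB1-Dam over Dam-only normalized counts.

    A pseudocount (default 1 read) is added to both samples' raw counts
    before forming proportions, guaranteeing finite values on zero-count
    fragments.
    """
    if lmnb1.fmap != dam.fmap:
        raise ValueError("count tracks are on different fragment maps")
    if lmnb1.total_filtered_reads <= 0 or dam.total_filtered_reads <= 0:
        raise ValueError("cannot form ratios with zero total reads")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    num = (lmnb1.counts + pseudocount) / lmnb1.total_filtered_reads
    den = (dam.counts + pseudocount) / dam.total_filtered_reads
    return RatioProfile(lmnb1.fmap, np.log2(num / den), sample=lmnb1.sample)


def quantile_normalize(profiles: list[RatioProfile]) -> list[RatioProfile]:
    """Force all profiles to share the same value distribution.

    Each rank is mapped to the across-profile mean of that rank's sorted
    values; tied values within a profile all receive the mean of the
    reference values their ranks span.  A single profile is returned
    unchanged with a notice.
    """
    if not profiles:
        raise ValueError("no profiles given")
    if len(profiles) == 1:
        log.info("quantile_normalize: single profile, returned unchanged")
        return [replace(profiles[0])]
    fmap = profiles[0].fmap
    if any(p.fmap != fmap for p in profiles[1:]):
        raise ValueError("profiles are on different fragment maps")
    mat = np.stack([p.values for p in profiles])
    reference = np.sort(mat, axis=1).mean(axis=0)
    out = []
    for p in profiles:
        order = np.argsort(p.values, kind="mergesort")
        assigned = np.empty_like(reference)
        assigned[order] = reference
        # average assigned reference values over ties
        normalized = (
            pd.Series(assigned).groupby(pd.Series(p.values)).transform("mean").to_numpy()
        )
        out.append(replace(p, values=normalized, quantile_normalized=True))
    return out


def smooth(profile: RatioProfile, n: int) -> RatioProfile:
    """Centered running mean over ``n`` surrounding fragments.

    Each value is replaced by the mean of itself and n/2 fragments on each
    side (n+1 values for even n); windows are truncated at chromosome ends
    and never cross chromosomes.  ``n=0`` is the identity.  Odd ``n`` is
    rounded down to the nearest even value with a warning.
    """
    if n < 0:
        raise ValueError("smoothing window must be non-negative")
    if n % 2:
        log.warning("smooth: odd window %d rounded down to %d", n, n - 1)
        n -= 1
    if n == 0:
        return replace(profile, smoothing_n=0)
    half = n // 2
    out = np.empty_like(profile.values)
    for chrom in profile.fmap.chroms:
        sl = profile.fmap.chrom_slice(chrom)
        v = profile.values[sl]
        m = len(v)
        pos = np.arange(m)
        lo = np.maximum(pos - half, 0)
        hi = np.minimum(pos + half + 1, m)
        csum = np.concatenate([[0.0], np.cumsum(v)])
        out[sl] = (csum[hi] - csum[lo]) / (hi - lo)
    return replace(profile, values=out, smoothing_n=n)
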