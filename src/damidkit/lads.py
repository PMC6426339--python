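"""LAD calling from CBS segments and LAD-set comparison.

The final LAD list is obtained from the segment means by the four-step
rule: subtract assembly gaps, keep segments whose mean exceeds the
threshold (strict ``>``, default 0), merge intervals separated by at most
``max_gap`` bp (default 5 kb), and drop intervals shorter than ``min_size``
bp (inclusive ``>=``, default 10 kb).  Defaults sit inside the ranges that
work well in practice (merge 5–8 kb, size cut 5–30 kb).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segment import SegmentSet

__all__ = [
    "LADSet",
    "subtract_gaps",
    "threshold_segments",
    "merge_intervals",
    "filter_min_size",
    "call_lads",
    "compare_lads",
]

_EMPTY = pd.DataFrame(columns=["chrom", "start", "end"])


@dataclass
class LADSet:
    """Final called LADs with the parameters that produced them."""

    intervals: pd.DataFrame  # chrom, start, end; sorted, non-overlapping
    provenance: dict = field(default_factory=dict)

    @property
    def total_bp(self) -> int:
        if self.intervals.empty:
            return 0
        return int((self.intervals["end"] - self.intervals["start"]).sum())

    def __len__(self) -> int:
        return len(self.intervals)


def _sorted(df: pd.DataFrame) -> pd.DataFrame:
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


def subtract_gaps(intervals: pd.DataFrame, gaps: pd.DataFrame) -> pd.DataFrame:
    """Base-pair set difference ``intervals - gaps``.

    Extra columns (e.g. segment means) are carried through to every
    surviving piece; intervals fully covered by gaps vanish.
    """
    if intervals.empty or gaps is None or gaps.empty:
        return _sorted(intervals.copy())
    gaps = _sorted(gaps)
    rows = []
    gap_by_chrom = {c: g for c, g in gaps.groupby("chrom")}
    for row in _sorted(intervals).itertuples(index=False):
        pieces = [(row.start, row.end)]
        g = gap_by_chrom.get(row.chrom)
        if g is not None:
            for gs, ge in zip(g["start"], g["end"]):
                nxt = []
                for s, e in pieces:
                    if ge <= s or gs >= e:
                        nxt.append((s, e))
                        continue
                    if s < gs:
                        nxt.append((s, gs))
                    if ge < e:
                        nxt.append((ge, e))
                pieces = nxt
        for s, e in pieces:
            d = row._asdict()
            d["start"], d["end"] = s, e
            rows.append(d)
    if not rows:
        return _EMPTY.copy()
    return _sorted(pd.DataFrame(rows))


def threshold_segments(segments: SegmentSet | pd.DataFrame, tau: float = 0.0) -> pd.DataFrame:
    """Keep segments with mean value strictly above ``tau``."""
    df = segments.to_dataframe() if isinstance(segments, SegmentSet) else segments
    if df.empty:
        return _EMPTY.copy()
    return _sorted(df.loc[df["mean"] > tau, ["chrom", "start", "end", "mean"]])


def merge_intervals(intervals: pd.DataFrame, max_gap: int = 5000) -> pd.DataFrame:
    """Union overlapping intervals and same-chromosome gaps of <= ``max_gap`` bp."""
    if intervals.empty:
        return _EMPTY.copy()
    df = _sorted(intervals)
    rows = []
    for chrom, grp in df.groupby("chrom", sort=False):
        starts = grp["start"].to_numpy()
        ends = np.maximum.accumulate(grp["end"].to_numpy())
        new_block = np.ones(len(grp), dtype=bool)
        new_block[1:] = starts[1:] - ends[:-1] > max_gap
        block = np.cumsum(new_block)
        for _, b in pd.DataFrame({"s": starts, "e": grp["end"].to_numpy(), "b": block}).groupby("b"):
            rows.append((chrom, int(b["s"].min()), int(b["e"].max())))
    return _sorted(pd.DataFrame(rows, columns=["chrom", "start", "end"]))


def filter_min_size(intervals: pd.DataFrame, min_size: int = 10000) -> pd.DataFrame:
    """Retain intervals with length >= ``min_size`` (inclusive)."""
    if intervals.empty:
        return _EMPTY.copy()
    keep = (intervals["end"] - intervals["start"]) >= min_size
    return _sorted(intervals.loc[keep, ["chrom", "start", "end"]])


def call_lads(
    segments: SegmentSet | pd.DataFrame,
    gaps: pd.DataFrame | None = None,
    tau: float = 0.0,
    max_gap: int = 5000,
    min_size: int = 10000,
) -> LADSet:
    """Full LAD-calling rule: gaps -> threshold -> merge -> size filter."""
    df = segments.to_dataframe() if isinstance(segments, SegmentSet) else segments
    if gaps is None:
        gaps = _EMPTY.copy()
    step1 = subtract_gaps(df, gaps)
    step2 = threshold_segments(step1, tau)
    step3 = merge_intervals(step2, max_gap)
    step4 = filter_min_size(step3, min_size)
    return LADSet(
        intervals=step4[["chrom", "start", "end"]].reset_index(drop=True),
        provenance={"tau": tau, "max_gap": max_gap, "min_size": min_size,
                    "n_gaps": len(gaps)},
    )


def _intersect_bp(a: pd.DataFrame, b: pd.DataFrame) -> int:
    total = 0
    b_by_chrom = {c: g for c, g in b.groupby("chrom")}
    for chrom, ga in a.groupby("chrom"):
        gb = b_by_chrom.get(chrom)
        if gb is None:
            continue
        sa, ea = ga["start"].to_numpy(), ga["end"].to_numpy()
        for s, e in zip(gb["start"], gb["end"]):
            total += int(np.maximum(0, np.minimum(ea, e) - np.maximum(sa, s)).sum())
    return total


def compare_lads(a: LADSet | pd.DataFrame, b: LADSet | pd.DataFrame) -> dict:
    """Binary presence/absence comparison of two LAD sets.

    Returns the base-pair Jaccard index, the exclusive base pairs of each
    set, and for every boundary of ``a`` the distance to the nearest
    boundary of ``b`` on the same chromosome.
    """
    da = a.intervals if isinstance(a, LADSet) else a
    db = b.intervals if isinstance(b, LADSet) else b
    da, db = merge_intervals(da, max_gap=0) if not da.empty else da, (
        merge_intervals(db, max_gap=0) if not db.empty else db
    )
    bp_a = int((da["end"] - da["start"]).sum()) if not da.empty else 0
    bp_b = int((db["end"] - db["start"]).sum()) if not db.empty else 0
    inter = _intersect_bp(da, db) if bp_a and bp_b else 0
    union = bp_a + bp_b - inter
    offsets = []
    if not da.empty and not db.empty:
        b_bounds = {
            c: np.sort(np.concatenate([g["start"].to_numpy(), g["end"].to_numpy()]))
            for c, g in db.groupby("chrom")
        }
        for row in da.itertuples(index=False):
            bb = b_bounds.get(row.chrom)
            if bb is None:
                continue
            for x in (row.start, row.end):
                offsets.append(int(np.min(np.abs(bb - x))))
    return {
        "jaccard": (inter / union) if union else 1.0,
        "a_only_bp": bp_a - inter,
        "b_only_bp": bp_b - inter,
        "boundary_offsets": offsets,
    }
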