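"""LAD-calling rule steps, composition, comparison, and bedtools cross-checks."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from damidkit import (
    call_lads,
    compare_lads,
    filter_min_size,
    merge_intervals,
    subtract_gaps,
    threshold_segments,
)


def iv(rows, cols=("chrom", "start", "end")):
    return pd.DataFrame(rows, columns=list(cols))


def test_subtract_gap_splits_interval():
    out = subtract_gaps(iv([("c", 0, 100_000)]), iv([("c", 40_000, 60_000)]))
    assert list(zip(out.start, out.end)) == [(0, 40_000), (60_000, 100_000)]


def test_subtract_no_overlap_unchanged():
    out = subtract_gaps(iv([("c", 0, 100)]), iv([("c", 200, 300)]))
    assert list(zip(out.start, out.end)) == [(0, 100)]


def test_subtract_engulfing_gap_removes_interval():
    out = subtract_gaps(iv([("c", 10, 20)]), iv([("c", 0, 50)]))
    assert out.empty


@pytest.mark.parametrize(
    "mean,tau,kept",
    [(0.05, 0.0, True), (0.05, 0.1, False), (-0.3, 0.0, False), (0.1, 0.1, False)],
)
def test_threshold_is_strict(mean, tau, kept):
    seg = iv([("c", 0, 1000, mean)], cols=("chrom", "start", "end", "mean"))
    out = threshold_segments(seg, tau)
    assert (len(out) == 1) == kept


@pytest.mark.parametrize(
    "a,b,max_gap,merged",
    [((0, 10_000), (14_000, 20_000), 5000, True),
     ((0, 10_000), (19_000, 25_000), 8000, False),
     ((0, 10_000), (5_000, 12_000), 0, True)],
)
def test_merge_gap_rule(a, b, max_gap, merged):
    out = merge_intervals(iv([("c", *a), ("c", *b)]), max_gap)
    assert len(out) == (1 if merged else 2)


def test_merge_never_joins_chromosomes():
    out = merge_intervals(iv([("c1", 0, 10), ("c2", 0, 10)]), max_gap=10**9)
    assert len(out) == 2


@pytest.mark.parametrize(
    "length,min_size,kept", [(4000, 5000, False), (5000, 5000, True), (0, 0, True)]
)
def test_min_size_is_inclusive(length, min_size, kept):
    out = filter_min_size(iv([("c", 0, length)]), min_size)
    assert (len(out) == 1) == kept


def test_filter_min_size_empty_input():
    assert filter_min_size(iv([]), 5000).empty


def test_call_lads_composition():
    segs = iv([("c", 0, 100_000, 0.5)], cols=("chrom", "start", "end", "mean"))
    gaps = iv([("c", 40_000, 60_000)])
    lset = call_lads(segs, gaps, tau=0.0, max_gap=5000, min_size=10_000)
    assert list(zip(lset.intervals.start, lset.intervals.end)) == [
        (0, 40_000), (60_000, 100_000)
    ]
    assert lset.provenance["tau"] == 0.0


def test_call_lads_all_negative_is_empty():
    segs = iv([("c", 0, 100_000, -0.4)], cols=("chrom", "start", "end", "mean"))
    assert len(call_lads(segs)) == 0


def test_call_lads_is_idempotent():
    segs = iv(
        [("c", 0, 50_000, 1.0), ("c", 50_000, 52_000, -1.0), ("c", 52_000, 90_000, 0.8)],
        cols=("chrom", "start", "end", "mean"),
    )
    first = call_lads(segs)
    again = call_lads(
        first.intervals.assign(mean=1.0)[["chrom", "start", "end", "mean"]]
    )
    pd.testing.assert_frame_equal(first.intervals, again.intervals)


def test_lads_never_intersect_gaps():
    rng = np.random.default_rng(2)
    segs = iv(
        [("c", s, s + 30_000, rng.normal(0.5, 0.2)) for s in range(0, 600_000, 30_000)],
        cols=("chrom", "start", "end", "mean"),
    )
    gaps = iv([("c", 95_000, 130_000), ("c", 400_000, 410_000)])
    lset = call_lads(segs, gaps)
    for row in lset.intervals.itertuples():
        for g in gaps.itertuples():
            assert row.end <= g.start or row.start >= g.end


def test_parameter_monotonicity():
    rng = np.random.default_rng(8)
    starts = np.arange(0, 2_000_000, 20_000)
    segs = iv(
        [("c", s, s + 20_000, rng.normal(0.1, 0.5)) for s in starts],
        cols=("chrom", "start", "end", "mean"),
    )
    bp = lambda ls: ls.total_bp
    assert bp(call_lads(segs, tau=0.0)) >= bp(call_lads(segs, tau=0.2))
    assert bp(call_lads(segs, min_size=5000)) >= bp(call_lads(segs, min_size=50_000))
    assert len(call_lads(segs, max_gap=0)) >= len(call_lads(segs, max_gap=50_000))


def test_compare_lads_examples():
    a = iv([("c", 0, 100)])
    assert compare_lads(a, a.copy())["jaccard"] == 1.0
    assert compare_lads(a, iv([("c", 200, 300)]))["jaccard"] == 0.0
    res = compare_lads(a, iv([("c", 50, 150)]))
    assert res["jaccard"] == pytest.approx(1 / 3)
    assert res["a_only_bp"] == 50 and res["b_only_bp"] == 50
    assert sorted(res["boundary_offsets"]) == [50, 50]


def _run_bedtools(args, stdin=None):
    return subprocess.run(args, input=stdin, capture_output=True, text=True,
                          check=True).stdout


def _to_bed(df):
    return "".join(f"{r.chrom}\t{r.start}\t{r.end}\n" for r in df.itertuples())


def test_subtract_matches_bedtools(tmp_path):
    if shutil.which("bedtools") is None:
        pytest.fail("bedtools not available for the cross-check")
    rng = np.random.default_rng(13)
    ivs, gaps = [], []
    for chrom in ("c1", "c2"):
        pos = 0
        for _ in range(20):
            pos += int(rng.integers(100, 5000))
            end = pos + int(rng.integers(100, 8000))
            ivs.append((chrom, pos, end))
            pos = end
        for _ in range(10):
            s = int(rng.integers(0, 120_000))
            gaps.append((chrom, s, s + int(rng.integers(50, 6000))))
    a, b = iv(ivs), merge_intervals(iv(gaps), 0)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    fa.write_text(_to_bed(a))
    fb.write_text(_to_bed(b))
    expected = _run_bedtools(["bedtools", "subtract", "-a", fa, "-b", fb])
    ours = subtract_gaps(a, b)
    assert _to_bed(ours) == expected


def test_merge_matches_bedtools(tmp_path):
    if shutil.which("bedtools") is None:
        pytest.fail("bedtools not available for the cross-check")
    rng = np.random.default_rng(17)
    rows = sorted(
        ("c1", int(s), int(s + rng.integers(100, 4000)))
        for s in rng.integers(0, 100_000, size=30)
    )
    df = iv(rows)
    f = tmp_path / "in.bed"
    f.write_text(_to_bed(df))
    for dist in (0, 2000, 8000):
        expected = _run_bedtools(["bedtools", "merge", "-d", str(dist), "-i", f])
        assert _to_bed(merge_intervals(df, dist)) == expected
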