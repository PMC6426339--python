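"""Counting, normalization, log2 ratios, quantile normalization, smoothing."""

import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from damidkit import (
    CountTrack,
    RatioProfile,
    count_reads,
    log2_ratio,
    normalize_counts,
    quantile_normalize,
    smooth,
)


@pytest.mark.parametrize(
    "read,mode,expected",
    [
        ((5, 9), "overlap", (0, 1, 0)),
        ((5, 9), "midpoint", (0, 1, 0)),
        ((2, 6), "overlap", (1, 1, 0)),
        ((2, 6), "midpoint", (0, 1, 0)),  # midpoint 4 -> second fragment
    ],
)
def test_count_reads_modes(toy_fmap, make_alignments, read, mode, expected):
    aln = make_alignments([("c1", read[0], read[1], 60, 0)])
    track = count_reads(toy_fmap, aln, mode=mode)
    assert tuple(track.counts) == expected
    assert track.total_filtered_reads == 1


def test_count_reads_unknown_contig_tallied(toy_fmap, make_alignments):
    aln = make_alignments([("c1", 0, 4, 60, 0), ("weird", 0, 4, 60, 0)])
    track = count_reads(toy_fmap, aln)
    assert track.n_skipped == 1 and track.total_filtered_reads == 1


def test_normalize_counts(toy_fmap):
    track = CountTrack(toy_fmap, np.array([2, 1, 1]), total_filtered_reads=4)
    assert tuple(normalize_counts(track)) == (0.5, 0.25, 0.25)
    empty = CountTrack(toy_fmap, np.zeros(3, int), total_filtered_reads=0)
    with pytest.raises(ValueError):
        normalize_counts(empty)


def test_overlap_proportions_may_exceed_one(toy_fmap, make_alignments):
    # one read spanning two fragments: each gets proportion 1.0 by design
    aln = make_alignments([("c1", 2, 6, 60, 0)])
    track = count_reads(toy_fmap, aln, mode="overlap")
    assert tuple(normalize_counts(track)) == (1.0, 1.0, 0.0)


def test_log2_ratio_identical_tracks_is_zero(toy_fmap):
    t = CountTrack(toy_fmap, np.array([3, 7, 2]), total_filtered_reads=12)
    assert np.allclose(log2_ratio(t, t).values, 0.0)


def test_log2_ratio_pseudocount_arithmetic(toy_fmap):
    l = CountTrack(toy_fmap, np.array([15, 0, 0]), total_filtered_reads=100)
    d = CountTrack(toy_fmap, np.array([3, 0, 0]), total_filtered_reads=100)
    prof = log2_ratio(l, d, pseudocount=1)
    assert prof.values[0] == pytest.approx(np.log2(16 / 4)) == pytest.approx(2.0)
    assert np.all(np.isfinite(prof.values))  # zero counts guarded


def test_log2_ratio_rejects_mismatched_maps(toy_fmap, make_fmap):
    a = CountTrack(toy_fmap, np.array([1, 1, 1]), total_filtered_reads=3)
    b = CountTrack(make_fmap(3), np.array([1, 1, 1]), total_filtered_reads=3)
    with pytest.raises(ValueError):
        log2_ratio(a, b)


def test_quantile_normalize_hand_example(make_fmap):
    fmap = make_fmap(3)
    p1 = RatioProfile(fmap, np.array([1.0, 3.0, 5.0]))
    p2 = RatioProfile(fmap, np.array([2.0, 4.0, 8.0]))
    q1, q2 = quantile_normalize([p1, p2])
    assert np.allclose(q1.values, [1.5, 3.5, 6.5])
    assert np.allclose(q2.values, [1.5, 3.5, 6.5])
    assert q1.quantile_normalized and q2.quantile_normalized


def test_quantile_normalize_identity_cases(make_fmap):
    fmap = make_fmap(4)
    p = RatioProfile(fmap, np.array([0.5, -1.0, 2.0, 0.0]))
    (single,) = quantile_normalize([p])
    assert np.allclose(single.values, p.values)
    q1, q2 = quantile_normalize([p, RatioProfile(fmap, p.values.copy())])
    assert np.allclose(q1.values, p.values) and np.allclose(q2.values, p.values)


def test_quantile_normalize_rank_and_multiset_properties(make_fmap):
    rng = np.random.default_rng(3)
    fmap = make_fmap(60)
    profiles = [RatioProfile(fmap, rng.normal(size=60)) for _ in range(3)]
    out = quantile_normalize(profiles)
    for before, after in zip(profiles, out):
        assert np.array_equal(np.argsort(before.values), np.argsort(after.values))
    for other in out[1:]:
        assert np.allclose(np.sort(out[0].values), np.sort(other.values))


def test_quantile_normalize_matches_limma(make_fmap, tmp_path):
    """Cross-check against limma::normalizeQuantiles on a tie-free matrix."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the limma cross-check")
    rng = np.random.default_rng(7)
    mat = rng.normal(size=(25, 2))
    fmap = make_fmap(25)
    ours = quantile_normalize([RatioProfile(fmap, mat[:, i]) for i in range(2)])
    csv_in = tmp_path / "mat.csv"
    csv_out = tmp_path / "qn.csv"
    np.savetxt(csv_in, mat, delimiter=",")
    script = (
        f"suppressMessages(library(limma));"
        f"m <- as.matrix(read.csv('{csv_in}', header=FALSE));"
        f"write.table(normalizeQuantiles(m), '{csv_out}', sep=',',"
        f"row.names=FALSE, col.names=FALSE)"
    )
    subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
    theirs = np.loadtxt(csv_out, delimiter=",")
    for i in range(2):
        assert np.allclose(ours[i].values, theirs[:, i], atol=1e-8)


def test_smooth_hand_examples(make_fmap):
    fmap = make_fmap(5)
    prof = RatioProfile(fmap, np.array([0.0, 0.0, 10.0, 0.0, 0.0]))
    sm = smooth(prof, 2)
    assert np.allclose(sm.values, [0, 10 / 3, 10 / 3, 10 / 3, 0])
    # truncated edge window: element 0 averages elements 0..1
    prof2 = RatioProfile(fmap, np.array([4.0, 0.0, 0.0, 0.0, 0.0]))
    assert smooth(prof2, 2).values[0] == pytest.approx(2.0)


def test_smooth_identity_and_constant(make_fmap):
    fmap = make_fmap(10)
    const = RatioProfile(fmap, np.full(10, 1.25))
    assert np.allclose(smooth(const, 6).values, 1.25)
    prof = RatioProfile(fmap, np.arange(10.0))
    assert np.array_equal(smooth(prof, 0).values, prof.values)
    with pytest.raises(ValueError):
        smooth(prof, -2)


def test_smooth_rounds_odd_window_down(make_fmap):
    fmap = make_fmap(6)
    prof = RatioProfile(fmap, np.arange(6.0))
    assert np.allclose(smooth(prof, 5).values, smooth(prof, 4).values)


def test_smooth_is_linear(make_fmap):
    rng = np.random.default_rng(0)
    fmap = make_fmap(40)
    x = RatioProfile(fmap, rng.normal(size=40))
    y = RatioProfile(fmap, rng.normal(size=40))
    combo = RatioProfile(fmap, 2.0 * x.values + 3.0 * y.values)
    assert np.allclose(
        smooth(combo, 10).values,
        2.0 * smooth(x, 10).values + 3.0 * smooth(y, 10).values,
    )


def test_smooth_does_not_cross_chromosomes(make_fmap):
    fmap = make_fmap(5, chroms=("chrA", "chrB"))
    values = np.concatenate([np.full(5, 10.0), np.zeros(5)])
    sm = smooth(RatioProfile(fmap, values), 4)
    assert np.allclose(sm.values[:5], 10.0) and np.allclose(sm.values[5:], 0.0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=10))
def test_step_zero_crossing_moves_at_most_half_window(half):
    """On a noiseless step the sign change after smoothing by n stays
    within n/2 fragments of the true boundary."""
    from damidkit import FragmentMap

    n_frags, boundary = 60, 30
    starts = {"c": np.arange(n_frags, dtype=np.int64) * 100}
    fmap = FragmentMap(["c"], starts, {"c": starts["c"] + 100})
    step = np.where(np.arange(n_frags) < boundary, -1.0, 1.0)
    sm = smooth(RatioProfile(fmap, step), 2 * half)
    crossing = int(np.argmax(sm.values > 0))
    assert abs(crossing - boundary) <= half
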