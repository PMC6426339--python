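"""Circular binary segmentation (CBS) of per-fragment log2 ratio profiles.

CBS recursively splits each chromosome's value vector at the circular arc
whose inside/outside mean difference maximizes a pooled-variance t-like
statistic, accepting a split only when a within-segment permutation test
deems it significant.  Because the statistic is symmetric between an arc
and its complement, scanning contiguous arcs covers the wrapped ones too.

For long segments the arc search runs on a geometric grid of arc widths
with local refinement around the best width; the permutation decision
always compares the observed statistic and the permuted statistics on the
same width grid, so the split test remains a like-for-like exchangeability
test at any segment size.  |T| is monotone in the centered arc sum for a
fixed width, so each permutation costs one maximum and one minimum per
width instead of a full arc scan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .digest import FragmentMap
from .profiles import RatioProfile

__all__ = ["CBSParams", "Segment", "SegmentSet", "max_arc_statistic", "cbs_segment"]

VAR_FLOOR = 1e-12  # pooled-variance floor for near-constant arcs
_TIE_TOL = 1e-9
_SMALL_N = 64  # below this every arc is evaluated directly, perms included
_EXACT_SCAN_N = 2000  # exhaustive width scan (boundary placement) below this
_FINE_RATIO = 1.02
_COARSE_RATIO = 1.2
_BATCH_ELEMS = 4_000_000


@dataclass
class CBSParams:
    """Knobs of the split test (DNAcopy-like defaults)."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    rng_seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class Segment:
    chrom: str
    first: int  # within-chromosome fragment index, inclusive
    last: int  # inclusive
    start: int  # bp
    end: int  # bp
    mean_value: float
    n_fragments: int


@dataclass
class SegmentSet:
    fmap: FragmentMap
    segments: list[Segment] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [s.chrom for s in self.segments],
                "start": [s.start for s in self.segments],
                "end": [s.end for s in self.segments],
                "id": np.arange(len(self.segments)),
                "mean": [s.mean_value for s in self.segments],
            }
        )


# ---------------------------------------------------------------------------
# arc statistic


def _t_from_d(d, k, n: int, tot: float, ssq: float):
    """t statistic of arc sum ``d`` over width ``k`` vs the rest.

    Pooled within-group variance with a floor.  ``d`` and ``k`` broadcast.
    """
    mean_in = d / k
    mean_out = (tot - d) / (n - k)
    ss = ssq - d * mean_in - (tot - d) * mean_out
    s2 = np.maximum(ss / max(n - 2, 1), VAR_FLOOR)
    return (mean_in - mean_out) / np.sqrt(s2 * (1.0 / k + 1.0 / (n - k)))


@lru_cache(maxsize=512)
def _arc_pairs(n: int, min_width: int, half: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """(i, j) arc endpoint pairs with min_width <= j-i <= n-min_width.

    With ``half=True`` only widths up to n//2 are enumerated: an arc and
    its complement share |T|, so the half set suffices wherever only the
    maximum of |T| matters (the permutation null and the decision
    statistic).
    """
    hi = n // 2 if half else n - min_width
    i_list, j_list = [], []
    for k in range(min_width, hi + 1):
        i = np.arange(0, n - k + 1, dtype=np.int64)
        i_list.append(i)
        j_list.append(i + k)
    return np.concatenate(i_list), np.concatenate(j_list)


def _width_grid(n: int, min_width: int, ratio: float) -> np.ndarray:
    hi = n - min_width
    ks = [min_width]
    k = float(min_width)
    while ks[-1] < hi:
        k = max(k * ratio, k + 1)
        ks.append(min(int(round(k)), hi))
    return np.unique(np.asarray(ks, dtype=np.int64))


def _better(cand, best) -> bool:
    """Order candidates (absT, T, i, j): larger |T|, then positive T
    (elevated arc), then smaller i, then smaller j."""
    a_abs, a_T, a_i, a_j = cand
    b_abs, b_T, b_i, b_j = best
    tol = _TIE_TOL * max(1.0, a_abs, b_abs)
    if a_abs > b_abs + tol:
        return True
    if a_abs < b_abs - tol:
        return False
    if (a_T > 0) != (b_T > 0):
        return a_T > 0
    return (a_i, a_j) < (b_i, b_j)


def _scan_small(v: np.ndarray, min_width: int, half: bool = False):
    """Best arc by direct evaluation of every (i, j) pair."""
    n = len(v)
    I, J = _arc_pairs(n, min_width, half)
    S = np.concatenate([[0.0], np.cumsum(v)])
    d = S[J] - S[I]
    k = (J - I).astype(float)
    T = _t_from_d(d, k, n, float(S[-1]), float(np.dot(v, v)))
    absT = np.abs(T)
    top = absT.max()
    best = None
    for idx in np.flatnonzero(absT >= top - _TIE_TOL * max(1.0, top)):
        cand = (float(absT[idx]), float(T[idx]), int(I[idx]), int(J[idx]))
        if best is None or _better(cand, best):
            best = cand
    return best[2], best[3], best[1]


def _scan_widths(v: np.ndarray, widths: np.ndarray):
    """Best arc over the given widths via per-width sliding extremes.

    |T| is monotone in |d - k*mu| for fixed width k, so only the extreme
    arc sums need full statistic evaluation (batched across widths).
    """
    n = len(v)
    S = np.concatenate([[0.0], np.cumsum(v)])
    tot = float(S[-1])
    ssq = float(np.dot(v, v))
    w = len(widths)
    dvals = np.empty(2 * w)
    ivals = np.empty(2 * w, dtype=np.int64)
    for m, k in enumerate(widths):
        d = S[k:] - S[:-k]
        hi = int(np.argmax(d))
        lo = int(np.argmin(d))
        dvals[2 * m], ivals[2 * m] = d[hi], hi
        dvals[2 * m + 1], ivals[2 * m + 1] = d[lo], lo
    karr = np.repeat(widths, 2).astype(float)
    T = _t_from_d(dvals, karr, n, tot, ssq)
    absT = np.abs(T)
    top = absT.max()
    best = None
    for idx in np.flatnonzero(absT >= top - _TIE_TOL * max(1.0, top)):
        i = int(ivals[idx])
        cand = (float(absT[idx]), float(T[idx]), i, i + int(karr[idx]))
        if best is None or _better(cand, best):
            best = cand
    if best is None:
        return None
    return best[2], best[3], best[1]


def _scan_best(v: np.ndarray, min_width: int):
    """Best arc with exact widths (small/medium n) or grid + refinement."""
    n = len(v)
    if n <= _SMALL_N:
        return _scan_small(v, min_width)
    if n <= _EXACT_SCAN_N:
        return _scan_widths(v, np.arange(min_width, n - min_width + 1, dtype=np.int64))
    i, j, t = _scan_widths(v, _width_grid(n, min_width, _FINE_RATIO))
    k = j - i
    lo_k = max(min_width, int(k / _FINE_RATIO**2))
    hi_k = min(n - min_width, int(math.ceil(k * _FINE_RATIO**2)))
    res = _scan_widths(v, np.arange(lo_k, hi_k + 1, dtype=np.int64))
    if res is not None and abs(res[2]) >= abs(t):
        i, j, t = res
    return i, j, t


def max_arc_statistic(values, min_width: int = 1):
    """Arc ``(i, j]`` maximizing the two-sample |T| vs the rest of the vector.

    Exhaustive over all arc widths.  Returns ``(i, j, T)`` with T signed
    (positive when the arc mean exceeds the outside mean); a constant
    vector returns ``(None, None, 0.0)``.  On |T| ties the elevated arc is
    preferred, then the smallest ``i``, then the smallest ``j``.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    if n < 4:
        raise ValueError("need at least 4 values")
    if np.ptp(v) == 0:
        return None, None, 0.0
    if n <= max(_SMALL_N, 512):
        return _scan_small(v, min_width)
    return _scan_widths(v, np.arange(min_width, n - min_width + 1, dtype=np.int64))


# ---------------------------------------------------------------------------
# permutation split test


def _decision_widths(n: int, min_width: int) -> np.ndarray | None:
    if n <= _SMALL_N:
        return None  # all arcs, pair-vectorized (widths <= n/2 by symmetry)
    grid = _width_grid(n, min_width, _COARSE_RATIO)
    return grid[grid <= n // 2]


def _decision_stat(v: np.ndarray, widths: np.ndarray | None, min_width: int) -> float:
    if widths is None:
        res = _scan_small(v, min_width, half=True)
    else:
        res = _scan_widths(v, widths)
    return abs(res[2]) if res is not None else 0.0


def _perm_batch_max(perm: np.ndarray, widths: np.ndarray | None, min_width: int,
                    n: int, tot: float, ssq: float) -> np.ndarray:
    """Max |T| per permuted row (arc/complement symmetry: widths <= n/2)."""
    S = np.concatenate([np.zeros((perm.shape[0], 1)), np.cumsum(perm, axis=1)], axis=1)
    if widths is None:
        widths = np.arange(min_width, max(n // 2, min_width) + 1, dtype=np.int64)
    w = len(widths)
    dvals = np.empty((2 * w, perm.shape[0]))
    for m, k in enumerate(widths):
        d = S[:, k:] - S[:, :-k]
        dvals[2 * m] = d.max(axis=1)
        dvals[2 * m + 1] = d.min(axis=1)
    karr = np.repeat(widths, 2).astype(float)[:, None]
    T = _t_from_d(dvals, karr, n, tot, ssq)
    return np.abs(T).max(axis=0)


def _split_significant(
    v: np.ndarray, widths: np.ndarray | None, t_obs: float, params: CBSParams,
    rng: np.random.Generator,
) -> bool:
    """Permutation test of the max-arc statistic, early-stopping once the
    exceedance count already rules out significance."""
    n = len(v)
    tot = float(v.sum())
    ssq = float(np.dot(v, v))
    n_perm = params.n_perm
    exceed = 0
    done = 0
    batch = min(n_perm, 128)  # small first batch for cheap early rejection
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm = rng.permuted(np.tile(v, (b, 1)), axis=1)
        stats = _perm_batch_max(perm, widths, params.min_width, n, tot, ssq)
        exceed += int(np.sum(stats >= t_obs - _TIE_TOL))
        done += b
        if (1 + exceed) / (1 + n_perm) >= params.alpha:
            return False
        batch = max(128, _BATCH_ELEMS // max(n, 1))
    return True


def _segment_vector(v: np.ndarray, params: CBSParams, rng: np.random.Generator) -> list[int]:
    """Recursive CBS on one chromosome; returns sorted internal changepoints."""
    mw = params.min_width
    changepoints: list[int] = []
    stack = [(0, len(v))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < max(2 * mw, 4):
            continue
        x = v[lo:hi]
        if np.ptp(x) == 0:
            continue
        widths = _decision_widths(n, mw)
        t_obs = _decision_stat(x, widths, mw)
        if t_obs <= 0:
            continue
        if not _split_significant(x, widths, t_obs, params, rng):
            continue
        i, j, _ = _scan_best(x, mw)
        cuts = [c for c in (i, j) if 0 < c < n]
        if not cuts:
            continue
        changepoints.extend(lo + c for c in cuts)
        pieces = [lo] + [lo + c for c in cuts] + [hi]
        # LIFO stack: push right-to-left so traversal (and rng use) is
        # left-to-right and deterministic
        for a, bnd in zip(pieces[-2::-1], pieces[:0:-1]):
            if bnd - a >= max(2 * mw, 4):
                stack.append((a, bnd))
    return sorted(changepoints)


def cbs_segment(profile: RatioProfile, params: CBSParams | None = None) -> SegmentSet:
    """Segment a ratio profile chromosome by chromosome.

    Deterministic given ``params.rng_seed`` (chromosomes are processed in
    fragment-map order with a single generator).  Degenerate chromosomes
    yield a single segment.
    """
    params = params or CBSParams()
    rng = np.random.default_rng(params.rng_seed)
    fmap = profile.fmap
    segset = SegmentSet(fmap)
    for chrom in fmap.chroms:
        v = profile.chrom_values(chrom)
        cps = _segment_vector(v, params, rng) if len(v) >= 4 else []
        bounds = [0] + cps + [len(v)]
        starts = fmap.starts[chrom]
        ends = fmap.ends[chrom]
        for a, b in zip(bounds[:-1], bounds[1:]):
            segset.segments.append(
                Segment(
                    chrom=chrom,
                    first=a,
                    last=b - 1,
                    start=int(starts[a]),
                    end=int(ends[b - 1]),
                    mean_value=float(np.mean(v[a:b])),
                    n_fragments=b - a,
                )
            )
    return segset
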