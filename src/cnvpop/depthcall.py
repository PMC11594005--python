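"""Per-sample CNV calling from binned read depth.

The caller consumes a :class:`DepthTrack` (integer read counts in fixed-width
bins, with per-bin GC fraction and mapping-quality-zero fraction) and produces
:class:`CnvCall` records in four diploid copy states: 0 (homozygous deletion),
1 (heterozygous deletion), 3 (single-copy gain) and 4 (two or more copies
gained).  The stages are

1. GC correction by median scaling within 1%-wide GC strata,
2. normalisation to a diploid mean of 1,
3. exact penalized least-squares changepoint segmentation (PELT),
4. copy-state assignment, per-segment significance and q0 aggregation,
5. hard filtering (p < 0.001, length > 1 kb, q0 < 0.5, placed chromosomes).

Internal coordinates are 0-based half-open throughout; conversion to 1-based
happens only in VCF output (see :mod:`cnvpop.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Sequence

import numpy as np
from numba import njit
from scipy import stats

__all__ = [
    "GenomeLayout",
    "DepthTrack",
    "Segment",
    "CnvCall",
    "gc_correct",
    "normalize",
    "segment",
    "call_states",
    "filter_calls",
    "call_sample",
    "MIN_P_VALUE",
    "MIN_LENGTH_BP",
    "MAX_Q0",
]

# Hard-filter thresholds; all inequalities are strict.
MIN_P_VALUE = 0.001
MIN_LENGTH_BP = 1000
MAX_Q0 = 0.5


@dataclass(frozen=True)
class GenomeLayout:
    """Ordered chromosome set with lengths and placed/unplaced status.

    Calls on unplaced scaffolds are removed by :func:`filter_calls`.
    """

    lengths: Mapping[str, int]
    placed: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, L in self.lengths.items():
            if L <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {L}")
        object.__setattr__(
            self,
            "placed",
            {name: self.placed.get(name, True) for name in self.lengths},
        )

    @property
    def chroms(self) -> List[str]:
        return list(self.lengths)

    def is_placed(self, chrom: str) -> bool:
        return bool(self.placed.get(chrom, False))

    def n_bins(self, chrom: str, bin_width: int) -> int:
        return -(-self.lengths[chrom] // bin_width)

    def total_placed_bp(self) -> int:
        return sum(L for c, L in self.lengths.items() if self.is_placed(c))


@dataclass
class DepthTrack:
    """Binned read depth for one sample.

    ``counts``, ``gc`` and ``q0`` map chromosome name to equal-length arrays;
    a trailing short bin covers any remainder of the chromosome.
    """

    sample: str
    bin_width: int
    counts: Dict[str, np.ndarray]
    gc: Dict[str, np.ndarray]
    q0: Dict[str, np.ndarray]

    def validate(self, layout: GenomeLayout) -> None:
        for chrom in self.counts:
            n = layout.n_bins(chrom, self.bin_width)
            for name, arrs in (("counts", self.counts), ("gc", self.gc), ("q0", self.q0)):
                if len(arrs[chrom]) != n:
                    raise ValueError(
                        f"{name}[{chrom}] has {len(arrs[chrom])} bins, expected {n}"
                    )


@dataclass(frozen=True)
class Segment:
    """A maximal constant-depth run of bins (0-based half-open bin units)."""

    chrom: str
    bin_start: int
    bin_end: int
    mean: float  # normalized depth; 1.0 == diploid

    def __post_init__(self) -> None:
        if self.bin_start >= self.bin_end:
            raise ValueError("segment must contain at least one bin")


@dataclass(frozen=True)
class CnvCall:
    """One per-sample copy-number event (bp coordinates, 0-based half-open)."""

    sample: str
    chrom: str
    start: int
    end: int
    copy_state: int
    d: float
    p_value: float
    q0_frac: float

    def __post_init__(self) -> None:
        if self.copy_state == 2:
            raise ValueError("copy state 2 is diploid, not a CNV")
        if self.copy_state not in (0, 1, 3, 4):
            raise ValueError(f"invalid copy state {self.copy_state}")
        if self.end <= self.start:
            raise ValueError("call end must exceed start")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def is_deletion(self) -> bool:
        return self.copy_state in (0, 1)


# ---------------------------------------------------------------------------
# GC correction and normalisation
# ---------------------------------------------------------------------------

def gc_correct(track: DepthTrack, min_stratum_bins: int = 100) -> DepthTrack:
    """Median-scale counts within 1%-wide GC strata (pooled over chromosomes).

    ``corrected = count * global_median / stratum_median``.  Strata with fewer
    than ``min_stratum_bins`` bins borrow the factor of the nearest populated
    stratum; strata whose median is zero are left uncorrected.
    """
    chroms = list(track.counts)
    all_counts = np.concatenate([track.counts[c] for c in chroms]).astype(float)
    if not np.any(all_counts > 0):
        raise ValueError("no coverage: track is all zero")
    all_gc = np.concatenate([track.gc[c] for c in chroms])

    strat = np.clip((all_gc * 100).astype(int), 0, 99)
    global_med = np.median(all_counts)
    factor = np.ones(100)
    populated = []
    for s in range(100):
        sel = strat == s
        if sel.sum() >= min_stratum_bins:
            med = np.median(all_counts[sel])
            if med > 0:
                factor[s] = global_med / med
            populated.append(s)
    if populated:
        pop = np.asarray(populated)
        for s in range(100):
            if s not in populated and np.any(strat == s):
                factor[s] = factor[pop[np.argmin(np.abs(pop - s))]]

    corrected = all_counts * factor[strat]
    out: Dict[str, np.ndarray] = {}
    off = 0
    for c in chroms:
        n = len(track.counts[c])
        out[c] = corrected[off : off + n]
        off += n
    return replace(track, counts=out)


def normalize(track: DepthTrack, layout: GenomeLayout | None = None) -> Dict[str, np.ndarray]:
    """Scale corrected counts so the autosomal (placed-chromosome) mean is 1."""
    chroms = list(track.counts)
    use = [c for c in chroms if layout is None or layout.is_placed(c)]
    if not use:
        raise ValueError("no placed chromosomes to normalize against")
    mean = float(np.concatenate([track.counts[c] for c in use]).mean())
    if mean == 0:
        raise ValueError("autosomal mean depth is zero")
    return {c: np.asarray(track.counts[c], dtype=float) / mean for c in chroms}


# ---------------------------------------------------------------------------
# Segmentation: exact penalized least-squares changepoints
# ---------------------------------------------------------------------------

@njit(cache=False)
def _pelt_core(x: np.ndarray, beta: float) -> np.ndarray:  # pragma: no cover - jitted
    B = x.shape[0]
    S1 = np.zeros(B + 1)
    S2 = np.zeros(B + 1)
    for i in range(B):
        S1[i + 1] = S1[i] + x[i]
        S2[i + 1] = S2[i] + x[i] * x[i]
    F = np.empty(B + 1)
    F[0] = -beta
    prev = np.zeros(B + 1, dtype=np.int64)
    cand = np.empty(B + 1, dtype=np.int64)
    cand[0] = 0
    ncand = 1
    for t in range(1, B + 1):
        best = np.inf
        bestc = 0
        for i in range(ncand):
            c = cand[i]
            n = t - c
            sse = (S2[t] - S2[c]) - (S1[t] - S1[c]) ** 2 / n
            tot = F[c] + sse + beta
            if tot < best:
                best = tot
                bestc = c
        F[t] = best
        prev[t] = bestc
        # PELT pruning: for SSE cost, K = 0 is a valid pruning constant.
        m = 0
        for i in range(ncand):
            c = cand[i]
            n = t - c
            sse = (S2[t] - S2[c]) - (S1[t] - S1[c]) ** 2 / n
            if F[c] + sse <= best:
                cand[m] = c
                m += 1
        cand[m] = t
        ncand = m + 1
    return prev


def mad_variance(x: np.ndarray) -> float:
    """Robust variance estimate: squared scaled median absolute deviation."""
    mad = np.median(np.abs(x - np.median(x)))
    return float((1.4826 * mad) ** 2)


def segment(
    x: np.ndarray,
    chrom: str = "",
    lam: float = 2.0,
    sigma2: float | None = None,
) -> List[Segment]:
    """Optimal partition of ``x`` minimising SSE + beta * (#segments).

    ``beta = lam * sigma2 * log(B)`` with ``sigma2`` estimated by the
    MAD-based robust variance when not supplied.  The search (PELT) returns
    the exact optimum of penalized least squares; ties are resolved toward
    fewer segments.
    """
    x = np.asarray(x, dtype=float)
    B = len(x)
    if B == 0:
        raise ValueError("empty signal")
    if B == 1:
        return [Segment(chrom, 0, 1, float(x[0]))]
    if sigma2 is None:
        sigma2 = mad_variance(x)
    beta = lam * sigma2 * math.log(B)
    prev = _pelt_core(x, beta)
    bounds = []
    t = B
    while t > 0:
        bounds.append(t)
        t = int(prev[t])
    bounds.append(0)
    bounds = bounds[::-1]
    return [
        Segment(chrom, s, e, float(x[s:e].mean()))
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


def segmentation_cost(x: np.ndarray, breaks: Sequence[int], beta: float) -> float:
    """Cost of a given partition (interior breakpoints) -- test utility."""
    x = np.asarray(x, dtype=float)
    bounds = [0, *sorted(breaks), len(x)]
    cost = 0.0
    for s, e in zip(bounds[:-1], bounds[1:]):
        seg = x[s:e]
        cost += float(((seg - seg.mean()) ** 2).sum()) + beta
    return cost


# ---------------------------------------------------------------------------
# Copy-state calling
# ---------------------------------------------------------------------------

def _round_half_away(v: float) -> int:
    return int(math.floor(v + 0.5)) if v >= 0 else -int(math.floor(-v + 0.5))


def _copy_state(d: float) -> int:
    return max(0, min(_round_half_away(2.0 * d), 4))


def _segment_p_value(xs: np.ndarray) -> float:
    """Two-sided one-sample t-test of segment bins against diploid mean 1.

    Single-bin segments are conservatively assigned p = 1.  A zero-variance
    segment (e.g. an all-zero homozygous deletion) has an unbounded t
    statistic: p = 0 when its mean differs from 1, else 1.
    """
    if len(xs) < 2:
        return 1.0
    if float(np.var(xs)) == 0.0:
        return 0.0 if xs[0] != 1.0 else 1.0
    return float(stats.ttest_1samp(xs, 1.0).pvalue)


def call_states(
    segments: Iterable[Segment],
    track: DepthTrack,
    x: Mapping[str, np.ndarray],
    layout: GenomeLayout,
) -> List[CnvCall]:
    """Turn segments into CNV calls: copy = min(round(2d), 4), diploid dropped.

    Adjacent same-state segments are merged before testing; q0 is the
    count-weighted mean of bin q0 over the (merged) segment.
    """
    w = track.bin_width
    by_chrom: Dict[str, List[Segment]] = {}
    for seg in segments:
        by_chrom.setdefault(seg.chrom, []).append(seg)

    calls: List[CnvCall] = []
    for chrom, segs in by_chrom.items():
        segs = sorted(segs, key=lambda s: s.bin_start)
        # merge runs of adjacent segments sharing a non-diploid copy state
        runs: List[List[int]] = []
        for i, seg in enumerate(segs):
            state = _copy_state(seg.mean)
            if state == 2:
                runs.append([])
                continue
            if (
                runs
                and runs[-1]
                and _copy_state(segs[runs[-1][-1]].mean) == state
                and segs[runs[-1][-1]].bin_end == seg.bin_start
            ):
                runs[-1].append(i)
            else:
                runs.append([i])
        for run in runs:
            if not run:
                continue
            b0 = segs[run[0]].bin_start
            b1 = segs[run[-1]].bin_end
            xs = np.asarray(x[chrom][b0:b1], dtype=float)
            d = float(xs.mean())
            state = _copy_state(d)
            if state == 2:  # merged mean may round back to diploid
                continue
            counts = np.asarray(track.counts[chrom][b0:b1], dtype=float)
            q0s = np.asarray(track.q0[chrom][b0:b1], dtype=float)
            q0 = float(np.average(q0s, weights=counts)) if counts.sum() > 0 else float(q0s.mean())
            calls.append(
                CnvCall(
                    sample=track.sample,
                    chrom=chrom,
                    start=b0 * w,
                    end=min(b1 * w, layout.lengths[chrom]),
                    copy_state=state,
                    d=d,
                    p_value=_segment_p_value(xs),
                    q0_frac=q0,
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.start))
    return calls


def filter_calls(calls: Iterable[CnvCall], layout: GenomeLayout) -> List[CnvCall]:
    """Keep calls with p < 0.001, length > 1 kb, q0 < 0.5 on placed chromosomes.

    All inequalities are strict; a 1000 bp call or a call with q0 exactly 0.5
    is removed.  Input order is preserved (the filter is a pure conjunction).
    """
    return [
        c
        for c in calls
        if c.p_value < MIN_P_VALUE
        and c.length > MIN_LENGTH_BP
        and c.q0_frac < MAX_Q0
        and layout.is_placed(c.chrom)
    ]


def call_sample(
    track: DepthTrack,
    layout: GenomeLayout,
    lam: float = 2.0,
    apply_filters: bool = True,
) -> List[CnvCall]:
    """Full per-sample pipeline: GC-correct, normalize, segment, call, filter.

    Changepoints are located on the square-root scale (a variance-stabilizing
    transform for near-Poisson counts, which sharpens deletion breakpoints);
    segment means, copy states and significance are computed on the natural
    normalized-depth scale.
    """
    corrected = gc_correct(track)
    x = normalize(corrected, layout)
    segs: List[Segment] = []
    for chrom, xc in x.items():
        for s in segment(np.sqrt(xc), chrom=chrom, lam=lam):
            segs.append(Segment(chrom, s.bin_start, s.bin_end, float(xc[s.bin_start : s.bin_end].mean())))
    calls = call_states(segs, track, x, layout)
    return filter_calls(calls, layout) if apply_filters else calls
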