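"""CNVR construction: merge per-sample CNV calls into population regions.

A CNVR is the union span of a transitive-closure cluster of calls overlapping
by at least 1 bp.  Merging happens per breed first, regions carried by fewer
than ``min_carriers`` individuals (default 4, i.e. 13.3% of a 30-animal
cohort) are dropped, and the surviving per-breed regions are merged across
breeds into the final locus set.  Every individual is then genotyped at every
CNVR (no overlapping call = diploid state 2), and summary statistics (type and
length distributions, deleted/duplicated sequence proportions, genome
coverage) are computed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .depthcall import CnvCall, GenomeLayout

__all__ = [
    "Cnvr",
    "CnvrGenotypes",
    "CnvrSummary",
    "merge_cnvrs",
    "merge_across_breeds",
    "genotype_cnvrs",
    "summarize",
    "carrier_frequency_pct",
    "frequency_min_carriers",
]

DEFAULT_MIN_CARRIERS = 4


@dataclass
class Cnvr:
    """A population-level merged copy-number region (0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    type: str  # gain | loss | mixed
    carriers: Dict[str, Set[str]]  # breed -> sample ids

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("CNVR end must exceed start")
        if self.type not in ("gain", "loss", "mixed"):
            raise ValueError(f"invalid CNVR type {self.type!r}")

    @property
    def carrier_count(self) -> int:
        return sum(len(s) for s in self.carriers.values())

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Cnvr") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class CnvrGenotypes:
    """Individuals x CNVR copy-state matrix; non-carriers are diploid (2)."""

    sample_ids: List[str]
    breed_labels: List[str]
    cnvrs: List[Cnvr]
    states: np.ndarray  # (N, M) int, values in {0..4}

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.states,
            index=self.sample_ids,
            columns=[c.id for c in self.cnvrs],
        )


@dataclass
class CnvrSummary:
    """Descriptive statistics over calls and CNVRs."""

    n_calls: int
    n_cnvrs: int
    counts_by_chrom: Dict[str, int]
    counts_by_type: Dict[str, int]
    counts_by_length_bin: Dict[str, int]
    mean_length_by_state: Dict[int, float]
    mean_call_length: float
    deletion_bp_proportion: float
    duplication_bp_proportion: float
    genome_coverage: float

    def to_dict(self) -> dict:
        return {
            "n_calls": self.n_calls,
            "n_cnvrs": self.n_cnvrs,
            "counts_by_chrom": self.counts_by_chrom,
            "counts_by_type": self.counts_by_type,
            "counts_by_length_bin": self.counts_by_length_bin,
            "mean_length_by_state": {str(k): v for k, v in self.mean_length_by_state.items()},
            "mean_call_length": self.mean_call_length,
            "deletion_bp_proportion": self.deletion_bp_proportion,
            "duplication_bp_proportion": self.duplication_bp_proportion,
            "genome_coverage": self.genome_coverage,
        }


def _chrom_key(chrom: str) -> Tuple:
    """Natural sort: chr2 before chr10."""
    digits = "".join(ch for ch in chrom if ch.isdigit())
    return (chrom.rstrip("0123456789"), int(digits) if digits else -1)


def _cluster_type(states: Iterable[int]) -> str:
    s = set(states)
    if s <= {0, 1}:
        return "loss"
    if s <= {3, 4}:
        return "gain"
    return "mixed"


def _merge_type(types: Iterable[str]) -> str:
    t = set(types)
    if "mixed" in t or ("loss" in t and "gain" in t):
        return "mixed"
    return next(iter(t))


def carrier_frequency_pct(min_carriers: int, cohort_size: int) -> float:
    """The carrier-frequency threshold implied by a minimum-carrier count."""
    return 100.0 * min_carriers / cohort_size


def frequency_min_carriers(freq: float, cohort_size: int) -> int:
    """Alternative frequency mode: smallest carrier count reaching ``freq``."""
    return math.ceil(freq * cohort_size)


def merge_cnvrs(
    calls: Sequence[CnvCall],
    min_carriers: int = DEFAULT_MIN_CARRIERS,
    breed: str = "pop",
) -> List[Cnvr]:
    """Merge one breed's calls into CNVRs (>=1 bp transitive overlap).

    The CNVR span is the union of its constituent calls; the type is loss if
    all states are deletions, gain if all are duplications, mixed otherwise.
    Regions carried by fewer than ``min_carriers`` distinct individuals are
    dropped.  An empty call set yields an empty region set.
    """
    if min_carriers < 1:
        raise ValueError("min_carriers must be >= 1")
    ordered = sorted(calls, key=lambda c: (_chrom_key(c.chrom), c.start, c.end))
    out: List[Cnvr] = []
    cluster: List[CnvCall] = []

    def flush() -> None:
        if not cluster:
            return
        samples = {c.sample for c in cluster}
        if len(samples) >= min_carriers:
            out.append(
                Cnvr(
                    id="",
                    chrom=cluster[0].chrom,
                    start=min(c.start for c in cluster),
                    end=max(c.end for c in cluster),
                    type=_cluster_type(c.copy_state for c in cluster),
                    carriers={breed: samples},
                )
            )

    cur_end = -1
    for call in ordered:
        if cluster and (call.chrom != cluster[0].chrom or call.start >= cur_end):
            flush()
            cluster = []
        cluster.append(call)
        cur_end = max(cur_end, call.end) if len(cluster) > 1 else call.end
    flush()

    for i, r in enumerate(out):
        r.id = f"{breed}_cnvr_{i:05d}"
    return out


def merge_across_breeds(per_breed: Mapping[str, Sequence[Cnvr]]) -> List[Cnvr]:
    """Union-merge per-breed CNVR sets into the final cross-breed locus set.

    Overlap (>=1 bp) closure again defines each merged region; carriers are
    aggregated per breed; ids are deterministic in (chrom, start) order.
    """
    regions: List[Cnvr] = [r for rs in per_breed.values() for r in rs]
    regions.sort(key=lambda r: (_chrom_key(r.chrom), r.start, r.end))
    out: List[Cnvr] = []
    cluster: List[Cnvr] = []

    def flush() -> None:
        if not cluster:
            return
        carriers: Dict[str, Set[str]] = {}
        for r in cluster:
            for b, s in r.carriers.items():
                carriers.setdefault(b, set()).update(s)
        out.append(
            Cnvr(
                id="",
                chrom=cluster[0].chrom,
                start=min(r.start for r in cluster),
                end=max(r.end for r in cluster),
                type=_merge_type(r.type for r in cluster),
                carriers=carriers,
            )
        )

    cur_end = -1
    for r in regions:
        if cluster and (r.chrom != cluster[0].chrom or r.start >= cur_end):
            flush()
            cluster = []
        cluster.append(r)
        cur_end = max(cur_end, r.end) if len(cluster) > 1 else r.end
    flush()

    for i, r in enumerate(out):
        r.id = f"cnvr_{i:05d}"
    return out


def genotype_cnvrs(
    cnvrs: Sequence[Cnvr],
    calls: Sequence[CnvCall],
    sample_ids: Sequence[str],
    breed_labels: Sequence[str],
) -> CnvrGenotypes:
    """Copy state of every individual at every CNVR.

    An individual's state is that of its largest-overlap call at the region
    (ties: earlier call start); a call overlapping several CNVRs counts only
    toward its largest-overlap region; individuals with no overlapping call
    are diploid (state 2).
    """
    order = sorted(range(len(cnvrs)), key=lambda i: (_chrom_key(cnvrs[i].chrom), cnvrs[i].start))
    states = np.full((len(sample_ids), len(cnvrs)), 2, dtype=np.int8)
    sample_idx = {s: i for i, s in enumerate(sample_ids)}

    # best (overlap, -start) call per (sample, cnvr)
    best: Dict[Tuple[int, int], Tuple[int, int, int]] = {}
    for call in calls:
        if call.sample not in sample_idx:
            continue
        # assign the call to its largest-overlap CNVR
        cand: List[Tuple[int, int, int]] = []  # (overlap, cnvr_start, cnvr_idx)
        for j in order:
            r = cnvrs[j]
            if r.chrom != call.chrom:
                continue
            ov = min(call.end, r.end) - max(call.start, r.start)
            if ov > 0:
                cand.append((ov, r.start, j))
        if not cand:
            continue
        cand.sort(key=lambda t: (-t[0], t[1]))
        j = cand[0][2]
        ov = cand[0][0]
        key = (sample_idx[call.sample], j)
        prev = best.get(key)
        if prev is None or (ov, -call.start) > (prev[0], -prev[1]):
            best[key] = (ov, call.start, call.copy_state)

    for (i, j), (_, _, state) in best.items():
        states[i, j] = state
    return CnvrGenotypes(
        sample_ids=list(sample_ids),
        breed_labels=list(breed_labels),
        cnvrs=list(cnvrs),
        states=states,
    )


def summarize(
    calls: Sequence[CnvCall],
    cnvrs: Sequence[Cnvr],
    layout: GenomeLayout,
    length_bins: Tuple[int, ...] = (20_000, 500_000),
) -> CnvrSummary:
    """Descriptive statistics: counts, length bins, bp proportions, coverage."""
    lo, hi = length_bins
    by_chrom: Dict[str, int] = {}
    by_type = {"loss": 0, "gain": 0, "mixed": 0}
    for r in cnvrs:
        by_chrom[r.chrom] = by_chrom.get(r.chrom, 0) + 1
        by_type[r.type] += 1
    by_len = {f"<={lo // 1000}kb": 0, f"{lo // 1000}-{hi // 1000}kb": 0, f">{hi // 1000}kb": 0}
    for c in calls:
        if c.length <= lo:
            by_len[f"<={lo // 1000}kb"] += 1
        elif c.length <= hi:
            by_len[f"{lo // 1000}-{hi // 1000}kb"] += 1
        else:
            by_len[f">{hi // 1000}kb"] += 1

    mean_by_state: Dict[int, float] = {}
    for state in (0, 1, 3, 4):
        lens = [c.length for c in calls if c.copy_state == state]
        if lens:
            mean_by_state[state] = float(np.mean(lens))

    del_bp = sum(c.length for c in calls if c.is_deletion)
    dup_bp = sum(c.length for c in calls if not c.is_deletion)
    tot_bp = del_bp + dup_bp

    covered = 0
    by_chrom_regions: Dict[str, List[Tuple[int, int]]] = {}
    for r in cnvrs:
        by_chrom_regions.setdefault(r.chrom, []).append((r.start, r.end))
    for chrom, spans in by_chrom_regions.items():
        spans.sort()
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s > cur_e:
                covered += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        covered += cur_e - cur_s

    genome_bp = sum(layout.lengths.values())
    return CnvrSummary(
        n_calls=len(calls),
        n_cnvrs=len(cnvrs),
        counts_by_chrom=dict(sorted(by_chrom.items(), key=lambda kv: _chrom_key(kv[0]))),
        counts_by_type=by_type,
        counts_by_length_bin=by_len,
        mean_length_by_state=mean_by_state,
        mean_call_length=float(np.mean([c.length for c in calls])) if calls else 0.0,
        deletion_bp_proportion=del_bp / tot_bp if tot_bp else 0.0,
        duplication_bp_proportion=dup_bp / tot_bp if tot_bp else 0.0,
        genome_coverage=covered / genome_bp if genome_bp else 0.0,
    )
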