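"""Weir-Cockerham F_ST between two population groups and top-1% scanning.

Per biallelic locus, the moment estimator decomposes variance into
among-population (a), among-individual-within-population (b) and
within-individual (c) components from per-group sample sizes ``n_i``,
variant-allele frequencies ``p_i`` and observed heterozygote proportions
``h_i`` (r = 2 groups):

    nbar = sum n_i / r
    n_c  = (r nbar - sum n_i^2 / (r nbar)) / (r - 1)
    pbar = sum n_i p_i / (r nbar)
    s2   = sum n_i (p_i - pbar)^2 / ((r - 1) nbar)
    hbar = sum n_i h_i / (r nbar)
    a = (nbar/n_c) [s2 - (pbar(1-pbar) - s2 (r-1)/r - hbar/4) / (nbar - 1)]
    b = (nbar/(nbar-1)) [pbar(1-pbar) - s2 (r-1)/r - hbar (2 nbar - 1)/(4 nbar)]
    c = hbar / 2

The per-locus estimate is ``a / (a + b + c)``; the multi-locus "weighted"
value is the ratio of sums ``sum a / sum (a+b+c)``.  Loci monomorphic in both
groups (or with a group of fewer than two individuals) are undefined and are
excluded from ranking.  Loci with F_ST at or above the empirical 99th
percentile (linear-interpolation quantile, ties included) form the selected
set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "FstLocus",
    "SelectionResult",
    "wc_fst_locus",
    "wc_fst_components",
    "weighted_fst",
    "select_top",
    "candidates",
]


@dataclass(frozen=True)
class FstLocus:
    """Variance components and F_ST estimate at one locus."""

    locus_id: str
    n: Tuple[int, int]
    p: Tuple[float, float]
    h: Tuple[float, float]
    a: float
    b: float
    c: float
    fst: float  # nan when undefined
    defined: bool


@dataclass
class SelectionResult:
    """Ranked per-locus table with the top-quantile threshold tau."""

    table: pd.DataFrame  # locus_id, a, b, c, fst, defined, rank, selected
    tau: float
    quantile: float
    weighted_fst: float

    @property
    def selected_ids(self) -> List[str]:
        return list(self.table.loc[self.table["selected"], "locus_id"])


def _components_from_stats(
    n: np.ndarray, p: np.ndarray, h: np.ndarray
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised a, b, c over loci; inputs shaped (2, L)."""
    r = 2.0
    n = n.astype(float)
    nbar = n.sum(axis=0) / r
    nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1)
    pbar = (n * p).sum(axis=0) / (r * nbar)
    s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
    hbar = (n * h).sum(axis=0) / (r * nbar)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - s2 * (r - 1) / r - hbar * (2 * nbar - 1) / (4 * nbar)
        )
    c = hbar / 2
    return a, b, c


def wc_fst_locus(
    dosages: np.ndarray, groups: np.ndarray, locus_id: str = ""
) -> FstLocus:
    """Estimate the variance components at one locus from dosage data.

    ``dosages`` holds variant-allele counts in {0,1,2} per individual;
    ``groups`` assigns each individual to group 0 or 1.  A group with fewer
    than two individuals, or a locus with ``a + b + c == 0`` (monomorphic in
    both groups), is flagged undefined; components are still returned.
    """
    dosages = np.asarray(dosages)
    groups = np.asarray(groups)
    if set(np.unique(groups)) - {0, 1}:
        raise ValueError("groups must be coded 0/1")
    g0, g1 = dosages[groups == 0], dosages[groups == 1]
    n = np.array([[len(g0)], [len(g1)]])
    if len(g0) < 2 or len(g1) < 2:
        p0 = g0.mean() / 2 if len(g0) else np.nan
        p1 = g1.mean() / 2 if len(g1) else np.nan
        return FstLocus(
            locus_id, (len(g0), len(g1)), (p0, p1), (np.nan, np.nan),
            0.0, 0.0, 0.0, np.nan, False,
        )
    p = np.array([[g0.mean() / 2], [g1.mean() / 2]])
    h = np.array([[(g0 == 1).mean()], [(g1 == 1).mean()]])
    a, b, c = _components_from_stats(n, p, h)
    a, b, c = float(a[0]), float(b[0]), float(c[0])
    tot = a + b + c
    defined = tot != 0.0
    return FstLocus(
        locus_id,
        (len(g0), len(g1)),
        (float(p[0, 0]), float(p[1, 0])),
        (float(h[0, 0]), float(h[1, 0])),
        a,
        b,
        c,
        a / tot if defined else np.nan,
        defined,
    )


def wc_fst_components(
    dosage_matrix: np.ndarray,
    groups: np.ndarray,
    locus_ids: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Per-locus components for a whole (N, L) dosage matrix at once."""
    G = np.asarray(dosage_matrix)
    groups = np.asarray(groups)
    g0, g1 = G[groups == 0], G[groups == 1]
    L = G.shape[1]
    if locus_ids is None:
        locus_ids = [f"locus_{j}" for j in range(L)]
    if len(g0) < 2 or len(g1) < 2:
        return pd.DataFrame(
            dict(locus_id=locus_ids, a=0.0, b=0.0, c=0.0, fst=np.nan, defined=False)
        )
    n = np.array([[len(g0)] * L, [len(g1)] * L])
    p = np.vstack([g0.mean(axis=0) / 2, g1.mean(axis=0) / 2])
    h = np.vstack([(g0 == 1).mean(axis=0), (g1 == 1).mean(axis=0)])
    a, b, c = _components_from_stats(n, p, h)
    tot = a + b + c
    defined = tot != 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(defined, a / np.where(defined, tot, 1.0), np.nan)
    return pd.DataFrame(
        dict(locus_id=list(locus_ids), a=a, b=b, c=c, fst=fst, defined=defined)
    )


def weighted_fst(table: pd.DataFrame) -> float:
    """Multi-locus ratio of sums over defined loci: sum a / sum (a+b+c)."""
    t = table[table["defined"]]
    if t.empty:
        raise ValueError("no defined loci")
    denom = (t["a"] + t["b"] + t["c"]).sum()
    if denom == 0:
        raise ValueError("zero total variance")
    return float(t["a"].sum() / denom)


def select_top(table: pd.DataFrame, quantile: float = 0.99) -> SelectionResult:
    """Flag loci with F_ST >= the empirical ``quantile`` threshold (tau).

    The threshold is the linear-interpolation (type-7) quantile of defined
    per-locus values; ties at tau are included; negative estimates are kept
    in the ranking, not clamped.
    """
    t = table.copy()
    defined = t["defined"].to_numpy()
    n_def = int(defined.sum())
    if n_def == 0:
        raise ValueError("no defined loci to rank")
    if n_def < 100:
        warnings.warn(
            f"only {n_def} defined loci; the top-{100 * (1 - quantile):g}% "
            "threshold is unstable",
            stacklevel=2,
        )
    vals = t.loc[defined, "fst"].to_numpy()
    tau = float(np.quantile(vals, quantile))
    t["rank"] = t["fst"].rank(ascending=False, method="min")
    t["selected"] = defined & (t["fst"].to_numpy() >= tau)
    return SelectionResult(
        table=t, tau=tau, quantile=quantile, weighted_fst=weighted_fst(table)
    )


def candidates(
    selected_cnvr_ids: Sequence[str],
    annotated: Mapping[str, Sequence[str]],
) -> List[str]:
    """Unique sorted genes overlapped by selected CNVRs.

    ``annotated`` maps CNVR id to the gene ids it overlaps (>=1 bp), as
    produced by the annotation stage.
    """
    genes: set = set()
    for cid in selected_cnvr_ids:
        genes.update(annotated.get(cid, ()))
    return sorted(genes)
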