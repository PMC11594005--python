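"""Synthetic CNV cohorts with saved truth.

Generates everything the downstream pipeline consumes: a genome layout, a set
of non-overlapping biallelic CNV loci (each carrying a loss or a gain allele),
population-differentiated allele frequencies under the Balding-Nichols model,
admixed diploid copy-number genotypes, per-sample binned depth tracks with GC
bias and mapping-quality-zero (q0) artifacts, gene models, and gene-set
tables.  The planted truth (:class:`TruthSet`) is the oracle for every
parameter-recovery test downstream.

Population differentiation
--------------------------
Background loci: per-population frequencies ``p_k ~ Beta(p0(1-F)/F,
(1-p0)(1-F)/F)`` around an ancestral ``p0 ~ U(0.05, 0.95)``, so the expected
multi-locus Weir-Cockerham F_ST equals ``F_bg``.

Selected loci emulate divergent selection: the variant allele is swept toward
fixation in one population group and against it in the other.  Frequencies are
drawn tightly (Beta with concentration ``sel_concentration``) around opposite
means ``(1 +/- delta)/2`` with ``delta = sqrt(F_sel)``, which yields per-locus
F_ST close to ``F_sel`` at every planted locus.  Independent high-drift draws
would instead fix the same allele in both populations about half the time,
leaving many "selected" loci undifferentiated; the divergent scheme is what
makes a planted selection signature detectable by construction.

All randomness flows from a single ``numpy.random.default_rng(seed)`` in a
fixed order (frequencies, genotypes, gene models, gene sets, depth), so an
identical :class:`SimConfig` reproduces byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .depthcall import DepthTrack, GenomeLayout

__all__ = [
    "SimConfig",
    "TruthSet",
    "GeneSet",
    "SimResult",
    "simulate_freqs",
    "simulate_genotypes",
    "simulate_depth",
    "simulate_gene_models",
    "simulate_cohort",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults model a desk-scale version of a two-breed resequencing cohort:
    two populations, 200 bp depth bins at 10x mean per-bin depth, CNV loci of
    5-100 kb (log-uniform; the field reports multi-kb CNVs with mean ~42 kb),
    deletions at 80% of loci, background drift F_bg and a 1% minority of
    strongly differentiated selected loci at F_sel.
    """

    seed: int = 0
    n_pops: int = 2
    pop_sizes: Tuple[int, ...] = (15, 15)
    n_loci: int = 100
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr1": 1_000_000, "chr2": 1_000_000}
    )
    bin_width: int = 200
    mean_depth_per_bin: float = 10.0
    F_bg: float = 0.1
    F_sel: float = 0.8
    frac_selected: float = 0.01
    frac_loss_loci: float = 0.8
    admix_alpha: float = 0.0
    n_genes: int = 40
    gc_amp: float = 0.1
    overdispersion: float = 0.0
    min_locus_len: int = 5_000
    max_locus_len: int = 100_000
    repeat_frac: float = 0.01
    sel_concentration: float = 200.0
    unplaced_chroms: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.pop_sizes) != self.n_pops:
            raise ValueError("pop_sizes must have one entry per population")
        if any(s < 1 for s in self.pop_sizes):
            raise ValueError("every population needs at least one individual")
        if not (0.0 < self.F_bg < 1.0):
            raise ValueError(f"F_bg must lie in (0,1), got {self.F_bg}")
        if not (0.0 < self.F_sel <= 1.0):
            raise ValueError(f"F_sel must lie in (0,1], got {self.F_sel}")
        if not (0.0 <= self.frac_selected <= 1.0):
            raise ValueError("frac_selected must lie in [0,1]")
        if not (0.0 <= self.frac_loss_loci <= 1.0):
            raise ValueError("frac_loss_loci must lie in [0,1]")
        if not (0.0 <= self.gc_amp < 1.0):
            raise ValueError("gc_amp must lie in [0,1)")
        if self.bin_width < 1 or self.mean_depth_per_bin <= 0:
            raise ValueError("bin_width and mean_depth_per_bin must be positive")

    @property
    def n_individuals(self) -> int:
        return int(sum(self.pop_sizes))

    def layout(self) -> GenomeLayout:
        return GenomeLayout(
            lengths=dict(self.chrom_lengths),
            placed={c: c not in self.unplaced_chroms for c in self.chrom_lengths},
        )

    def breed_names(self) -> List[str]:
        return [f"pop{k + 1}" for k in range(self.n_pops)]

    def sample_ids(self) -> List[str]:
        ids = []
        for k, size in enumerate(self.pop_sizes):
            ids.extend(f"pop{k + 1}_s{i + 1}" for i in range(size))
        return ids


@dataclass
class TruthSet:
    """Planted truth: locus table, genotypes, ancestry and breed labels."""

    locus_table: pd.DataFrame
    genotypes: Optional[np.ndarray] = None  # (N, L) copy states in {0..4}
    Q_true: Optional[np.ndarray] = None  # (N, K) rows sum to 1
    breed_labels: Optional[List[str]] = None
    sample_ids: Optional[List[str]] = None

    def validate(self) -> None:
        lt = self.locus_table
        assert set(lt["allele_type"]) <= {"loss", "gain"}
        assert ((lt.filter(like="p_pop") >= 0) & (lt.filter(like="p_pop") <= 1)).all().all()
        if self.Q_true is not None:
            np.testing.assert_allclose(self.Q_true.sum(axis=1), 1.0, atol=1e-12)
        if self.genotypes is not None:
            loss = (lt["allele_type"] == "loss").to_numpy()
            g = self.genotypes
            assert np.all((g[:, loss] >= 0) & (g[:, loss] <= 2))
            assert np.all((g[:, ~loss] >= 2) & (g[:, ~loss] <= 4))


@dataclass
class GeneSet:
    """A term -> gene map with a namespace tag (GMT-style)."""

    term: str
    namespace: str
    genes: Tuple[str, ...]


@dataclass
class SimResult:
    """One fully simulated cohort."""

    config: SimConfig
    layout: GenomeLayout
    truth: TruthSet
    tracks: Dict[str, DepthTrack]
    genes: pd.DataFrame
    gene_sets: List[GeneSet]


# ---------------------------------------------------------------------------
# locus placement
# ---------------------------------------------------------------------------

def _place_intervals(
    rng: np.random.Generator,
    chrom_lengths: Mapping[str, int],
    n: int,
    min_len: int,
    max_len: int,
    what: str,
) -> pd.DataFrame:
    """Place n non-overlapping intervals with log-uniform lengths.

    Intervals are allocated to chromosomes proportionally to length, then
    positioned by distributing the free space uniformly (sorted uniform cuts),
    which guarantees no overlap without rejection sampling.
    """
    chroms = list(chrom_lengths)
    sizes = np.array([chrom_lengths[c] for c in chroms], dtype=float)
    alloc = np.floor(n * sizes / sizes.sum()).astype(int)
    for i in np.argsort(-sizes):
        if alloc.sum() >= n:
            break
        alloc[i] += n - alloc.sum()
    rows = []
    for c, nc in zip(chroms, alloc):
        if nc == 0:
            continue
        lens = np.exp(
            rng.uniform(math.log(min_len), math.log(max_len), size=nc)
        ).astype(int)
        free = chrom_lengths[c] - int(lens.sum())
        if free < 0:
            raise ValueError(
                f"genome too small: cannot place {nc} {what} on {c} "
                f"({lens.sum()} bp needed, {chrom_lengths[c]} available)"
            )
        cuts = np.sort(rng.uniform(0, free, size=nc)).astype(int)
        starts = cuts + np.concatenate([[0], np.cumsum(lens[:-1])])
        for s, L in zip(starts, lens):
            rows.append({"chrom": c, "start": int(s), "end": int(s + L)})
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"], ignore_index=True)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def simulate_freqs(cfg: SimConfig, rng: Optional[np.random.Generator] = None) -> TruthSet:
    """Plant loci and per-population allele frequencies (locus table only)."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    L = cfg.n_loci
    df = _place_intervals(
        rng, cfg.chrom_lengths, L, cfg.min_locus_len, cfg.max_locus_len, "CNV loci"
    )
    p0 = rng.uniform(0.05, 0.95, size=L)
    n_sel = math.ceil(cfg.frac_selected * L)
    selected = np.zeros(L, dtype=bool)
    if n_sel > 0:
        selected[rng.choice(L, size=n_sel, replace=False)] = True

    K = cfg.n_pops
    F = cfg.F_bg
    pk = rng.beta(p0 * (1 - F) / F, (1 - p0) * (1 - F) / F, size=(K, L))

    # Divergent selection at planted loci: one population group sweeps the
    # variant allele up, the rest down, around means (1 +/- delta)/2.
    delta = math.sqrt(cfg.F_sel)
    kappa = cfg.sel_concentration
    hi_mean = min(0.5 + delta / 2, 1 - 1 / kappa)
    lo_mean = max(0.5 - delta / 2, 1 / kappa)
    for l in np.flatnonzero(selected):
        hi_pop = int(rng.integers(K))
        p0[l] = 0.5
        for k in range(K):
            m = hi_mean if k == hi_pop else lo_mean
            pk[k, l] = rng.beta(m * kappa, (1 - m) * kappa)

    df["allele_type"] = np.where(
        rng.random(L) < cfg.frac_loss_loci, "loss", "gain"
    )
    df["p0"] = p0
    df["selected"] = selected
    for k in range(K):
        df[f"p_pop{k + 1}"] = pk[k]
    df.insert(0, "locus_id", [f"locus_{i:05d}" for i in range(L)])
    return TruthSet(locus_table=df)


def simulate_genotypes(
    truth: TruthSet, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> TruthSet:
    """Draw ancestry and diploid copy-number genotypes for every individual.

    With ``admix_alpha == 0`` individuals are unadmixed (one-hot Q by breed);
    otherwise ``Q ~ Dirichlet(admix_alpha * 1)``.  The variant-allele count is
    ``x ~ Binomial(2, pi)`` with ``pi = sum_k Q_k p_k``; the copy state is
    ``2 - x`` at loss loci and ``2 + x`` at gain loci.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    lt = truth.locus_table
    K, N, L = cfg.n_pops, cfg.n_individuals, len(lt)
    pk = lt[[f"p_pop{k + 1}" for k in range(K)]].to_numpy().T  # (K, L)

    breeds = []
    for k, size in enumerate(cfg.pop_sizes):
        breeds.extend([f"pop{k + 1}"] * size)
    if cfg.admix_alpha == 0:
        Q = np.zeros((N, K))
        for i, b in enumerate(breeds):
            Q[i, int(b[3:]) - 1] = 1.0
    else:
        Q = rng.dirichlet(np.full(K, cfg.admix_alpha), size=N)

    pi = Q @ pk  # (N, L)
    x = rng.binomial(2, pi)
    loss = (lt["allele_type"] == "loss").to_numpy()
    geno = np.where(loss[None, :], 2 - x, 2 + x).astype(np.int8)

    truth.genotypes = geno
    truth.Q_true = Q
    truth.breed_labels = breeds
    truth.sample_ids = cfg.sample_ids()
    return truth


def _gc_tracks(cfg: SimConfig) -> Dict[str, np.ndarray]:
    """Smooth per-bin GC fraction in [0.3, 0.7] (a genome property)."""
    out = {}
    for chrom, length in cfg.chrom_lengths.items():
        n = -(-length // cfg.bin_width)
        b = np.arange(n)
        out[chrom] = 0.5 + 0.2 * np.sin(2 * np.pi * b / 523.0)
    return out


def _repeat_masks(
    cfg: SimConfig, rng: np.random.Generator, run_bins: int = 10
) -> Dict[str, np.ndarray]:
    """Contiguous 'repeat' runs covering ~repeat_frac of each chromosome."""
    out = {}
    for chrom, length in cfg.chrom_lengths.items():
        n = -(-length // cfg.bin_width)
        mask = np.zeros(n, dtype=bool)
        n_runs = int(round(cfg.repeat_frac * n / run_bins))
        if n_runs > 0 and n > run_bins:
            starts = rng.integers(0, n - run_bins, size=n_runs)
            for s in starts:
                mask[s : s + run_bins] = True
        out[chrom] = mask
    return out


def simulate_depth(
    truth: TruthSet, cfg: SimConfig, rng: Optional[np.random.Generator] = None
) -> Dict[str, DepthTrack]:
    """Poisson depth tracks consistent with each individual's copy states.

    Expected count per bin: ``mean_depth * (copy/2) * (1 + gc_amp *
    sin(2 pi gc))``; copy is 2 outside planted loci.  q0 is Beta(1,19) per bin
    (mean 0.05) except in designated repeat runs, where it is Beta(8,2).
    With ``overdispersion > 0`` counts are gamma-Poisson mixed.
    """
    if truth.genotypes is None:
        raise ValueError("genotypes not simulated yet")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    gc = _gc_tracks(cfg)
    repeats = _repeat_masks(cfg, rng)
    lt = truth.locus_table
    w = cfg.bin_width

    tracks: Dict[str, DepthTrack] = {}
    for i, sample in enumerate(truth.sample_ids):
        counts: Dict[str, np.ndarray] = {}
        q0: Dict[str, np.ndarray] = {}
        for chrom, length in cfg.chrom_lengths.items():
            n = -(-length // w)
            copy = np.full(n, 2.0)
            sel = lt["chrom"] == chrom
            for start, end, g in zip(
                lt.loc[sel, "start"], lt.loc[sel, "end"], truth.genotypes[i, sel.to_numpy()]
            ):
                copy[start // w : -(-end // w)] = g
            mu = cfg.mean_depth_per_bin * (copy / 2.0) * (
                1.0 + cfg.gc_amp * np.sin(2 * np.pi * gc[chrom])
            )
            # short trailing bin scales with its width
            last_bp = length - (n - 1) * w
            mu[-1] *= last_bp / w
            if cfg.overdispersion > 0:
                shape = 1.0 / cfg.overdispersion
                lam = np.where(mu > 0, rng.gamma(shape, 1.0, size=n) * mu / shape, 0.0)
            else:
                lam = mu
            counts[chrom] = rng.poisson(lam).astype(np.int64)
            base = rng.beta(1, 19, size=n)
            rep = rng.beta(8, 2, size=n)
            q0[chrom] = np.where(repeats[chrom], rep, base)
        tracks[sample] = DepthTrack(
            sample=sample, bin_width=w, counts=counts, gc=dict(gc), q0=q0
        )
    return tracks


def simulate_gene_models(
    cfg: SimConfig,
    rng: Optional[np.random.Generator] = None,
    truth: Optional[TruthSet] = None,
    frac_noncoding: float = 0.1,
    n_terms: int = 12,
) -> Tuple[pd.DataFrame, List[GeneSet]]:
    """Non-overlapping gene models plus a GMT-style term -> gene table.

    Genes have 2-8 exons; coding genes carry a CDS whose total length is a
    multiple of 3 (start/stop trimmed to frame).  About ``frac_noncoding`` of
    genes carry exons but no CDS.  If ``truth`` is given, one planted term
    collects every gene overlapping a selected locus, giving the enrichment
    stage a positive control; remaining terms are random draws.

    Returns a table with one row per feature interval (gene/exon/CDS) in
    0-based half-open coordinates, plus the gene sets.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 3)
    rows: List[dict] = []
    if cfg.n_genes > 0:
        spans = _place_intervals(
            rng, cfg.chrom_lengths, cfg.n_genes, 2_000, 20_000, "genes"
        )
    else:
        spans = pd.DataFrame(columns=["chrom", "start", "end"])

    for gi, span in spans.iterrows():
        gene_id = f"gene_{gi:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        coding = rng.random() >= frac_noncoding
        glen = span.end - span.start
        n_ex = int(rng.integers(2, 9))
        # carve exons: alternating exon/intron blocks scaled to gene length
        parts = rng.uniform(1, 3, size=2 * n_ex - 1)
        parts = np.maximum((parts / parts.sum() * glen).astype(int), 30)
        pos = span.start
        exons: List[Tuple[int, int]] = []
        for j, plen in enumerate(parts):
            if pos + plen > span.end:
                plen = span.end - pos
            if j % 2 == 0 and plen >= 30:
                exons.append((int(pos), int(pos + plen)))
            pos += plen
            if pos >= span.end:
                break
        if not exons:
            exons = [(int(span.start), int(span.end))]
        cds: List[Tuple[int, int]] = []
        if coding:
            # CDS spans from inside the first exon to inside the last exon
            cds = [list(e) for e in exons]
            cds[0][0] = min(cds[0][0] + 10, cds[0][1] - 1)
            cds[-1][1] = max(cds[-1][1] - 10, cds[-1][0] + 1)
            total = sum(e - s for s, e in cds)
            trim = total % 3
            j = len(cds) - 1
            while trim > 0 and j >= 0:
                take = min(trim, cds[j][1] - cds[j][0] - 1)
                if take > 0:
                    cds[j][1] -= take
                    trim -= take
                j -= 1
            cds = [(int(s), int(e)) for s, e in cds]
        rows.append(
            dict(gene_id=gene_id, chrom=span.chrom, start=int(span.start),
                 end=int(span.end), strand=strand, feature="gene")
        )
        for s, e in exons:
            rows.append(dict(gene_id=gene_id, chrom=span.chrom, start=s, end=e,
                             strand=strand, feature="exon"))
        for s, e in cds:
            rows.append(dict(gene_id=gene_id, chrom=span.chrom, start=s, end=e,
                             strand=strand, feature="CDS"))

    genes = pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "feature"]
    ).sort_values(["chrom", "start", "gene_id"], ignore_index=True)

    # gene sets
    gene_ids = sorted(genes.loc[genes.feature == "gene", "gene_id"].unique())
    namespaces = ["BP", "CC", "MF", "pathway"]
    sets: List[GeneSet] = []
    if truth is not None and gene_ids:
        gspans = genes[genes.feature == "gene"]
        sel_loci = truth.locus_table[truth.locus_table["selected"]]
        hits = set()
        for _, loc in sel_loci.iterrows():
            m = (
                (gspans.chrom == loc.chrom)
                & (gspans.start < loc.end)
                & (gspans.end > loc.start)
            )
            hits.update(gspans.loc[m, "gene_id"])
        if hits:
            sets.append(GeneSet("TERM_SELECTED", "BP", tuple(sorted(hits))))
    n_random = max(n_terms - len(sets), 10)
    for t in range(n_random):
        if not gene_ids:
            break
        size = int(rng.integers(5, min(31, len(gene_ids) + 1)))
        members = sorted(rng.choice(gene_ids, size=size, replace=False))
        sets.append(
            GeneSet(f"TERM_{t:03d}", namespaces[t % len(namespaces)], tuple(members))
        )
    return genes, sets


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Run the full generator with a single seeded stream in a fixed order."""
    rng = np.random.default_rng(cfg.seed)
    truth = simulate_freqs(cfg, rng)
    truth = simulate_genotypes(truth, cfg, rng)
    genes, gene_sets = simulate_gene_models(cfg, rng, truth=truth)
    tracks = simulate_depth(truth, cfg, rng)
    truth.validate()
    return SimResult(
        config=cfg,
        layout=cfg.layout(),
        truth=truth,
        tracks=tracks,
        genes=genes,
        gene_sets=gene_sets,
    )
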