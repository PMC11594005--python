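"""Gene-context annotation of CNVRs.

Classifies each CNVR against gene models with the gene-based precedence
``exonic > UTR > intronic > upstream > downstream > intergenic`` (the
convention of gene-based annotators): a region takes the highest-precedence
class among every feature it overlaps by at least 1 bp.  ``exonic`` means the
region touches coding sequence (or any exon of a non-coding gene); ``UTR``
means it touches only the untranslated portion of a coding gene's exons;
``intronic`` means it lies within a gene span without touching an exon;
upstream/downstream use a strand-aware 1 kb window.

Loss CNVRs overlapping coding exons are sub-classified by the reading-frame
rule: a deletion removing a CDS length not divisible by 3 is a frameshift
deletion; divisible by 3, a non-frameshift deletion; touching no CDS (a
non-coding exon), unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Set, Tuple

import pandas as pd

from .cnvr import Cnvr

__all__ = [
    "GeneModel",
    "AnnotatedCnvr",
    "build_gene_models",
    "classify_region",
    "frameshift_subtype",
    "annotate_cnvrs",
    "class_fractions",
    "gene_sets",
    "venn_counts",
    "REGION_PRECEDENCE",
]

REGION_PRECEDENCE = ("exonic", "UTR", "intronic", "upstream", "downstream", "intergenic")


@dataclass(frozen=True)
class GeneModel:
    """One gene with exon and CDS intervals (0-based half-open internally)."""

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: Tuple[Tuple[int, int], ...]
    cds: Tuple[Tuple[int, int], ...]

    @property
    def coding(self) -> bool:
        return len(self.cds) > 0

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class AnnotatedCnvr:
    """A CNVR with its genomic-context class and gene hits."""

    cnvr_id: str
    region_class: str
    genes: Tuple[str, ...]
    exonic_subtype: str = "not_applicable"
    whole_gene: bool = False

    def __post_init__(self) -> None:
        if self.region_class not in REGION_PRECEDENCE:
            raise ValueError(f"invalid region class {self.region_class!r}")
        if self.region_class == "intergenic" and self.genes:
            raise ValueError("intergenic CNVR cannot have gene hits")


def build_gene_models(features: pd.DataFrame) -> List[GeneModel]:
    """Assemble :class:`GeneModel` objects from a feature table.

    The table uses 0-based half-open coordinates with columns
    gene_id/chrom/start/end/strand/feature (gene, exon, CDS rows), the format
    produced by the simulator and by :func:`cnvpop.io.read_gff3`.
    """
    models: List[GeneModel] = []
    for gene_id, grp in features.groupby("gene_id", sort=True):
        gene_rows = grp[grp.feature == "gene"]
        if gene_rows.empty:
            raise ValueError(f"gene {gene_id!r} has no gene-span row")
        g = gene_rows.iloc[0]
        exons = tuple(
            sorted(
                (int(r.start), int(r.end))
                for r in grp[grp.feature == "exon"].itertuples()
            )
        )
        cds = tuple(
            sorted(
                (int(r.start), int(r.end))
                for r in grp[grp.feature == "CDS"].itertuples()
            )
        )
        models.append(
            GeneModel(
                gene_id=str(gene_id),
                chrom=str(g.chrom),
                strand=str(g.strand),
                start=int(g.start),
                end=int(g.end),
                exons=exons or ((int(g.start), int(g.end)),),
                cds=cds,
            )
        )
    return models


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def classify_region(
    cnvr: Cnvr, genes: Sequence[GeneModel], window: int = 1000
) -> AnnotatedCnvr:
    """Assign the highest-precedence genomic-context class to one CNVR."""
    hits: List[GeneModel] = []
    classes: Set[str] = set()
    for g in genes:
        if g.chrom != cnvr.chrom:
            continue
        if _overlap(cnvr.start, cnvr.end, g.start, g.end) > 0:
            hits.append(g)
            exon_ov = any(_overlap(cnvr.start, cnvr.end, s, e) > 0 for s, e in g.exons)
            cds_ov = any(_overlap(cnvr.start, cnvr.end, s, e) > 0 for s, e in g.cds)
            if cds_ov or (exon_ov and not g.coding):
                classes.add("exonic")
            elif exon_ov:
                classes.add("UTR")
            else:
                classes.add("intronic")
        else:
            # strand-aware flanks: upstream precedes the 5' end
            if g.strand == "+":
                up = (g.start - window, g.start)
                down = (g.end, g.end + window)
            else:
                up = (g.end, g.end + window)
                down = (g.start - window, g.start)
            if _overlap(cnvr.start, cnvr.end, *up) > 0:
                classes.add("upstream")
            elif _overlap(cnvr.start, cnvr.end, *down) > 0:
                classes.add("downstream")
    for cls in REGION_PRECEDENCE[:-1]:
        if cls in classes:
            return AnnotatedCnvr(
                cnvr_id=cnvr.id,
                region_class=cls,
                genes=tuple(sorted(g.gene_id for g in hits)),
            )
    return AnnotatedCnvr(cnvr_id=cnvr.id, region_class="intergenic", genes=())


def frameshift_subtype(
    cnvr: Cnvr, ann: AnnotatedCnvr, genes: Sequence[GeneModel]
) -> AnnotatedCnvr:
    """Sub-classify an exonic loss CNVR by the deleted-CDS mod-3 rule."""
    if ann.region_class != "exonic" or cnvr.type != "loss":
        ann.exonic_subtype = "not_applicable"
        return ann
    gene_by_id = {g.gene_id: g for g in genes}
    deleted = 0
    whole = False
    for gid in ann.genes:
        g = gene_by_id[gid]
        deleted += sum(_overlap(cnvr.start, cnvr.end, s, e) for s, e in g.cds)
        if cnvr.start <= g.start and cnvr.end >= g.end:
            whole = True
    if deleted == 0:
        ann.exonic_subtype = "unknown"
    elif deleted % 3 != 0:
        ann.exonic_subtype = "frameshift_deletion"
    else:
        ann.exonic_subtype = "nonframeshift_deletion"
    ann.whole_gene = whole
    return ann


def annotate_cnvrs(
    cnvrs: Sequence[Cnvr], genes: Sequence[GeneModel], window: int = 1000
) -> List[AnnotatedCnvr]:
    """Classify every CNVR and sub-classify exonic losses."""
    out = []
    for r in cnvrs:
        ann = classify_region(r, genes, window=window)
        out.append(frameshift_subtype(r, ann, genes))
    return out


def class_fractions(annotated: Sequence[AnnotatedCnvr]) -> Dict[str, float]:
    """Fraction of CNVRs per genomic-context class (sums to 1)."""
    if not annotated:
        return {}
    counts: Dict[str, int] = {}
    for a in annotated:
        counts[a.region_class] = counts.get(a.region_class, 0) + 1
    n = len(annotated)
    return {cls: counts.get(cls, 0) / n for cls in REGION_PRECEDENCE if cls in counts}


def gene_sets(
    annotated_by_pop: Mapping[str, Sequence[AnnotatedCnvr]],
    region_class: str = "exonic",
) -> Dict[str, List[str]]:
    """Per-population sorted gene lists from CNVRs of one region class."""
    out: Dict[str, List[str]] = {}
    for pop, anns in annotated_by_pop.items():
        genes: Set[str] = set()
        for a in anns:
            if a.region_class == region_class:
                genes.update(a.genes)
        out[pop] = sorted(genes)
    return out


def venn_counts(sets_by_pop: Mapping[str, Sequence[str]]) -> Dict[str, int]:
    """Exact membership-pattern counts over populations (Venn regions).

    Keys are '&'-joined sorted population names; each gene contributes to the
    single region matching exactly the set of populations containing it.
    """
    pops = sorted(sets_by_pop)
    membership: Dict[str, Set[str]] = {p: set(sets_by_pop[p]) for p in pops}
    all_genes: Set[str] = set().union(*membership.values()) if membership else set()
    counts: Dict[str, int] = {}
    for gene in all_genes:
        key = "&".join(p for p in pops if gene in membership[p])
        counts[key] = counts.get(key, 0) + 1
    return dict(sorted(counts.items()))
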