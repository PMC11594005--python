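"""File formats and coordinate conventions.

All conversions between coordinate systems are centralized here: internal
structures are 0-based half-open; VCF is written/read 1-based (POS = start+1,
INFO END = end); GFF3 is 1-based inclusive (start+1, end); BED and the
bedGraph-like depth tracks are 0-based half-open.  VCF parsing goes through
cyvcf2; tabular formats through pandas.
"""

from __future__ import annotations

import hashlib
import json
import os
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .cnvr import Cnvr, CnvrGenotypes
from .depthcall import CnvCall, DepthTrack, GenomeLayout

__all__ = [
    "write_depth_track",
    "read_depth_track",
    "write_labels",
    "read_labels",
    "write_calls_vcf",
    "read_calls_vcf",
    "write_calls_bed",
    "write_cnvr_bed",
    "read_bed",
    "write_cnvr_vcf",
    "read_cnvr_vcf",
    "write_gff3",
    "read_gff3",
    "write_gmt",
    "read_gmt",
    "write_truth",
    "sha256_file",
]


# ---------------------------------------------------------------------------
# depth tracks (bedGraph-like TSV, 0-based half-open)
# ---------------------------------------------------------------------------

def write_depth_track(track: DepthTrack, path: str | Path) -> None:
    rows = []
    w = track.bin_width
    for chrom, counts in track.counts.items():
        n = len(counts)
        starts = np.arange(n) * w
        ends = starts + w
        rows.append(
            pd.DataFrame(
                dict(
                    chrom=chrom,
                    start=starts,
                    end=ends,
                    count=counts,
                    gc=np.round(track.gc[chrom], 6),
                    q0=np.round(track.q0[chrom], 6),
                )
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_depth_track(path: str | Path, sample: Optional[str] = None) -> DepthTrack:
    df = pd.read_csv(path, sep="\t")
    w = int((df["end"] - df["start"]).iloc[0])
    counts, gc, q0 = {}, {}, {}
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        counts[chrom] = grp["count"].to_numpy()
        gc[chrom] = grp["gc"].to_numpy()
        q0[chrom] = grp["q0"].to_numpy()
    name = sample if sample is not None else Path(path).stem
    return DepthTrack(sample=name, bin_width=w, counts=counts, gc=gc, q0=q0)


# ---------------------------------------------------------------------------
# breed labels (two-column TSV)
# ---------------------------------------------------------------------------

def write_labels(sample_ids: Sequence[str], breeds: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample": sample_ids, "breed": breeds}).to_csv(
        path, sep="\t", index=False
    )


def read_labels(path: str | Path) -> Dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["sample"].astype(str), df["breed"].astype(str)))


# ---------------------------------------------------------------------------
# per-sample CNV calls: VCF 4.2 (1-based) and BED5 (0-based half-open)
# ---------------------------------------------------------------------------

def _vcf_header(layout: GenomeLayout, samples: Sequence[str], fmt: bool) -> List[str]:
    lines = ["##fileformat=VCFv4.2", "##source=cnvpop"]
    for chrom, length in layout.lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>")
    lines += [
        '##ALT=<ID=DEL,Description="Deletion">',
        '##ALT=<ID=DUP,Description="Duplication">',
        '##ALT=<ID=CNV,Description="Copy number variable region">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position (1-based inclusive)">',
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##INFO=<ID=CN,Number=1,Type=Integer,Description="Copy state of the carrier">',
        '##INFO=<ID=Q0,Number=1,Type=Float,Description="Fraction of mapping-quality-zero reads">',
        '##INFO=<ID=PVAL,Number=1,Type=Float,Description="Depth-deviation p-value">',
    ]
    if fmt:
        lines.append(
            '##FORMAT=<ID=CN,Number=1,Type=Integer,Description="Copy state">'
        )
    header = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
    if fmt:
        header += "\tFORMAT\t" + "\t".join(samples)
    lines.append(header)
    return lines


def write_calls_vcf(
    calls: Sequence[CnvCall], layout: GenomeLayout, path: str | Path
) -> None:
    """One sample's CNV calls as a symbolic-allele VCF (POS 1-based)."""
    sample = calls[0].sample if calls else "sample"
    lines = _vcf_header(layout, [sample], fmt=False)
    for i, c in enumerate(calls):
        svtype = "DEL" if c.is_deletion else "DUP"
        svlen = -c.length if c.is_deletion else c.length
        info = (
            f"END={c.end};SVTYPE={svtype};SVLEN={svlen};CN={c.copy_state};"
            f"Q0={c.q0_frac:.6g};PVAL={c.p_value:.6g}"
        )
        lines.append(
            f"{c.chrom}\t{c.start + 1}\tcall_{i:05d}\tN\t<{svtype}>\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_calls_vcf(path: str | Path, sample: Optional[str] = None) -> List[CnvCall]:
    from cyvcf2 import VCF

    name = sample if sample is not None else Path(path).stem.replace(".vcf", "")
    calls = []
    for v in VCF(str(path)):
        end = int(v.INFO["END"])
        calls.append(
            CnvCall(
                sample=name,
                chrom=v.CHROM,
                start=v.POS - 1,
                end=end,
                copy_state=int(v.INFO["CN"]),
                d=int(v.INFO["CN"]) / 2.0,
                p_value=float(v.INFO["PVAL"]),
                q0_frac=float(v.INFO["Q0"]),
            )
        )
    return calls


def write_calls_bed(calls: Sequence[CnvCall], path: str | Path) -> None:
    """BED5: chrom, start, end, copy_state, score=0 (0-based half-open)."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(f"{c.chrom}\t{c.start}\t{c.end}\t{c.copy_state}\t0\n")


def write_cnvr_bed(cnvrs: Sequence[Cnvr], path: str | Path) -> None:
    """BED6: name=type, score=carrier count, strand '.'."""
    with open(path, "w") as fh:
        for r in cnvrs:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.type}\t{r.carrier_count}\t.\n"
            )


def read_bed(path: str | Path) -> pd.DataFrame:
    """Validated BED reader; rejects records with end <= start."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
            row = dict(chrom=chrom, start=start, end=end)
            if len(parts) > 3:
                row["name"] = parts[3]
            if len(parts) > 4:
                row["score"] = parts[4]
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# merged CNVR VCF with per-sample CN genotypes
# ---------------------------------------------------------------------------

_SVTYPE = {"loss": "DEL", "gain": "DUP", "mixed": "CNV"}


def write_cnvr_vcf(geno: CnvrGenotypes, layout: GenomeLayout, path: str | Path) -> None:
    lines = _vcf_header(layout, geno.sample_ids, fmt=True)
    for j, r in enumerate(geno.cnvrs):
        svtype = _SVTYPE[r.type]
        info = f"END={r.end};SVTYPE={svtype};SVLEN={r.length}"
        states = "\t".join(str(int(s)) for s in geno.states[:, j])
        lines.append(
            f"{r.chrom}\t{r.start + 1}\t{r.id}\tN\t<{svtype}>\t.\tPASS\t{info}\tCN\t{states}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_cnvr_vcf(
    path: str | Path, breeds: Optional[Mapping[str, str]] = None
) -> CnvrGenotypes:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    inv_svtype = {v: k for k, v in _SVTYPE.items()}
    cnvrs: List[Cnvr] = []
    cols: List[np.ndarray] = []
    for v in vcf:
        rtype = inv_svtype[v.INFO["SVTYPE"]]
        cn = v.format("CN").reshape(-1).astype(int)
        carriers: Dict[str, set] = {}
        for s, state in zip(samples, cn):
            if state != 2:
                b = breeds.get(s, "pop") if breeds else "pop"
                carriers.setdefault(b, set()).add(s)
        cnvrs.append(
            Cnvr(
                id=v.ID or f"cnvr_{len(cnvrs):05d}",
                chrom=v.CHROM,
                start=v.POS - 1,
                end=int(v.INFO["END"]),
                type=rtype,
                carriers=carriers,
            )
        )
        cols.append(cn)
    states = (
        np.column_stack(cols) if cols else np.zeros((len(samples), 0), dtype=int)
    )
    labels = [breeds.get(s, "pop") if breeds else "pop" for s in samples]
    return CnvrGenotypes(
        sample_ids=samples, breed_labels=labels, cnvrs=cnvrs, states=states
    )


# ---------------------------------------------------------------------------
# GFF3 gene models (1-based inclusive on disk, 0-based half-open in memory)
# ---------------------------------------------------------------------------

def write_gff3(features: pd.DataFrame, path: str | Path) -> None:
    """Write the gene/exon/CDS feature table as sorted GFF3."""
    lines = ["##gff-version 3"]
    df = features.sort_values(["chrom", "start", "gene_id"])
    for r in df.itertuples():
        if r.feature == "gene":
            attrs = f"ID={r.gene_id}"
        else:
            attrs = f"Parent={r.gene_id}"
        phase = "0" if r.feature == "CDS" else "."
        lines.append(
            f"{r.chrom}\tcnvpop\t{r.feature}\t{r.start + 1}\t{r.end}\t.\t{r.strand}\t{phase}\t{attrs}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read GFF3 into the internal feature table (0-based half-open)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            chrom, _, feature, start, end, _, strand, _, attrs = parts
            start_i, end_i = int(start) - 1, int(end)
            if end_i <= start_i:
                raise ValueError(f"{path}:{lineno}: empty interval")
            gene_id = None
            for kv in attrs.split(";"):
                if kv.startswith(("ID=", "Parent=")):
                    gene_id = kv.split("=", 1)[1]
                    break
            rows.append(
                dict(
                    gene_id=gene_id,
                    chrom=chrom,
                    start=start_i,
                    end=end_i,
                    strand=strand,
                    feature=feature,
                )
            )
    return pd.DataFrame(
        rows, columns=["gene_id", "chrom", "start", "end", "strand", "feature"]
    )


# ---------------------------------------------------------------------------
# GMT-style gene sets
# ---------------------------------------------------------------------------

def write_gmt(gene_sets, path: str | Path) -> None:
    """term <tab> namespace <tab> gene1 <tab> gene2 ..."""
    with open(path, "w") as fh:
        for s in gene_sets:
            fh.write("\t".join([s.term, s.namespace, *s.genes]) + "\n")


def read_gmt(path: str | Path):
    from .simdata import GeneSet

    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: need term, namespace, >=1 gene")
            sets.append(GeneSet(parts[0], parts[1], tuple(parts[2:])))
    return sets


# ---------------------------------------------------------------------------
# truth tables and checksums
# ---------------------------------------------------------------------------

def write_truth(truth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth.locus_table.to_csv(outdir / "truth_loci.tsv", sep="\t", index=False)
    if truth.genotypes is not None:
        pd.DataFrame(
            truth.genotypes,
            index=truth.sample_ids,
            columns=truth.locus_table["locus_id"],
        ).to_csv(outdir / "truth_genotypes.tsv", sep="\t")
    if truth.Q_true is not None:
        pd.DataFrame(
            truth.Q_true,
            index=truth.sample_ids,
            columns=[f"K{k + 1}" for k in range(truth.Q_true.shape[1])],
        ).to_csv(outdir / "truth_Q.tsv", sep="\t")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
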