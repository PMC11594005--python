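"""End-to-end orchestration: simulate -> call -> merge -> annotate ->
structure -> fst -> enrich, with a YAML config and a reproducibility manifest.

Each stage reads its predecessors only through the declared file formats in
:mod:`cnvpop.io`; a :class:`RunManifest` (JSON) records the config hash, seed
and per-output SHA-256 checksums, so a re-run with an identical config can be
verified checksum-for-checksum on the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import annotate as annotate_mod
from . import cnvr as cnvr_mod
from . import enrich as enrich_mod
from . import io as io_mod
from . import selscan, simdata, structure
from .depthcall import GenomeLayout, call_sample

logger = logging.getLogger("cnvpop")

__all__ = ["RunConfig", "RunManifest", "run"]

ALL_STAGES = ("simulate", "call", "merge", "annotate", "structure", "fst", "enrich")


@dataclass
class RunConfig:
    """Parameters of one pipeline run.

    Defaults follow the study design the pipeline models: 200 bp bins, call
    filters p < 0.001 / length > 1 kb / q0 < 0.5, CNVRs in >= 4 carriers,
    top-1% F_ST threshold, admixture for K = 2..10.
    """

    outdir: str = "cnvpop_run"
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    sim: Dict = field(default_factory=dict)
    bin_width: int = 200
    lam: float = 2.0
    min_carriers: int = 4
    quantile: float = 0.99
    k_min: int = 2
    k_max: int = 10
    admixture_restarts: int = 5
    upstream_window: int = 1000
    calls_dir: Optional[str] = None  # external per-sample call VCFs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.stages = tuple(cfg.stages)
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def sim_config(self) -> simdata.SimConfig:
        params = dict(self.sim)
        params.setdefault("seed", self.seed)
        params.setdefault("bin_width", self.bin_width)
        if "pop_sizes" in params:
            params["pop_sizes"] = tuple(params["pop_sizes"])
        if "chrom_lengths" in params:
            params["chrom_lengths"] = dict(params["chrom_lengths"])
        if "unplaced_chroms" in params:
            params["unplaced_chroms"] = tuple(params["unplaced_chroms"])
        return simdata.SimConfig(**params)

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["stages"] = list(self.stages)
        blob = json.dumps(data, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunManifest:
    """What a run produced: checksums, counts, timing, versions."""

    config_hash: str
    seed: int
    started: str
    finished: str = ""
    stages: Dict[str, Dict] = field(default_factory=dict)
    checksums: Dict[str, str] = field(default_factory=dict)
    versions: Dict[str, str] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)


def _checksum_outputs(manifest: RunManifest, outdir: Path, names: Sequence[str]) -> None:
    for name in names:
        p = outdir / name
        if p.exists():
            manifest.checksums[name] = io_mod.sha256_file(p)


def run(config: RunConfig) -> RunManifest:
    """Execute the enabled stages in dependency order."""
    import cnvpop

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=config.config_hash(),
        seed=config.seed,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
        versions={"cnvpop": cnvpop.__version__, "numpy": np.__version__},
    )
    config.to_yaml(outdir / "config.yaml")

    sim_cfg = config.sim_config()
    layout = sim_cfg.layout()
    result = None
    truth = None

    if "simulate" in config.stages:
        t0 = time.time()
        result = simdata.simulate_cohort(sim_cfg)
        truth = result.truth
        sim_dir = outdir / "sim"
        (sim_dir / "depth").mkdir(parents=True, exist_ok=True)
        for sample, track in result.tracks.items():
            io_mod.write_depth_track(track, sim_dir / "depth" / f"{sample}.tsv")
        io_mod.write_truth(truth, sim_dir)
        io_mod.write_labels(
            truth.sample_ids, truth.breed_labels, sim_dir / "labels.tsv"
        )
        io_mod.write_gff3(result.genes, sim_dir / "genes.gff3")
        io_mod.write_gmt(result.gene_sets, sim_dir / "gene_sets.gmt")
        manifest.stages["simulate"] = {
            "n_samples": len(result.tracks),
            "n_loci": len(truth.locus_table),
            "n_genes": int((result.genes.feature == "gene").sum()),
            "seconds": round(time.time() - t0, 2),
        }
        logger.info("simulate: %d samples, %d loci", len(result.tracks), len(truth.locus_table))

    breeds = {s: b for s, b in zip(truth.sample_ids, truth.breed_labels)} if truth else {}
    calls_dir = outdir / "calls"

    if "call" in config.stages:
        t0 = time.time()
        calls_dir.mkdir(exist_ok=True)
        n_calls = 0
        for sample, track in result.tracks.items():
            calls = call_sample(track, layout, lam=config.lam)
            io_mod.write_calls_vcf(calls, layout, calls_dir / f"{sample}.vcf")
            io_mod.write_calls_bed(calls, calls_dir / f"{sample}.bed")
            n_calls += len(calls)
        manifest.stages["call"] = {
            "n_calls": n_calls,
            "seconds": round(time.time() - t0, 2),
        }
        logger.info("call: %d filtered calls", n_calls)

    geno = None
    cnvrs = None
    if "merge" in config.stages:
        t0 = time.time()
        src = Path(config.calls_dir) if config.calls_dir else calls_dir
        all_calls = []
        for vcf in sorted(src.glob("*.vcf")):
            all_calls.extend(io_mod.read_calls_vcf(vcf, sample=vcf.stem))
        by_breed: Dict[str, List] = {}
        for c in all_calls:
            by_breed.setdefault(breeds.get(c.sample, "pop"), []).append(c)
        per_breed = {
            b: cnvr_mod.merge_cnvrs(cs, min_carriers=config.min_carriers, breed=b)
            for b, cs in sorted(by_breed.items())
        }
        cnvrs = cnvr_mod.merge_across_breeds(per_breed)
        sample_ids = truth.sample_ids if truth else sorted({c.sample for c in all_calls})
        breed_labels = [breeds.get(s, "pop") for s in sample_ids]
        geno = cnvr_mod.genotype_cnvrs(cnvrs, all_calls, sample_ids, breed_labels)
        io_mod.write_cnvr_bed(cnvrs, outdir / "cnvr.bed")
        io_mod.write_cnvr_vcf(geno, layout, outdir / "cnvr.vcf")
        summary = cnvr_mod.summarize(all_calls, cnvrs, layout)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary.to_dict(), fh, indent=2)
        manifest.stages["merge"] = {
            "n_cnvrs": len(cnvrs),
            "seconds": round(time.time() - t0, 2),
        }
        logger.info("merge: %d CNVRs", len(cnvrs))

    annotated = None
    gene_models = None
    if "annotate" in config.stages and cnvrs is not None:
        t0 = time.time()
        features = io_mod.read_gff3(outdir / "sim" / "genes.gff3")
        gene_models = annotate_mod.build_gene_models(features)
        annotated = annotate_mod.annotate_cnvrs(
            cnvrs, gene_models, window=config.upstream_window
        )
        pd.DataFrame(
            [
                dict(
                    cnvr_id=a.cnvr_id,
                    region_class=a.region_class,
                    exonic_subtype=a.exonic_subtype,
                    whole_gene=a.whole_gene,
                    genes=",".join(a.genes),
                )
                for a in annotated
            ]
        ).to_csv(outdir / "annotation.tsv", sep="\t", index=False)
        by_pop: Dict[str, List] = {}
        for r, a in zip(cnvrs, annotated):
            for b in r.carriers:
                by_pop.setdefault(b, []).append(a)
        sets = annotate_mod.gene_sets(by_pop)
        with open(outdir / "venn.json", "w") as fh:
            json.dump(annotate_mod.venn_counts(sets), fh, indent=2)
        manifest.stages["annotate"] = {
            "class_fractions": annotate_mod.class_fractions(annotated),
            "seconds": round(time.time() - t0, 2),
        }

    mat = None
    if geno is not None:
        mat = structure.recode_biallelic(geno)

    if "structure" in config.stages and mat is not None and mat.dosages.shape[1] > 0:
        t0 = time.time()
        st_dir = outdir / "structure"
        st_dir.mkdir(exist_ok=True)
        # NJ on breed-level F_ST distances when >=3 breeds, else individual IBS
        n_breeds = len(set(mat.breed_labels))
        mode = "fst_population" if n_breeds >= 3 else "ibs_individual"
        labels, D = structure.distance_matrix(mat, mode=mode)
        if len(labels) >= 3:
            tree = structure.nj_tree(labels, D)
            (st_dir / "nj.nwk").write_text(structure.to_newick(tree) + "\n")
        if (~mat.monomorphic).any():
            pres = structure.pca(mat)
            pd.DataFrame(
                pres.coords,
                index=mat.sample_ids,
                columns=[f"PC{j + 1}" for j in range(pres.coords.shape[1])],
            ).to_csv(st_dir / "pca_vectors.tsv", sep="\t")
            pd.DataFrame(
                dict(eigenvalue=pres.eigenvalues, pct_variance=pres.pct_variance)
            ).to_csv(st_dir / "pca_values.tsv", sep="\t", index=False)
        k_hi = min(config.k_max, len(mat.sample_ids))
        for K in range(config.k_min, k_hi + 1):
            fit = structure.admixture_em(
                mat, K, seed=config.seed + K, restarts=config.admixture_restarts
            )
            np.savetxt(st_dir / f"admixture.K{K}.Q", fit.Q_, fmt="%.6f")
            np.savetxt(st_dir / f"admixture.K{K}.P", fit.F_.T, fmt="%.6f")
        manifest.stages["structure"] = {
            "distance_mode": mode,
            "k_range": [config.k_min, k_hi],
            "seconds": round(time.time() - t0, 2),
        }

    sel_result = None
    if "fst" in config.stages and mat is not None and mat.dosages.shape[1] > 0:
        t0 = time.time()
        # default grouping: first breed vs all others pooled
        b = np.asarray(mat.breed_labels)
        first = sorted(set(mat.breed_labels))[0]
        groups = np.where(b == first, 0, 1)
        tab = selscan.wc_fst_components(
            mat.dosages, groups, locus_ids=list(mat.loci["locus_id"])
        )
        if tab["defined"].any():
            sel_result = selscan.select_top(tab, quantile=config.quantile)
            out = sel_result.table.merge(mat.loci, on="locus_id")
            out.to_csv(outdir / "fst.tsv", sep="\t", index=False)
            manifest.stages["fst"] = {
                "tau": sel_result.tau,
                "weighted_fst": sel_result.weighted_fst,
                "n_selected": int(sel_result.table["selected"].sum()),
                "seconds": round(time.time() - t0, 2),
            }

    if (
        "enrich" in config.stages
        and sel_result is not None
        and annotated is not None
    ):
        t0 = time.time()
        ann_by_id = {a.cnvr_id: a.genes for a in annotated}
        sel_cnvrs = set(
            mat.loci.set_index("locus_id").loc[sel_result.selected_ids, "source_cnvr"]
        )
        cand = selscan.candidates(sorted(sel_cnvrs), ann_by_id)
        (outdir / "candidates.txt").write_text("\n".join(cand) + "\n")
        gene_sets = io_mod.read_gmt(outdir / "sim" / "gene_sets.gmt")
        universe = sorted({g.gene_id for g in gene_models}) if gene_models else []
        db = enrich_mod.GeneSetDb.from_gene_sets(gene_sets, universe=universe)
        table = enrich_mod.enrich(cand, db)
        table.to_csv(outdir / "enrich.tsv", sep="\t", index=False)
        manifest.stages["enrich"] = {
            "n_candidates": len(cand),
            "n_terms": len(table),
            "seconds": round(time.time() - t0, 2),
        }

    _checksum_outputs(
        manifest,
        outdir,
        [
            "cnvr.bed",
            "cnvr.vcf",
            "summary.json",
            "annotation.tsv",
            "fst.tsv",
            "enrich.tsv",
            "candidates.txt",
            "venn.json",
            "structure/nj.nwk",
            "structure/pca_values.tsv",
        ],
    )
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.save(outdir / "manifest.json")
    return manifest
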