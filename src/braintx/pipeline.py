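"""End-to-end orchestration of the analysis stages.

``run_pipeline`` executes (optionally) the simulator, then genome
partition, stability ranking, AEI calling, isoform deviation ranking,
and detectability/selectivity summaries, writing TSV/JSON outputs plus a
machine-readable manifest (config hash, seed, per-stage row counts and
timings) into one output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd
import yaml

from . import aei as aei_mod
from . import io as io_mod
from . import isoforms as iso_mod
from . import selectivity as sel_mod
from . import stability as stab_mod
from .models import ExpressionMatrix, GeneModelSet
from .regions import partition_genome, summarize_reads
from .simulate import SimConfig, simulate_all

log = logging.getLogger("braintx")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """All inputs and thresholds of one pipeline run.

    Threshold defaults follow the analysis conventions used throughout
    the package: stable genes must exceed 3 FPKM, detection needs >2
    FPKM in >=2 subjects, isoform inclusion needs >=5 FPKM in >=40
    libraries, and the AEI cascade uses 10-read coverage in >=3 regions,
    >=2 SNPs spaced >=51 bases, a twofold CI bound, and a 30-read
    stringent tier.
    """

    outdir: str = "braintx_out"
    seed: int = 0
    simulate: bool = True
    # input paths (used when simulate is False)
    annotation: Optional[str] = None
    expression: Optional[str] = None
    isoform_fpkm: Optional[str] = None
    allele_counts: Optional[str] = None
    genotypes: Optional[str] = None
    reads_bed: Optional[str] = None
    # thresholds
    stability_min_fpkm: float = 3.0
    entropy_threshold: float = 0.99
    detect_fpkm: float = 2.0
    detect_min_subjects: int = 2
    iso_min_fpkm: float = 5.0
    iso_min_libraries: int = 40
    iso_conf_level: float = 0.99
    aei_min_coverage: int = 10
    aei_min_regions: int = 3
    aei_min_snps: int = 2
    aei_min_spacing: int = 51
    aei_fold_cutoff: float = 2.0
    aei_stringent_depth: float = 30.0
    aei_bin_pad: int = 1000
    cutoff_ladder: tuple = (2, 5, 10, 50, 100, 500, 1000, 5000)
    sim: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        positive = {
            "stability_min_fpkm": self.stability_min_fpkm,
            "detect_fpkm": self.detect_fpkm,
            "iso_min_fpkm": self.iso_min_fpkm,
            "aei_min_coverage": self.aei_min_coverage,
            "aei_min_regions": self.aei_min_regions,
            "aei_min_snps": self.aei_min_snps,
            "aei_min_spacing": self.aei_min_spacing,
            "aei_fold_cutoff": self.aei_fold_cutoff,
            "aei_stringent_depth": self.aei_stringent_depth,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value}")
        if not self.simulate:
            required = {
                "annotation": self.annotation,
                "expression": self.expression,
            }
            for name, value in required.items():
                if value is None:
                    raise ConfigError(
                        f"config field '{name}' is required unless simulate=True"
                    )
            if self.allele_counts is not None and self.genotypes is None:
                raise ConfigError(
                    "config field 'genotypes' is required when allele_counts is set"
                )

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        """Hash of the analytic configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Run all stages; returns the in-memory bundle and writes files to outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: Dict[str, object] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    bundle: Dict[str, object] = {}

    def stage(name):
        def deco(fn):
            start = time.time()
            try:
                info = fn()
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc
            manifest["stages"][name] = info or {}
            manifest["stages"][name]["_elapsed_s"] = round(time.time() - start, 3)
            return info
        return deco

    truth = None
    if config.simulate:
        @stage("simulate")
        def _sim():
            nonlocal truth
            sim_cfg = SimConfig(seed=config.seed, **config.sim)
            models, tr, expr, counts, iso = simulate_all(sim_cfg)
            truth = tr
            bundle.update(models=models, expression=expr,
                          allele_counts=counts, isoform_fpkm=iso, truth=tr)
            io_mod.write_gtf(models, outdir / "annotation.gtf")
            io_mod.write_bed6(models, outdir / "genes.bed")
            io_mod.write_expression_tsv(expr, outdir / "expression.tsv")
            io_mod.write_table(iso, outdir / "isoform_fpkm.tsv")
            io_mod.write_allele_counts_tsv(counts, outdir / "allele_counts.tsv")
            io_mod.write_het_tsv(tr.het_table(), outdir / "genotypes_het.tsv")
            io_mod.write_ground_truth(tr, outdir / "ground_truth.json")
            return {"genes": len(models), "samples": expr.values.shape[1],
                    "allele_rows": len(counts)}
    else:
        @stage("load")
        def _load():
            bundle["models"] = io_mod.read_gtf(config.annotation)
            bundle["expression"] = io_mod.read_expression_tsv(config.expression)
            if config.isoform_fpkm:
                bundle["isoform_fpkm"] = io_mod.read_table(config.isoform_fpkm)
            if config.allele_counts:
                bundle["allele_counts"] = io_mod.read_allele_counts_tsv(
                    config.allele_counts
                )
                bundle["genotypes"] = io_mod.read_het_tsv(config.genotypes)
            return {"genes": len(bundle["models"])}

    models: GeneModelSet = bundle["models"]
    expr: ExpressionMatrix = bundle["expression"]

    @stage("partition")
    def _partition():
        part = partition_genome(models)
        bundle["partition"] = part
        for name, ivs in part.sets().items():
            io_mod.write_intervals_bed(ivs, outdir / f"partition_{name}.bed")
        if config.reads_bed:
            reads_df = io_mod.read_bed(config.reads_bed)
            reads = list(zip(reads_df["chrom"], reads_df["start"], reads_df["end"]))
            summ = summarize_reads(part, reads, total_mapped=len(reads),
                                   main_chrom=models.genes[0].chrom)
            io_mod.write_table(summ.to_frame().reset_index(names="set"),
                               outdir / "read_summary.tsv")
        return {k: round(v, 3) for k, v in part.total_len_kb.items()}

    @stage("stability")
    def _stability():
        report = stab_mod.stability_report(
            expr, min_fpkm=config.stability_min_fpkm,
            entropy_threshold=config.entropy_threshold, seed=config.seed,
        )
        bundle["stability"] = report
        io_mod.write_table(report.reset_index(names="gene_id"),
                           outdir / "stability.tsv")
        return {"genes_ranked": int(report["norm_entropy"].notna().sum()),
                "flat": int(report["flat_across_regions"].sum())}

    if "allele_counts" in bundle:
        @stage("aei")
        def _aei():
            counts = bundle["allele_counts"]
            het = bundle["genotypes"] if "genotypes" in bundle else truth.het_table()
            bins = aei_mod.make_gene_bins(models.spans(), pad=config.aei_bin_pad)
            snp2gene = aei_mod.assign_snps_to_bins(counts, bins)
            filtered, attrition = aei_mod.filter_snp_calls(
                counts, het, min_coverage=config.aei_min_coverage,
                min_regions=config.aei_min_regions,
            )
            calls = aei_mod.gene_level_aei(
                filtered, snp2gene, min_snps=config.aei_min_snps,
                min_spacing=config.aei_min_spacing,
                fold_cutoff=config.aei_fold_cutoff,
                stringent_depth=config.aei_stringent_depth,
            )
            recur = aei_mod.recurrence_summary(calls)
            bundle.update(aei_calls=calls, aei_recurrence=recur,
                          aei_attrition=attrition)
            io_mod.write_table(calls, outdir / "aei_calls.tsv")
            io_mod.write_table(recur, outdir / "aei_recurrence.tsv")
            (outdir / "aei_attrition.json").write_text(json.dumps(attrition))
            return dict(attrition, calls=len(calls),
                        stringent=int((calls["tier"] == aei_mod.TIER_STRINGENT).sum()))

    if "isoform_fpkm" in bundle:
        @stage("isoforms")
        def _isoforms():
            iso = bundle["isoform_fpkm"]
            fractions = iso_mod.isoform_fractions(iso)
            gene_totals = (
                iso.assign(sample=iso["subject"] + "." + iso["region"])
                .pivot_table(index="gene_id", columns="sample", values="fpkm",
                             aggfunc="sum")
                .fillna(0.0)
            )
            included = iso_mod.inclusion_filter(
                gene_totals, min_fpkm=config.iso_min_fpkm,
                min_libraries=config.iso_min_libraries,
            )
            scores = iso_mod.region_deviation_score(
                fractions, included_genes=included,
                conf_level=config.iso_conf_level,
            )
            bundle.update(isoform_fractions=fractions, isoform_scores=scores)
            io_mod.write_table(fractions, outdir / "isoform_fractions.tsv")
            io_mod.write_table(scores.reset_index(), outdir / "isoform_scores.tsv")
            return {"genes_included": len(included), "genes_scored": len(scores)}

    @stage("selectivity")
    def _selectivity():
        classes = {g.gene_id: g.rna_class for g in models}
        profiles = sel_mod.detectability(
            expr, fpkm_cutoff=config.detect_fpkm,
            min_subjects=config.detect_min_subjects, classes=classes,
        )
        summary = sel_mod.class_selectivity_summary(profiles)
        ladder = sel_mod.expression_cutoff_ladder(
            expr, classes, cutoffs=config.cutoff_ladder
        )
        bundle.update(detectability=profiles, class_summary=summary,
                      cutoff_ladder=ladder)
        io_mod.write_table(profiles.reset_index(), outdir / "detectability.tsv")
        io_mod.write_table(summary.reset_index(), outdir / "class_selectivity.tsv")
        io_mod.write_table(ladder.reset_index(), outdir / "cutoff_ladder.tsv")
        return {"genes": len(profiles)}

    manifest["elapsed_s"] = round(time.time() - t0, 3)
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    bundle["manifest"] = manifest
    return bundle
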