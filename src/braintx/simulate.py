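"""Synthetic multi-region brain RNA-seq data with planted ground truth.

The generator emulates the structure of a ten-region x ten-subject brain
expression survey: a gene annotation with three RNA classes of different
detectability (protein coding, lncRNA, pseudogene), a gene-level FPKM
matrix, an isoform-level FPKM table, and per-SNP allelic read counts with
a subject x SNP heterozygosity mask.  Four kinds of signal are planted so
every downstream stage has a recoverable truth:

* **stable** genes — well expressed (>3 FPKM) with a flat profile across
  all regions and subjects (multiplicative noise with a small CV);
* **region-selective** genes — expressed above the detection cutoff in a
  designated subset of regions only;
* **AEI** genes — heterozygous SNPs whose read counts are drawn with an
  allelic skew away from 0.5, direction randomized per gene;
* **isoform-switch** genes — two isoforms whose major/minor roles swap
  between two designated groups of regions.

Everything is driven by a single integer seed; identical configurations
produce byte-identical serialized output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .models import ExpressionMatrix, GeneModel, GeneModelSet

#: The ten sampled brain regions (four Brodmann cortical areas plus six
#: subcortical/cerebellar structures), used as default region labels.
DEFAULT_REGIONS = (
    "BA10", "BA22", "BA24", "BA46", "insula",
    "hippocampus", "amygdala", "putamen", "cerebellum", "raphe",
)

DEFAULT_CLASS_COUNTS = {"protein_coding": 60, "lncRNA": 25, "pseudogene": 15}

#: Per-class probability that a gene is expressed in any given region;
#: encodes the broad expression of mRNAs versus the restricted expression
#: of non-coding classes.
DEFAULT_REGION_BREADTH = {"protein_coding": 0.97, "lncRNA": 0.55, "pseudogene": 0.40}

#: Per-class lognormal (mu, sigma) of baseline FPKM, on the natural-log scale.
DEFAULT_FPKM_PARAMS = {
    "protein_coding": (3.0, 1.0),
    "lncRNA": (1.2, 1.0),
    "pseudogene": (0.8, 1.0),
}


class SimulationError(ValueError):
    """Raised for impossible configurations (e.g. genome too small)."""


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 10 subjects (5 smokers, 5
    non-smokers) x 10 brain regions, three RNA classes with class-
    dependent expression breadth, and modest numbers of planted genes of
    each kind.
    """

    n_subjects: int = 10
    n_regions: int = 10
    n_genes_per_class: Dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS)
    )
    n_stable_genes: int = 8
    n_selective_genes: int = 8
    n_selective_regions: int = 3
    n_aei_genes: int = 8
    aei_skew: float = 0.75
    n_switch_genes: int = 8
    n_switch_minor_regions: int = 3
    snps_per_gene: Tuple[int, int] = (2, 4)
    het_prob: float = 0.5
    depth_mean: float = 100.0
    depth_dispersion: float = 0.3
    fpkm_lognormal_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FPKM_PARAMS)
    )
    region_breadth_by_class: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_BREADTH)
    )
    stable_cv: float = 0.02
    genome_length: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        counts = [
            self.n_subjects, self.n_regions, self.n_stable_genes,
            self.n_selective_genes, self.n_aei_genes, self.n_switch_genes,
        ] + list(self.n_genes_per_class.values())
        if any(c < 0 for c in counts):
            raise SimulationError("all counts must be non-negative")
        if not 0.5 < self.aei_skew < 1.0:
            raise SimulationError("aei_skew must lie in (0.5, 1)")
        if self.n_regions > len(DEFAULT_REGIONS):
            raise SimulationError(
                f"at most {len(DEFAULT_REGIONS)} named regions are available"
            )
        total = sum(self.n_genes_per_class.values())
        planted = self.n_stable_genes + self.n_selective_genes + self.n_switch_genes
        if planted > total:
            raise SimulationError(
                f"{planted} planted stable+selective+switch genes exceed "
                f"{total} genes in the roster"
            )
        if self.n_aei_genes > total:
            raise SimulationError("n_aei_genes exceeds the gene roster")
        if self.n_selective_regions > self.n_regions:
            raise SimulationError("n_selective_regions exceeds n_regions")

    @property
    def regions(self) -> List[str]:
        return list(DEFAULT_REGIONS[: self.n_regions])

    @property
    def subjects(self) -> List[str]:
        return [f"S{i + 1:02d}" for i in range(self.n_subjects)]

    @property
    def smoker(self) -> Dict[str, bool]:
        # 5/5 split in the default design: first half are smokers.
        half = self.n_subjects // 2
        return {s: i < half for i, s in enumerate(self.subjects)}

    def rng(self, stream: int) -> np.random.Generator:
        """Independent deterministic stream per pipeline stage."""
        return np.random.default_rng([self.seed, stream])

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Planted signals of one simulation, keyed by gene id."""

    stable_gene_ids: List[str]
    selective_genes: Dict[str, List[str]]
    aei_genes: Dict[str, dict]          # gene -> {"skew", "ref_skewed"}
    switch_genes: Dict[str, dict]       # gene -> {"isoform_a","isoform_b","regions_b"}
    class_of_gene: Dict[str, str]
    snps: Dict[str, List[dict]]         # gene -> [{"rsid","pos"}]
    het_subjects: Dict[str, List[str]]  # gene -> subjects het at all its SNPs
    subjects: List[str]
    regions: List[str]
    smoker: Dict[str, bool]

    @property
    def aei_gene_ids(self) -> List[str]:
        return list(self.aei_genes)

    @property
    def switch_gene_ids(self) -> List[str]:
        return list(self.switch_genes)

    def het_table(self) -> pd.DataFrame:
        """Long (subject, rsid) table of heterozygous genotype calls."""
        rows = []
        for gene, subjects in self.het_subjects.items():
            for snp in self.snps[gene]:
                for s in subjects:
                    rows.append((s, snp["rsid"]))
        return pd.DataFrame(rows, columns=["subject", "rsid"]).drop_duplicates()

    def to_dict(self) -> dict:
        return asdict(self)


def simulate_annotation(cfg: SimConfig) -> Tuple[GeneModelSet, GroundTruth]:
    """Lay out genes on a toy chromosome and assign planted roles.

    Genes are placed sequentially with intergenic gaps; each gene has 2-5
    exons and one or two transcripts (switch genes always two).  Every
    gene carries 2-4 exonic SNP positions with pairwise genomic distance
    >50 bases, so the allelic caller's spacing rule is satisfiable.
    """
    rng = cfg.rng(1)
    gene_ids: List[str] = []
    class_of: Dict[str, str] = {}
    for cls, n in sorted(cfg.n_genes_per_class.items()):
        for i in range(n):
            gid = f"{cls}_{i + 1:04d}"
            gene_ids.append(gid)
            class_of[gid] = cls

    order = [str(g) for g in rng.permutation(gene_ids)]
    stable = sorted(order[: cfg.n_stable_genes])
    sel_pool = order[cfg.n_stable_genes: cfg.n_stable_genes + cfg.n_selective_genes]
    switch_pool = order[
        cfg.n_stable_genes + cfg.n_selective_genes:
        cfg.n_stable_genes + cfg.n_selective_genes + cfg.n_switch_genes
    ]
    aei_pool = sorted(
        str(g) for g in rng.choice(gene_ids, size=cfg.n_aei_genes, replace=False)
    )

    regions = cfg.regions
    selective = {
        g: sorted(
            str(r)
            for r in rng.choice(regions, size=cfg.n_selective_regions, replace=False)
        )
        for g in sorted(sel_pool)
    }
    aei = {
        g: {"skew": cfg.aei_skew, "ref_skewed": bool(rng.integers(2))}
        for g in aei_pool
    }

    genes: List[GeneModel] = []
    snps: Dict[str, List[dict]] = {}
    switch: Dict[str, dict] = {}
    het_subjects: Dict[str, List[str]] = {}
    cursor = int(rng.integers(500, 2000))
    rs_counter = 1
    switch_set = set(switch_pool)

    for gid in gene_ids:
        n_exons = int(rng.integers(2, 6))
        exon_lens = rng.integers(120, 300, size=n_exons)
        intron_lens = rng.integers(100, 500, size=n_exons - 1)
        exons: List[Tuple[int, int]] = []
        pos = cursor
        for i, L in enumerate(exon_lens):
            exons.append((pos, pos + int(L)))
            pos += int(L)
            if i < n_exons - 1:
                pos += int(intron_lens[i])
        start, end = exons[0][0], exons[-1][1]

        transcripts = {f"{gid}.t1": list(exons)}
        two_tx = gid in switch_set or (n_exons >= 3 and rng.random() < 0.4)
        if two_tx:
            if n_exons >= 3:
                alt = exons[:1] + exons[2:]          # skip the second exon
            else:
                alt = exons[:1]
            transcripts[f"{gid}.t2"] = list(alt)
        genes.append(
            GeneModel(
                gene_id=gid,
                rna_class=class_of[gid],
                chrom="chr1",
                strand="+" if rng.random() < 0.5 else "-",
                start=start,
                end=end,
                transcripts=transcripts,
            )
        )
        if gid in switch_set:
            regions_b = sorted(
                str(r)
                for r in rng.choice(regions, size=cfg.n_switch_minor_regions,
                                    replace=False)
            )
            switch[gid] = {
                "isoform_a": f"{gid}.t1",
                "isoform_b": f"{gid}.t2",
                "regions_b": regions_b,
            }

        # exonic SNPs, pairwise genomic distance >= 51
        n_snps = int(rng.integers(cfg.snps_per_gene[0], cfg.snps_per_gene[1] + 1))
        positions: List[int] = []
        for es, ee in exons:
            p = es + 10
            while p < ee - 1 and len(positions) < n_snps:
                positions.append(p)
                p += 61
            if len(positions) >= n_snps:
                break
        if len(positions) < max(2, n_snps):
            raise SimulationError(
                f"gene {gid} has too little exonic space to place "
                f"{n_snps} SNPs spaced >50 bases apart"
            )
        snps[gid] = [
            {"rsid": f"rs{rs_counter + i}", "pos": int(p)}
            for i, p in enumerate(positions)
        ]
        rs_counter += len(positions)

        het = [s for s in cfg.subjects if rng.random() < cfg.het_prob]
        if not het and cfg.n_subjects:
            het = [cfg.subjects[int(rng.integers(cfg.n_subjects))]]
        het_subjects[gid] = het

        cursor = end + int(rng.integers(2100, 4000))

    genome_length = cursor + int(rng.integers(500, 2000))
    if cfg.genome_length is not None:
        if cfg.genome_length < cursor:
            raise SimulationError(
                f"genome_length={cfg.genome_length} is smaller than the "
                f"{cursor} bases required to place {len(gene_ids)} genes"
            )
        genome_length = cfg.genome_length

    truth = GroundTruth(
        stable_gene_ids=stable,
        selective_genes=selective,
        aei_genes=aei,
        switch_genes=switch,
        class_of_gene=class_of,
        snps=snps,
        het_subjects=het_subjects,
        subjects=cfg.subjects,
        regions=regions,
        smoker=cfg.smoker,
    )
    return GeneModelSet(genes=genes, genome_length=genome_length), truth


def simulate_expression(cfg: SimConfig, truth: GroundTruth) -> ExpressionMatrix:
    """Gene-level FPKM matrix with planted stable and selective profiles."""
    rng = cfg.rng(2)
    subjects, regions = truth.subjects, truth.regions
    sample_ids = [f"{s}.{r}" for s in subjects for r in regions]
    samples = pd.DataFrame(
        {
            "subject": [sid.split(".")[0] for sid in sample_ids],
            "region": [sid.split(".", 1)[1] for sid in sample_ids],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    samples["smoker"] = samples["subject"].map(truth.smoker)

    gene_ids = list(truth.class_of_gene)
    n_s, n_r = len(subjects), len(regions)
    region_idx = {r: j for j, r in enumerate(regions)}
    stable = set(truth.stable_gene_ids)
    values = np.zeros((len(gene_ids), n_s * n_r))

    for i, gid in enumerate(gene_ids):
        cls = truth.class_of_gene[gid]
        if gid in stable:
            base = rng.uniform(20.0, 80.0)
            eps = np.clip(rng.normal(0.0, cfg.stable_cv, n_s * n_r), -0.45, 0.45)
            values[i] = base * (1.0 + eps)
        elif gid in truth.selective_genes:
            on = np.zeros(n_r, dtype=bool)
            on[[region_idx[r] for r in truth.selective_genes[gid]]] = True
            base = rng.uniform(8.0, 60.0)
            row = np.where(
                np.tile(on, n_s),
                base * rng.lognormal(0.0, 0.15, n_s * n_r),
                rng.uniform(0.0, 1.0, n_s * n_r),
            )
            values[i] = row
        else:
            mu, sigma = cfg.fpkm_lognormal_params[cls]
            base = rng.lognormal(mu, sigma)
            breadth = cfg.region_breadth_by_class.get(cls, 1.0)
            on = rng.random(n_r) < breadth
            if gid in truth.switch_genes:   # switch genes must stay well expressed
                base = max(base, rng.uniform(20.0, 50.0))
                on[:] = True
            region_fac = rng.lognormal(0.0, 0.35, n_r)
            noise = rng.lognormal(0.0, 0.25, n_s * n_r)
            row = np.tile(base * region_fac * on, n_s) * noise
            row[row == 0.0] = rng.uniform(0.0, 1.0, (row == 0.0).sum())
            values[i] = row

    frame = pd.DataFrame(values, index=pd.Index(gene_ids, name="gene_id"),
                         columns=samples.index)
    return ExpressionMatrix(values=frame, samples=samples)


def simulate_allele_counts(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Per-(SNP, subject, region) reference/alternate read counts.

    Depth per row is negative-binomial (mean ``depth_mean``, dispersion
    ``depth_dispersion``; variance m + m^2*d), which reproduces the
    overdispersion of real RNA-seq SNP coverage.  Reference counts are
    binomial with p = the planted skew for heterozygous subjects of AEI
    genes, p = 0.5 for other heterozygous subjects, and p ~ 1 for
    homozygous-reference subjects (sequencing error only).
    """
    rng = cfg.rng(3)
    subjects, regions = truth.subjects, truth.regions
    rsid, chrom, pos, subj, reg, p_arr = [], [], [], [], [], []
    for gid, snp_list in truth.snps.items():
        info = truth.aei_genes.get(gid)
        het = set(truth.het_subjects[gid])
        for snp in snp_list:
            for s in subjects:
                if s not in het:
                    p_het = 0.999
                elif info is None:
                    p_het = 0.5
                else:
                    p_het = info["skew"] if info["ref_skewed"] else 1.0 - info["skew"]
                for r in regions:
                    rsid.append(snp["rsid"])
                    chrom.append("chr1")
                    pos.append(snp["pos"])
                    subj.append(s)
                    reg.append(r)
                    p_arr.append(p_het)
    n = len(rsid)
    size = 1.0 / cfg.depth_dispersion
    depth = rng.negative_binomial(size, size / (size + cfg.depth_mean), n)
    ref = rng.binomial(depth, np.asarray(p_arr))
    return pd.DataFrame(
        {
            "rsid": rsid,
            "chrom": chrom,
            "pos": pos,
            "subject": subj,
            "region": reg,
            "ref_count": ref,
            "alt_count": depth - ref,
        }
    )


def simulate_isoform_expression(
    cfg: SimConfig, truth: GroundTruth, models: GeneModelSet
) -> pd.DataFrame:
    """Isoform-level FPKM table (gene_id, transcript_id, subject, region, fpkm).

    Switch genes draw the designated major isoform's fraction uniformly in
    [0.65, 0.85] per sample, so its per-region mean exceeds 0.6 in the
    designated regions and falls below 0.4 in the others.  Non-switch
    multi-isoform genes get a Dirichlet base composition jittered mildly
    across samples.  Gene totals for switch genes are kept >= 5 FPKM so
    they survive the inclusion filter.
    """
    rng = cfg.rng(4)
    subjects, regions = truth.subjects, truth.regions
    rows: List[tuple] = []
    for gene in models:
        tx_ids = sorted(gene.transcripts)
        k = len(tx_ids)
        sw = truth.switch_genes.get(gene.gene_id)
        if sw is not None:
            regions_b = set(sw["regions_b"])
            a, b = sw["isoform_a"], sw["isoform_b"]
            for s in subjects:
                for r in regions:
                    total = rng.uniform(10.0, 60.0)
                    major = rng.uniform(0.65, 0.85)
                    frac = {a: 1.0 - major, b: major} if r in regions_b \
                        else {a: major, b: 1.0 - major}
                    for t in tx_ids:
                        rows.append((gene.gene_id, t, s, r, total * frac.get(t, 0.0)))
        else:
            base = rng.dirichlet(np.full(k, 5.0)) if k > 1 else np.ones(1)
            mu, sigma = cfg.fpkm_lognormal_params[gene.rna_class]
            gene_base = rng.lognormal(mu, sigma)
            for s in subjects:
                for r in regions:
                    total = gene_base * rng.lognormal(0.0, 0.3)
                    frac = rng.dirichlet(base * 200.0 + 1e-3) if k > 1 else base
                    for t, f in zip(tx_ids, frac):
                        rows.append((gene.gene_id, t, s, r, total * float(f)))
    return pd.DataFrame(
        rows, columns=["gene_id", "transcript_id", "subject", "region", "fpkm"]
    )


def simulate_all(cfg: SimConfig):
    """Run all four generators; returns (models, truth, expression, allele counts, isoform table)."""
    models, truth = simulate_annotation(cfg)
    expr = simulate_expression(cfg, truth)
    counts = simulate_allele_counts(cfg, truth)
    iso = simulate_isoform_expression(cfg, truth, models)
    return models, truth, expr, counts, iso
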