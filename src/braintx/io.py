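"""Readers and writers for the formats the pipeline consumes and emits.

Internal coordinates are 0-based half-open everywhere; GTF and VCF use
1-based inclusive coordinates, converted only here at the boundary.  BED
is already 0-based half-open.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List

import pandas as pd
import pyranges as pr

from .models import ExpressionMatrix, GeneModel, GeneModelSet
from .simulate import GroundTruth


class FormatError(ValueError):
    """Raised for malformed input files, with file and line context."""


# --- coordinate conversions -------------------------------------------------

def bed_to_gtf_coords(start: int, end: int) -> tuple[int, int]:
    """0-based half-open -> 1-based inclusive."""
    return start + 1, end


def gtf_to_bed_coords(start1: int, end1: int) -> tuple[int, int]:
    """1-based inclusive -> 0-based half-open."""
    return start1 - 1, end1


# --- annotation -------------------------------------------------------------

def write_gtf(models: GeneModelSet, path) -> None:
    """One exon line per (transcript, exon) with gene_id/transcript_id/gene_type."""
    lines = []
    for g in sorted(models, key=lambda g: (g.chrom, g.start, g.gene_id)):
        for tx_id in sorted(g.transcripts):
            for s, e in g.transcripts[tx_id]:
                s1, e1 = bed_to_gtf_coords(s, e)
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{tx_id}"; '
                    f'gene_type "{g.rna_class}";'
                )
                lines.append(
                    f"{g.chrom}\tbraintx\texon\t{s1}\t{e1}\t.\t{g.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path, genome_length: int | None = None) -> GeneModelSet:
    """Rebuild a :class:`GeneModelSet` from exon-level GTF."""
    df = pr.read_gtf(str(path)).df
    if df.empty:
        raise FormatError(f"{path}: no features")
    df = df[df["Feature"] == "exon"]
    genes: List[GeneModel] = []
    for gid, gdf in df.groupby("gene_id", sort=False):
        transcripts = {
            str(tx): sorted(zip(tdf["Start"].astype(int), tdf["End"].astype(int)))
            for tx, tdf in gdf.groupby("transcript_id", sort=False)
        }
        cls = str(gdf["gene_type"].iloc[0]) if "gene_type" in gdf else "unknown"
        genes.append(
            GeneModel(
                gene_id=str(gid),
                rna_class=cls,
                chrom=str(gdf["Chromosome"].iloc[0]),
                strand=str(gdf["Strand"].iloc[0]),
                start=int(gdf["Start"].min()),
                end=int(gdf["End"].max()),
                transcripts=transcripts,
            )
        )
    if genome_length is None:
        genome_length = max(g.end for g in genes)
    return GeneModelSet(genes=genes, genome_length=genome_length)


def write_bed6(models: GeneModelSet, path) -> None:
    """Gene spans as BED6 (name = gene_id, score = 0)."""
    rows = [
        f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}"
        for g in models
    ]
    Path(path).write_text("\n".join(rows) + "\n")


def read_bed(path) -> pd.DataFrame:
    """BED3+ into a chrom/start/end[/name/score/strand] frame."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    try:
        df = pd.read_csv(str(path), sep="\t", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error context
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    df.columns = names[: df.shape[1]]
    return df


def write_intervals_bed(intervals, path, chrom: str = "chr1") -> None:
    Path(path).write_text(
        "".join(f"{chrom}\t{s}\t{e}\n" for s, e in intervals)
    )


# --- tables -----------------------------------------------------------------

def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    matrix.to_long().to_csv(path, sep="\t", index=False)


def read_expression_tsv(path, smoker: Dict[str, bool] | None = None) -> ExpressionMatrix:
    long = pd.read_csv(path, sep="\t")
    required = {"gene_id", "subject", "region", "fpkm"}
    if not required.issubset(long.columns):
        raise FormatError(
            f"{path}: expression TSV needs columns {sorted(required)}"
        )
    return ExpressionMatrix.from_long(long, smoker=smoker)


def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# --- allele counts ----------------------------------------------------------

ALLELE_COLUMNS = ["rsid", "chrom", "pos", "subject", "region",
                  "ref_count", "alt_count"]


def write_allele_counts_tsv(table: pd.DataFrame, path) -> None:
    table[ALLELE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_allele_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALLELE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: allele-count TSV lacks columns {missing}")
    return df


def write_het_tsv(het: pd.DataFrame, path) -> None:
    het[["subject", "rsid"]].to_csv(path, sep="\t", index=False)


def read_het_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"subject", "rsid"}.issubset(df.columns):
        raise FormatError(f"{path}: genotype TSV needs subject and rsid columns")
    return df


def write_allele_counts_vcf(table: pd.DataFrame, path,
                            contig_length: int | None = None) -> None:
    """Minimal VCF with one sample column per (subject, region) and AD counts.

    Alleles are placeholders (A/G) — only positions, ids, and allelic
    depths are meaningful.
    """
    t = table.copy()
    t["sample"] = t["subject"].astype(str) + "." + t["region"].astype(str)
    samples = sorted(t["sample"].unique())
    chrom = str(t["chrom"].iloc[0]) if len(t) else "chr1"
    length = contig_length or (int(t["pos"].max()) + 1000 if len(t) else 1000)
    header = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={chrom},length={length}>",
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples),
    ]
    lines = []
    piv = t.pivot_table(index=["chrom", "pos", "rsid"], columns="sample",
                        values=["ref_count", "alt_count"], aggfunc="first")
    for (c, pos, rsid), row in piv.iterrows():
        fields = []
        for s in samples:
            ref = row.get(("ref_count", s))
            alt = row.get(("alt_count", s))
            if pd.isna(ref):
                fields.append(".")
            else:
                fields.append(f"{int(ref)},{int(alt)}")
        lines.append(
            f"{c}\t{int(pos) + 1}\t{rsid}\tA\tG\t.\t.\t.\tAD\t" + "\t".join(fields)
        )
    Path(path).write_text("\n".join(header + lines) + "\n")


def read_allele_counts_vcf(path) -> pd.DataFrame:
    """Parse a minimal AD-carrying VCF back into the long allele-count frame."""
    from cyvcf2 import VCF

    v = VCF(str(path))
    samples = v.samples
    rows = []
    for rec in v:
        ad = rec.format("AD")
        for i, sample in enumerate(samples):
            if ad is None or ad[i][0] < 0:
                continue
            subject, region = sample.split(".", 1)
            rows.append(
                (rec.ID, rec.CHROM, rec.POS - 1, subject, region,
                 int(ad[i][0]), int(ad[i][1]))
            )
    return pd.DataFrame(rows, columns=ALLELE_COLUMNS)


# --- ground truth -----------------------------------------------------------

def write_ground_truth(truth: GroundTruth, path) -> None:
    Path(path).write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))


def read_ground_truth(path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(**data)
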