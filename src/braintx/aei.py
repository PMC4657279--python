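"""Allelic expression imbalance (AEI) calling from heterozygous-SNP read counts.

A gene expressed unevenly from its two alleles in a heterozygous subject
betrays a cis-acting regulatory variant.  The caller works on per-(SNP,
subject, region) reference/alternate read counts and applies a filter
cascade before measuring imbalance per (gene, subject, region):

1. keep rows at SNPs genotyped heterozygous for that subject;
2. keep rows with combined coverage ref + alt >= 10 reads;
3. keep (subject, SNP) pairs that pass the coverage filter in >= 3
   regions of the same subject (recurrent, hence reliably measurable);
4. assign SNPs to gene bins — gene spans padded 1 kb both sides; a SNP
   may fall in several overlapping bins and is then scored in each;
5. per (gene, subject, region), require >= 2 retained SNPs with pairwise
   genomic distance > 50 bases (longer than one read, so measurements
   are independent); when spacing conflicts arise a maximal spaced
   subset is chosen greedily by descending depth (ties to the lower
   coordinate).

For each surviving (gene, subject, region) the per-SNP allelic ratio is
folded, r = max(ref, alt) / min(ref, alt) (phase is unknown, so only the
magnitude of imbalance is meaningful), and the gene-level call carries
the arithmetic mean folded ratio, the mean depth per SNP, and the lower
bound of a 95% confidence interval for the mean computed on log2(r) with
a t-distribution (n_snps - 1 df) and back-transformed.  Tiers:

* ``aei_2fold``          — CI lower bound > 2 (twofold imbalance);
* ``aei_2fold_30reads``  — additionally mean depth per SNP >= 30 reads.

A zero minor-allele count gets the Haldane-Anscombe 0.5 pseudocount on
both alleles before the ratio, so ratios are always finite.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Tuple

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

TIER_NONE = "none"
TIER_2FOLD = "aei_2fold"
TIER_STRINGENT = "aei_2fold_30reads"

REQUIRED_COLUMNS = ["rsid", "chrom", "pos", "subject", "region",
                    "ref_count", "alt_count"]


@dataclass
class GeneBin:
    """Gene span padded symmetrically for SNP assignment."""

    gene_id: str
    chrom: str
    start: int
    end: int

    @classmethod
    def from_span(cls, gene_id: str, chrom: str, start: int, end: int,
                  pad: int = 1000) -> "GeneBin":
        return cls(gene_id=gene_id, chrom=chrom,
                   start=max(0, start - pad), end=end + pad)


def make_gene_bins(spans: pd.DataFrame, pad: int = 1000) -> List[GeneBin]:
    """Pad gene spans (columns chrom/start/end/gene_id) into bins."""
    return [
        GeneBin.from_span(r.gene_id, r.chrom, int(r.start), int(r.end), pad)
        for r in spans.itertuples()
    ]


def assign_snps_to_bins(snps: pd.DataFrame, bins: Iterable[GeneBin]) -> pd.DataFrame:
    """Map each SNP to every bin containing its position.

    ``snps`` needs columns rsid/chrom/pos.  Returns a (rsid, gene_id)
    frame with one row per assignment; SNPs falling in no bin are
    dropped.
    """
    trees: Dict[str, IntervalTree] = {}
    for b in bins:
        if b.end > b.start:
            trees.setdefault(b.chrom, IntervalTree()).addi(b.start, b.end, b.gene_id)
    uniq = snps[["rsid", "chrom", "pos"]].drop_duplicates()
    rows = []
    for r in uniq.itertuples():
        tree = trees.get(r.chrom)
        if tree is None:
            continue
        for hit in sorted(tree[int(r.pos)]):
            rows.append((r.rsid, hit.data))
    return pd.DataFrame(rows, columns=["rsid", "gene_id"])


def filter_snp_calls(
    table: pd.DataFrame,
    het: pd.DataFrame,
    min_coverage: int = 10,
    min_regions: int = 3,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the heterozygosity, coverage, and cross-region recurrence filters.

    ``het`` is a (subject, rsid) frame listing heterozygous genotype
    calls.  Returns the surviving rows plus an attrition ledger whose
    drop counts sum exactly to rows_in - rows_out.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"allele-count table lacks columns {missing}")
    attrition = {"rows_in": len(table)}
    het_pairs = pd.MultiIndex.from_frame(het[["subject", "rsid"]])
    keys = pd.MultiIndex.from_frame(table[["subject", "rsid"]])
    is_het = keys.isin(het_pairs)
    attrition["dropped_not_heterozygous"] = int((~is_het).sum())
    t = table.loc[is_het]

    covered = (t["ref_count"] + t["alt_count"]) >= min_coverage
    attrition["dropped_low_coverage"] = int((~covered).sum())
    t = t.loc[covered]

    n_regions = t.groupby(["subject", "rsid"], sort=False)["region"].transform("nunique")
    recurrent = n_regions >= min_regions
    attrition["dropped_region_recurrence"] = int((~recurrent).sum())
    t = t.loc[recurrent]

    attrition["rows_out"] = len(t)
    return t.copy(), attrition


def _spaced_subset(pos: np.ndarray, depth: np.ndarray, min_spacing: int) -> np.ndarray:
    """Greedy maximal subset with pairwise distance >= min_spacing.

    SNPs are admitted in order of descending depth (ties broken toward
    the lower coordinate).
    """
    order = np.lexsort((pos, -depth))
    kept: List[int] = []
    for i in order:
        if all(abs(int(pos[i]) - int(pos[j])) >= min_spacing for j in kept):
            kept.append(i)
    return np.array(sorted(kept), dtype=int)


def gene_level_aei(
    filtered: pd.DataFrame,
    snp_to_gene: pd.DataFrame,
    min_snps: int = 2,
    min_spacing: int = 51,
    fold_cutoff: float = 2.0,
    stringent_depth: float = 30.0,
    conf_level: float = 0.95,
    log_scale_mean: bool = False,
) -> pd.DataFrame:
    """Per-(gene, subject, region) folded allelic-ratio calls with CI tiers.

    ``log_scale_mean`` switches the reported mean from the arithmetic
    mean of folded ratios (default) to the geometric mean.
    """
    merged = filtered.merge(snp_to_gene, on="rsid", how="inner")
    if merged.empty:
        return _empty_calls()

    ref = merged["ref_count"].to_numpy(dtype=float)
    alt = merged["alt_count"].to_numpy(dtype=float)
    zero_minor = np.minimum(ref, alt) == 0
    ref = np.where(zero_minor, ref + 0.5, ref)
    alt = np.where(zero_minor, alt + 0.5, alt)
    merged = merged.assign(
        _depth=merged["ref_count"] + merged["alt_count"],
        _ratio=np.maximum(ref, alt) / np.minimum(ref, alt),
        _pseudocount=zero_minor,
    )
    merged["_log2_ratio"] = np.log2(merged["_ratio"])

    # spacing: genes whose full SNP placement is already mutually spaced
    # need no per-sample subset selection
    gene_pos = merged[["gene_id", "rsid", "pos"]].drop_duplicates()
    needs_selection = set()
    for gid, grp in gene_pos.groupby("gene_id", sort=False):
        p = np.sort(grp["pos"].to_numpy())
        if len(p) > 1 and np.diff(p).min() < min_spacing:
            needs_selection.add(gid)

    if needs_selection:
        tricky = merged["gene_id"].isin(needs_selection)
        easy, hard = merged.loc[~tricky], merged.loc[tricky]
        parts = [easy]
        for _, grp in hard.groupby(["gene_id", "subject", "region"], sort=False):
            # one row per SNP position: collapse duplicates (same rsid) first
            grp = grp.sort_values("pos", kind="mergesort")
            idx = _spaced_subset(
                grp["pos"].to_numpy(), grp["_depth"].to_numpy(), min_spacing
            )
            parts.append(grp.iloc[idx])
        merged = pd.concat(parts, ignore_index=True)

    g = merged.groupby(["gene_id", "subject", "region"], sort=False)
    calls = g.agg(
        n_snps=("_ratio", "size"),
        mean_ratio=("_ratio", "mean"),
        geo_log2=("_log2_ratio", "mean"),
        sd_log2=("_log2_ratio", lambda x: x.std(ddof=1)),
        mean_depth=("_depth", "mean"),
        pseudocount_used=("_pseudocount", "any"),
    ).reset_index()
    calls = calls.loc[calls["n_snps"] >= min_snps].reset_index(drop=True)
    if calls.empty:
        return _empty_calls()

    n = calls["n_snps"].to_numpy()
    tcrit = stats.t.ppf(0.5 + conf_level / 2.0, n - 1)
    hw = tcrit * calls["sd_log2"].to_numpy() / np.sqrt(n)
    hw = np.where(np.isnan(hw), 0.0, hw)
    calls["ci_lower_95"] = 2.0 ** (calls["geo_log2"].to_numpy() - hw)
    if log_scale_mean:
        calls["mean_ratio"] = 2.0 ** calls["geo_log2"].to_numpy()

    tier = np.where(
        calls["ci_lower_95"] > fold_cutoff,
        np.where(calls["mean_depth"] >= stringent_depth, TIER_STRINGENT, TIER_2FOLD),
        TIER_NONE,
    )
    calls["tier"] = tier
    cols = ["gene_id", "subject", "region", "n_snps", "mean_ratio",
            "ci_lower_95", "mean_depth", "tier", "pseudocount_used"]
    return calls[cols].sort_values(
        ["gene_id", "subject", "region"], kind="mergesort"
    ).reset_index(drop=True)


def _empty_calls() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["gene_id", "subject", "region", "n_snps", "mean_ratio",
                 "ci_lower_95", "mean_depth", "tier", "pseudocount_used"]
    )


def recurrence_summary(calls: pd.DataFrame, min_subjects: int = 2) -> pd.DataFrame:
    """Genes called at the stringent tier in >= ``min_subjects`` subjects of one region.

    Reports, per (gene, region): the subject count, mean +/- SD of the
    gene-level mean ratios, and the average number of contributing SNPs
    per sample.
    """
    stringent = calls.loc[calls["tier"] == TIER_STRINGENT]
    if stringent.empty:
        return pd.DataFrame(
            columns=["gene_id", "region", "n_subjects", "mean_aei_ratio",
                     "sd_aei_ratio", "avg_snps_per_sample"]
        )
    g = stringent.groupby(["gene_id", "region"], sort=False)
    out = g.agg(
        n_subjects=("subject", "nunique"),
        mean_aei_ratio=("mean_ratio", "mean"),
        sd_aei_ratio=("mean_ratio", lambda x: x.std(ddof=1)),
        avg_snps_per_sample=("n_snps", "mean"),
    ).reset_index()
    out = out.loc[out["n_subjects"] >= min_subjects]
    return out.sort_values(
        ["n_subjects", "mean_aei_ratio"], ascending=[False, False], kind="mergesort"
    ).reset_index(drop=True)


def call_matrix(calls: pd.DataFrame) -> pd.DataFrame:
    """Regions x subjects table of tiers for each gene (diagnostic view)."""
    return calls.pivot_table(
        index=["gene_id", "region"], columns="subject", values="tier",
        aggfunc="first",
    )
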