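"""Isoform fractions and cross-region isoform-usage deviation ranking.

The isoform fraction of a transcript in a sample is its FPKM divided by
the summed FPKM of all isoforms of its gene in that sample.  To find
genes whose isoform composition differs between brain regions, each
isoform's fraction is given a 99% normal-approximation band
(mean +/- z_0.995 * SD over all samples); a region whose mean fraction
falls strictly outside the band "deviates".  The gene score is the mean,
over isoforms, of the number of deviating regions — a gene whose major
isoform swaps between region groups deviates in many regions for every
isoform and rises to the top of the ranking.
"""

from __future__ import annotations

from typing import Set

import numpy as np
import pandas as pd
from scipy import stats

ISO_COLUMNS = ["gene_id", "transcript_id", "subject", "region", "fpkm"]


def isoform_fractions(iso_fpkm: pd.DataFrame) -> pd.DataFrame:
    """Add per-sample isoform fractions to a long isoform FPKM table.

    Samples where a gene's total FPKM is zero get NaN fractions and
    ``undefined_fraction=True``; such rows are excluded from downstream
    region means rather than treated as zero usage.
    """
    missing = [c for c in ISO_COLUMNS if c not in iso_fpkm.columns]
    if missing:
        raise ValueError(f"isoform table lacks columns {missing}")
    if (iso_fpkm["fpkm"] < 0).any():
        raise ValueError("negative FPKM in isoform table")
    out = iso_fpkm.copy()
    totals = out.groupby(["gene_id", "subject", "region"], sort=False)[
        "fpkm"
    ].transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        out["fraction"] = np.where(totals > 0, out["fpkm"] / totals, np.nan)
    out["undefined_fraction"] = totals.to_numpy() == 0
    return out


def inclusion_filter(
    gene_fpkm: pd.DataFrame, min_fpkm: float = 5.0, min_libraries: int = 40
) -> Set[str]:
    """Genes with FPKM >= min_fpkm in at least min_libraries libraries.

    ``gene_fpkm`` is a wide genes x libraries frame (both thresholds are
    inclusive).
    """
    n_pass = (gene_fpkm >= min_fpkm).sum(axis=1)
    return set(gene_fpkm.index[n_pass >= min_libraries])


def region_deviation_score(
    fractions: pd.DataFrame,
    included_genes: Set[str] | None = None,
    conf_level: float = 0.99,
    ci_mode: str = "se",
) -> pd.DataFrame:
    """Rank multi-isoform genes by regions deviating from the global fraction band.

    ``ci_mode='se'`` (default) uses the confidence interval of the grand
    mean, mean +/- z * SD / sqrt(N) over all N samples (z two-sided for
    ``conf_level``).  This is the only band under which a strongly
    switching gene deviates in many regions: the switch inflates the
    all-sample SD itself, so a mean +/- z*SD band (``ci_mode='sd'``)
    swallows any region structure and is kept only as a diagnostic
    alternative, as is ``'quantile'`` (empirical ((1-c)/2, 1-(1-c)/2)
    quantiles).  A region mean exactly on a band edge counts as inside.
    Isoforms with fewer than two defined fraction values cannot anchor a
    band and are skipped.  Output is one row per gene sorted by score
    descending (ties by gene id), with the per-isoform deviation counts
    retained for inspection.
    """
    f = fractions.loc[~fractions["undefined_fraction"]]
    if included_genes is not None:
        f = f.loc[f["gene_id"].isin(included_genes)]
    multi = f.groupby("gene_id", sort=False)["transcript_id"].transform("nunique") >= 2
    f = f.loc[multi]
    if f.empty:
        return pd.DataFrame(
            columns=["gene_id", "n_isoforms", "score", "rank"]
        ).set_index("gene_id")

    grp = f.groupby(["gene_id", "transcript_id"], sort=False)["fraction"]
    overall = grp.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="size")
    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    if ci_mode == "se":
        hw = z * overall["sd"] / np.sqrt(overall["n"])
        overall["lo"] = overall["mean"] - hw
        overall["hi"] = overall["mean"] + hw
    elif ci_mode == "sd":
        overall["lo"] = overall["mean"] - z * overall["sd"]
        overall["hi"] = overall["mean"] + z * overall["sd"]
    elif ci_mode == "quantile":
        a = (1.0 - conf_level) / 2.0
        overall["lo"] = grp.quantile(a)
        overall["hi"] = grp.quantile(1.0 - a)
    else:
        raise ValueError(f"unknown ci_mode {ci_mode!r}")
    usable = overall["n"] >= 2

    region_means = (
        f.groupby(["gene_id", "transcript_id", "region"], sort=False)["fraction"]
        .mean()
        .rename("region_mean")
        .reset_index()
        .merge(overall.reset_index(), on=["gene_id", "transcript_id"])
    )
    region_means = region_means.loc[
        region_means.set_index(["gene_id", "transcript_id"]).index.isin(
            usable[usable].index
        )
    ]
    region_means["outside"] = (
        (region_means["region_mean"] < region_means["lo"])
        | (region_means["region_mean"] > region_means["hi"])
    )
    per_iso = (
        region_means.groupby(["gene_id", "transcript_id"], sort=False)["outside"]
        .sum()
        .rename("n_regions_outside")
    )
    score = per_iso.groupby("gene_id").mean().rename("score")
    n_iso = per_iso.groupby("gene_id").size().rename("n_isoforms")
    out = pd.concat([n_iso, score], axis=1).reset_index()
    out = out.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    out.attrs["per_isoform"] = per_iso
    return out.set_index("gene_id")
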