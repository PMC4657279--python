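"""Detectability, region selectivity by RNA class, and expression filters.

Detection of a gene within a region is defined as FPKM strictly above a
cutoff (default 2) in at least a minimum number of subjects (default 2)
of that region.  Counting detected regions per gene and stratifying by
RNA class exposes the broad expression of protein-coding genes versus
the restricted, region-selective expression of non-coding classes.
"""

from __future__ import annotations

import warnings
from typing import Dict, Sequence, Set, Tuple

import pandas as pd

from .models import ExpressionMatrix


def detectability(
    matrix: ExpressionMatrix,
    fpkm_cutoff: float = 2.0,
    min_subjects: int = 2,
    classes: Dict[str, str] | None = None,
) -> pd.DataFrame:
    """Per-gene detected-region profile.

    Returns one row per gene with a boolean column per region, the
    ``regions_detected`` count, per-region mean FPKM columns
    (``mean_<region>``) and, when ``classes`` is given, an ``rna_class``
    column.
    """
    detected = {}
    for region in matrix.regions:
        mask = (matrix.samples["region"] == region).to_numpy()
        sub = matrix.values.loc[:, mask]
        detected[region] = (sub > fpkm_cutoff).sum(axis=1) >= min_subjects
    det = pd.DataFrame(detected)
    out = det.copy()
    out["regions_detected"] = det.sum(axis=1)
    means = matrix.region_means()
    for region in matrix.regions:
        out[f"mean_{region}"] = means[region]
    if classes is not None:
        out["rna_class"] = pd.Series(classes).reindex(out.index)
    out.index.name = "gene_id"
    return out


def class_selectivity_summary(profiles: pd.DataFrame) -> pd.DataFrame:
    """Distribution of regions_detected (1..n) per RNA class.

    Only genes detectable somewhere (regions_detected >= 1) enter the
    denominator; fractions per class sum to 1.  Classes with no
    detectable gene are omitted with a warning.
    """
    if "rna_class" not in profiles.columns:
        raise ValueError("profiles need an 'rna_class' column")
    detectable = profiles.loc[profiles["regions_detected"] >= 1]
    n_regions = int(profiles["regions_detected"].max()) if len(profiles) else 0
    n_regions = max(
        n_regions,
        len([c for c in profiles.columns if c.startswith("mean_")]),
    )
    rows = {}
    for cls, grp in profiles.groupby("rna_class", sort=False):
        d = grp.loc[grp["regions_detected"] >= 1, "regions_detected"]
        if d.empty:
            warnings.warn(f"RNA class {cls!r} has no detectable genes; omitted")
            continue
        counts = d.value_counts().reindex(range(1, n_regions + 1), fill_value=0)
        rows[cls] = counts / counts.sum()
    out = pd.DataFrame(rows).T
    out.index.name = "rna_class"
    out.columns.name = "regions_detected"
    return out


def expression_cutoff_ladder(
    matrix: ExpressionMatrix,
    classes: Dict[str, str],
    cutoffs: Sequence[float] = (2, 5, 10, 50, 100, 500, 1000, 5000),
    per_region: bool = False,
) -> pd.DataFrame:
    """Count genes per class whose average FPKM exceeds each cutoff.

    The default average is the grand mean over all samples; with
    ``per_region`` a gene counts when any region's mean exceeds the
    cutoff.  Cutoffs must be strictly ascending, making the counts
    monotonically non-increasing along the ladder.
    """
    cut = list(cutoffs)
    if any(b <= a for a, b in zip(cut, cut[1:])):
        raise ValueError("cutoffs must be strictly ascending")
    if per_region:
        avg = matrix.region_means().max(axis=1)
    else:
        avg = matrix.values.mean(axis=1)
    cls = pd.Series(classes).reindex(avg.index)
    rows = {}
    for c, grp in avg.groupby(cls, sort=False):
        rows[c] = {cutoff: int((grp > cutoff).sum()) for cutoff in cut}
    out = pd.DataFrame(rows).T
    out.index.name = "rna_class"
    out.columns.name = "fpkm_cutoff"
    return out


def de_inclusion_filters(
    counts: pd.DataFrame,
    mode: str,
    library_sizes: pd.Series | None = None,
    min_reads: int = 10,
    min_samples: int = 8,
    min_cpm: float = 2.0,
) -> Tuple[Set[str], Dict[str, int]]:
    """Inclusion filters used upstream of differential-expression fitting.

    ``mode='region'`` keeps genes with > ``min_reads`` reads in
    > ``min_samples`` samples (both strict).  ``mode='smoking'`` keeps
    genes with CPM >= ``min_cpm`` in *every* sample, where CPM = reads
    per gene / million aligned reads of that sample (``library_sizes``
    indexed by sample, required).  Returns the surviving gene set and an
    attrition ledger.
    """
    attrition = {"genes_in": int(counts.shape[0])}
    if mode == "region":
        keep = (counts > min_reads).sum(axis=1) > min_samples
    elif mode == "smoking":
        if library_sizes is None:
            raise ValueError("smoking mode requires library_sizes per sample")
        sizes = library_sizes.reindex(counts.columns)
        if sizes.isna().any():
            missing = list(sizes.index[sizes.isna()])
            raise ValueError(f"library_sizes missing for samples {missing}")
        cpm = counts / (sizes / 1e6)
        keep = (cpm >= min_cpm).all(axis=1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    survivors = set(counts.index[keep])
    attrition["genes_dropped"] = int((~keep).sum())
    attrition["genes_out"] = len(survivors)
    return survivors, attrition
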