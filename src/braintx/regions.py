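"""Non-overlapping exonic/intronic/intergenic genome partition and read accounting.

The partition follows the standard subtraction scheme: exons of all
transcripts are merged into one exonic set; gene spans minus exons give
introns; the genome minus all gene spans gives the intergenic set.  The
three sets are pairwise disjoint and together cover the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd

from ._intervals import complement, merge, subtract, total_length
from .models import GeneModelSet

Interval = Tuple[int, int]

SET_NAMES = ("exonic", "intronic", "intergenic")


@dataclass
class RegionPartition:
    """Disjoint exonic/intronic/intergenic interval sets covering a genome."""

    exonic: List[Interval]
    intronic: List[Interval]
    intergenic: List[Interval]
    genome_length: int

    @property
    def total_len_kb(self) -> Dict[str, float]:
        return {name: total_length(getattr(self, name)) / 1000.0 for name in SET_NAMES}

    def sets(self) -> Dict[str, List[Interval]]:
        return {name: getattr(self, name) for name in SET_NAMES}

    def label_of_base(self, pos: int) -> str:
        """Set membership of a single base (mainly for oracles/debugging)."""
        if not 0 <= pos < self.genome_length:
            raise ValueError(f"base {pos} outside genome [0,{self.genome_length})")
        for name in SET_NAMES:
            ivs = getattr(self, name)
            i = np.searchsorted([s for s, _ in ivs], pos, side="right") - 1
            if i >= 0 and ivs[i][0] <= pos < ivs[i][1]:
                return name
        raise AssertionError("partition does not cover the genome")


@dataclass
class RegionReadSummary:
    """Read counts, fractions and per-set RPKM over a partition."""

    reads: Dict[str, int]
    fractions: Dict[str, float]
    rpkm: Dict[str, float]
    side_channel_reads: Dict[str, int] = field(default_factory=dict)
    side_channel_fractions: Dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "reads": pd.Series(self.reads),
                "fraction": pd.Series(self.fractions),
                "rpkm": pd.Series(self.rpkm),
            }
        )


def partition_genome(models: GeneModelSet, genome_length: int | None = None) -> RegionPartition:
    """Split the genome into merged exonic, intronic, and intergenic sets.

    Exons are merged across transcripts *and* genes, so bases shared by
    overlapping genes are counted once.  Introns are gene-span bases not
    exonic in any gene; intergenic bases lie outside every gene span.
    """
    if genome_length is None:
        genome_length = models.genome_length
    if models.genes and genome_length < max(g.end for g in models.genes):
        raise ValueError(
            f"genome_length {genome_length} smaller than the furthest gene end"
        )
    exonic = merge(
        iv for g in models for exons in g.transcripts.values() for iv in exons
    )
    spans = merge((g.start, g.end) for g in models)
    intronic = subtract(spans, exonic)
    intergenic = complement(spans, genome_length)
    return RegionPartition(
        exonic=exonic,
        intronic=intronic,
        intergenic=intergenic,
        genome_length=genome_length,
    )


def _assign_midpoint(
    partition: RegionPartition, reads: Sequence[Interval]
) -> Dict[str, int]:
    """Count reads per set by the midpoint base of each read."""
    counts = {name: 0 for name in SET_NAMES}
    # flatten the partition into sorted labelled boundaries for O(log n) lookup
    starts, labels = [], []
    for name in SET_NAMES:
        for s, e in getattr(partition, name):
            starts.append(s)
            labels.append(name)
    order = np.argsort(starts)
    starts_arr = np.asarray(starts)[order]
    labels_arr = np.asarray(labels)[order]
    mids = np.asarray([(s + e) // 2 for s, e in reads])
    if len(mids):
        if mids.min() < 0 or mids.max() >= partition.genome_length:
            bad = mids[(mids < 0) | (mids >= partition.genome_length)][0]
            raise ValueError(f"read midpoint {bad} outside the genome")
        idx = np.searchsorted(starts_arr, mids, side="right") - 1
        for name, n in zip(*np.unique(labels_arr[idx], return_counts=True)):
            counts[str(name)] = int(n)
    return counts


def _assign_priority(
    partition: RegionPartition, reads: Sequence[Interval]
) -> Dict[str, int]:
    """Count reads per set by any-overlap with priority exonic > intronic > intergenic."""
    counts = {name: 0 for name in SET_NAMES}
    sets = {name: getattr(partition, name) for name in SET_NAMES}
    starts = {name: np.asarray([s for s, _ in sets[name]]) for name in SET_NAMES}
    for s, e in reads:
        if s < 0 or e > partition.genome_length:
            raise ValueError(f"read [{s},{e}) outside the genome")
        hit = None
        for name in SET_NAMES:
            ivs = sets[name]
            i = int(np.searchsorted(starts[name], e, side="left")) - 1
            if i >= 0 and ivs[i][1] > s:
                hit = name
                break
        counts[hit or "intergenic"] += 1
    return counts


def summarize_reads(
    partition: RegionPartition,
    reads: Sequence[Interval] | Iterable[Tuple[str, int, int]],
    total_mapped: int,
    assignment: str = "midpoint",
    main_chrom: str | None = None,
) -> RegionReadSummary:
    """Assign each read to exactly one set and summarize counts/fractions/RPKM.

    ``reads`` may be (start, end) pairs, or (chrom, start, end) triples
    when ``main_chrom`` is given; reads on other sequence names (e.g. a
    mitochondrial contig) are tallied in a side channel and excluded from
    the three-way fractions, mirroring the separate reporting of
    mitochondrial and ribosomal reads.

    RPKM per set = reads in set / (set length in kb x total mapped reads
    in millions); an empty set has RPKM 0 by convention.
    """
    if total_mapped <= 0:
        raise ValueError("total_mapped must be positive")
    side: Dict[str, int] = {}
    main_reads: List[Interval] = []
    for row in reads:
        if len(row) == 3:
            chrom, s, e = row
            if main_chrom is not None and chrom != main_chrom:
                side[chrom] = side.get(chrom, 0) + 1
                continue
            main_reads.append((s, e))
        else:
            main_reads.append(tuple(row))  # type: ignore[arg-type]

    if assignment == "midpoint":
        counts = _assign_midpoint(partition, main_reads)
    elif assignment == "priority":
        counts = _assign_priority(partition, main_reads)
    else:
        raise ValueError(f"unknown assignment rule {assignment!r}")

    n_main = sum(counts.values())
    fractions = {
        name: (counts[name] / n_main if n_main else 0.0) for name in SET_NAMES
    }
    lengths_kb = partition.total_len_kb
    rpkm = {
        name: (
            counts[name] / (lengths_kb[name] * total_mapped / 1e6)
            if lengths_kb[name] > 0
            else 0.0
        )
        for name in SET_NAMES
    }
    total_all = n_main + sum(side.values())
    side_frac = {
        k: (v / total_all if total_all else 0.0) for k, v in sorted(side.items())
    }
    return RegionReadSummary(
        reads=counts,
        fractions=fractions,
        rpkm=rpkm,
        side_channel_reads=dict(sorted(side.items())),
        side_channel_fractions=side_frac,
    )
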