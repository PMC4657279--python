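"""Core data containers shared across the pipeline.

Coordinates are 0-based half-open everywhere inside the package (BED
convention); conversion to 1-based inclusive systems (GTF, VCF) happens
only at the I/O boundary in :mod:`braintx.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import pandas as pd

from ._intervals import merge

Interval = Tuple[int, int]


class AnnotationError(ValueError):
    """Raised when a gene model is internally inconsistent."""


@dataclass
class GeneModel:
    """A gene locus: class label, strand, span, and exon-level transcripts."""

    gene_id: str
    rna_class: str
    chrom: str
    strand: str
    start: int
    end: int
    transcripts: Dict[str, List[Interval]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tx_id, exons in self.transcripts.items():
            exons.sort()
            for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
                if s2 < e1:
                    raise AnnotationError(
                        f"transcript {tx_id} of {self.gene_id} has overlapping "
                        f"exons [{s1},{e1}) and [{s2},{e2})"
                    )
            for s, e in exons:
                if s < self.start or e > self.end:
                    raise AnnotationError(
                        f"exon [{s},{e}) of {tx_id} lies outside the span "
                        f"[{self.start},{self.end}) of gene {self.gene_id}"
                    )

    @property
    def merged_exons(self) -> List[Interval]:
        """Union of exons over all transcripts of this gene."""
        return merge(iv for exons in self.transcripts.values() for iv in exons)

    @property
    def span(self) -> Interval:
        return self.start, self.end


@dataclass
class GeneModelSet:
    """A collection of gene models on one toy genome."""

    genes: List[GeneModel]
    genome_length: int

    def __post_init__(self) -> None:
        if self.genes:
            top = max(g.end for g in self.genes)
            if self.genome_length < top:
                raise AnnotationError(
                    f"genome_length {self.genome_length} < max gene end {top}"
                )

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)

    def by_id(self) -> Dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def spans(self) -> pd.DataFrame:
        """BED-like frame of gene spans (one row per gene)."""
        return pd.DataFrame(
            {
                "chrom": [g.chrom for g in self.genes],
                "start": [g.start for g in self.genes],
                "end": [g.end for g in self.genes],
                "gene_id": [g.gene_id for g in self.genes],
                "rna_class": [g.rna_class for g in self.genes],
                "strand": [g.strand for g in self.genes],
            }
        )


@dataclass
class ExpressionMatrix:
    """FPKM values for genes x samples with (subject, region, smoker) labels.

    ``values`` is a wide frame indexed by gene_id with one column per
    sample id; ``samples`` is indexed by the same sample ids and carries
    ``subject``, ``region`` and boolean ``smoker`` columns.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.samples.index):
            self.samples = self.samples.loc[self.values.columns]
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")
        for col in ("subject", "region"):
            if col not in self.samples.columns:
                raise ValueError(f"sample table lacks a '{col}' column")

    @property
    def regions(self) -> List[str]:
        return list(pd.unique(self.samples["region"]))

    @property
    def subjects(self) -> List[str]:
        return list(pd.unique(self.samples["subject"]))

    def region_means(self) -> pd.DataFrame:
        """Mean FPKM per gene per region (averaged over subjects)."""
        return self.values.T.groupby(self.samples["region"], sort=False).mean().T

    def region_values(self, gene_id: str) -> pd.DataFrame:
        """regions x subjects table of one gene's FPKM."""
        row = self.values.loc[gene_id]
        frame = pd.DataFrame(
            {
                "subject": self.samples["subject"],
                "region": self.samples["region"],
                "fpkm": row.to_numpy(),
            }
        )
        return frame.pivot_table(
            index="region", columns="subject", values="fpkm", sort=False
        )

    def to_long(self) -> pd.DataFrame:
        long = self.values.reset_index(names="gene_id").melt(
            id_vars="gene_id", var_name="sample_id", value_name="fpkm"
        )
        long["subject"] = self.samples.loc[long["sample_id"], "subject"].to_numpy()
        long["region"] = self.samples.loc[long["sample_id"], "region"].to_numpy()
        return long[["gene_id", "subject", "region", "fpkm"]]

    @classmethod
    def from_long(
        cls, long: pd.DataFrame, smoker: Dict[str, bool] | None = None
    ) -> "ExpressionMatrix":
        long = long.copy()
        long["sample_id"] = long["subject"].astype(str) + "." + long["region"].astype(str)
        values = long.pivot_table(
            index="gene_id", columns="sample_id", values="fpkm", sort=False
        )
        samples = (
            long[["sample_id", "subject", "region"]]
            .drop_duplicates("sample_id")
            .set_index("sample_id")
            .loc[values.columns]
        )
        samples["smoker"] = (
            samples["subject"].map(smoker) if smoker else False
        )
        return cls(values=values, samples=samples)
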