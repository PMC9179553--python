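"""Core genomic domain types shared by every stage of the pipeline.

All coordinates are 0-based half-open (BED convention). Formats with other
conventions (GTF) are translated at the I/O boundary, never internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

VALID_STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic span ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def overlaps(self, other: "GenomicInterval", min_bp: int = 1) -> bool:
        return self.overlap_bp(other) >= min_bp

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def distance_to_point(self, pos: int) -> int:
        """Gap in bp between this span and a point; 0 when the point is inside.

        Distances on the right are measured from the last included base
        (``end - 1``), so a point one base past the span has distance 1.
        """
        if self.contains_point(pos):
            return 0
        if pos < self.start:
            return self.start - pos
        return pos - (self.end - 1)


@dataclass(frozen=True)
class Peak:
    """A ChIP-seq peak call. ``summit_offset`` is bp from ``interval.start``."""

    interval: GenomicInterval
    peak_id: str
    score: float | None = None
    summit_offset: int | None = None

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def midpoint(self) -> int:
        return self.interval.midpoint


@dataclass(frozen=True)
class GeneModel:
    """One gene with strand-aware TSS/TES and exon/UTR block structure.

    ``interval`` is the TSS-to-TES extent (gene body). ``exons`` are
    non-overlapping, sorted, and contained in the body. UTR blocks, when a
    coding region is known, are the exonic sequence outside the CDS extent.
    """

    gene_id: str
    gene_name: str
    interval: GenomicInterval
    strand: str
    exons: tuple[GenomicInterval, ...] = ()
    utr5: tuple[GenomicInterval, ...] = ()
    utr3: tuple[GenomicInterval, ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError("gene strand must be '+' or '-'")
        prev_end = None
        for ex in self.exons:
            if not self.interval.contains(ex):
                raise ValueError(
                    f"{self.gene_id}: exon {ex} outside gene body {self.interval}"
                )
            if prev_end is not None and ex.start < prev_end:
                raise ValueError(f"{self.gene_id}: exons unsorted or overlapping")
            prev_end = ex.end

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def tss(self) -> int:
        """Transcription start site: first transcribed base."""
        return self.interval.start if self.strand == "+" else self.interval.end - 1

    @property
    def tes(self) -> int:
        """Transcription end site: last transcribed base (inclusive position)."""
        return self.interval.end - 1 if self.strand == "+" else self.interval.start

    def promoter(self, halfwidth: int) -> GenomicInterval:
        """Window ``[tss - halfwidth, tss + halfwidth)`` clipped at 0."""
        return GenomicInterval(
            self.chrom, max(0, self.tss - halfwidth), self.tss + halfwidth
        )


@dataclass(frozen=True)
class Loop:
    """A chromatin loop: two anchor intervals on one chromosome."""

    loop_id: str
    chrom: str
    left_anchor: GenomicInterval
    right_anchor: GenomicInterval

    def __post_init__(self) -> None:
        if self.left_anchor.chrom != self.chrom or self.right_anchor.chrom != self.chrom:
            raise ValueError(f"{self.loop_id}: anchors must lie on {self.chrom}")
        if self.left_anchor.end > self.right_anchor.start:
            raise ValueError(
                f"{self.loop_id}: left anchor must end before right anchor starts"
            )

    @property
    def extent(self) -> int:
        return self.right_anchor.end - self.left_anchor.start


class ExpressionMatrix:
    """Genes x samples RPKM values with a sample -> (group, donor) design.

    ``values`` is a DataFrame indexed by gene id with one column per sample;
    ``design`` is indexed by sample id with columns ``group`` and ``donor``.
    """

    def __init__(self, values: pd.DataFrame, design: pd.DataFrame):
        if values.index.duplicated().any():
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if (values.to_numpy() < 0).any():
            raise ValueError("RPKM values must be non-negative")
        missing = [s for s in values.columns if s not in design.index]
        if missing:
            raise ValueError(f"samples absent from design: {missing}")
        if "group" not in design.columns:
            raise ValueError("design must have a 'group' column")
        design = design.loc[list(values.columns)]
        if design["group"].nunique() < 2:
            raise ValueError("design must contain at least two groups")
        self.values = values.astype(float)
        self.design = design

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.design["group"]:
            seen.setdefault(g, None)
        return list(seen)

    def samples_in_group(self, group: str) -> list[str]:
        return list(self.design.index[self.design["group"] == group])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.design)

    def drop_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.values.columns if s not in set(sample_ids)]
        return ExpressionMatrix(self.values[keep], self.design.loc[keep])

    def max_per_gene(self) -> pd.Series:
        """Per-gene maximum RPKM over all samples (the 'MAX' statistic)."""
        return self.values.max(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.design.copy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ExpressionMatrix):
            return NotImplemented
        return self.values.equals(other.values) and self.design.equals(other.design)

    def __repr__(self) -> str:
        return (
            f"ExpressionMatrix({len(self.gene_ids)} genes x "
            f"{len(self.sample_ids)} samples, groups={self.groups})"
        )


def group_by_chrom(items, key):
    """Bucket items by chromosome name; preserves input order within buckets."""
    out: dict[str, list] = {}
    for it in items:
        out.setdefault(key(it), []).append(it)
    return out
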