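"""Classify peak locations relative to gene models (PAVIS-style).

Each peak is reduced to its midpoint and assigned exactly one category:
a gene-body feature (5'UTR > coding exon > 3'UTR > intron, in that priority)
of a gene whose body contains the midpoint, else a strand-aware
upstream/downstream distance bin of the nearest gene ((0,5kb] and (5kb,25kb]),
else distal (>25 kb). The midpoint reference makes the categories a true
partition of the peak set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .core import GeneModel, GenomicInterval, Peak, group_by_chrom

logger = logging.getLogger(__name__)

GENE_BODY_CATEGORIES = ("5utr", "exon", "3utr", "intron")
CATEGORIES = GENE_BODY_CATEGORIES + (
    "upstream_0_5kb",
    "upstream_5_25kb",
    "downstream_0_5kb",
    "downstream_5_25kb",
    "distal_gt_25kb",
)
NEAR_BIN_BP = 5_000
FAR_BIN_BP = 25_000
_PRIORITY = {c: i for i, c in enumerate(GENE_BODY_CATEGORIES)}


@dataclass(frozen=True)
class PeakLocationCall:
    peak_id: str
    category: str
    assigned_gene: str | None
    distance_bp: int  # 0 inside a gene body; negative upstream, positive downstream


@dataclass(frozen=True)
class LocationSummary:
    counts: dict[str, int]
    fractions: dict[str, float]
    gene_body_fraction: float
    n_peaks: int


def _coding_blocks(gene: GeneModel) -> list[GenomicInterval]:
    """Exon sequence minus UTR blocks; whole exons when no CDS is annotated."""
    utrs = list(gene.utr5) + list(gene.utr3)
    if not utrs:
        return list(gene.exons)
    from .io_formats import _subtract_blocks

    return _subtract_blocks(list(gene.exons), utrs)


def _feature_at(gene: GeneModel, pos: int) -> str | None:
    """Gene-body feature containing ``pos``, or None if outside the body."""
    if not gene.interval.contains_point(pos):
        return None
    for block in gene.utr5:
        if block.contains_point(pos):
            return "5utr"
    for block in _coding_blocks(gene):
        if block.contains_point(pos):
            return "exon"
    for block in gene.utr3:
        if block.contains_point(pos):
            return "3utr"
    return "intron"


def _flank_relation(gene: GeneModel, pos: int) -> tuple[str, int] | None:
    """('upstream'|'downstream', gap bp) for a position outside the gene body."""
    iv = gene.interval
    if iv.contains_point(pos):
        return None
    if pos < iv.start:
        gap = iv.start - pos
        side = "upstream" if gene.strand == "+" else "downstream"
    else:
        gap = pos - (iv.end - 1)
        side = "downstream" if gene.strand == "+" else "upstream"
    return side, gap


def annotate_peak_location(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    overlap_mode: str = "midpoint",
) -> list[PeakLocationCall]:
    """Assign each peak one location category relative to the gene models.

    ``overlap_mode='midpoint'`` (default) classifies the peak midpoint;
    ``'any'`` lets any base of the peak claim a gene-body feature (the best
    feature over the peak's span), with flank bins still midpoint-based.
    """
    if overlap_mode not in {"midpoint", "any"}:
        raise ValueError("overlap_mode must be 'midpoint' or 'any'")
    if not genes:
        logger.warning("empty gene set: all peaks classified distal_gt_25kb")
        return [
            PeakLocationCall(p.peak_id, "distal_gt_25kb", None, 0) for p in peaks
        ]
    genes_by_chrom = group_by_chrom(genes, key=lambda g: g.chrom)
    calls = []
    for peak in peaks:
        calls.append(
            _classify_one(peak, genes_by_chrom.get(peak.chrom, []), overlap_mode)
        )
    return calls


def _feature_over_span(gene: GeneModel, iv: GenomicInterval) -> str | None:
    """Best-priority gene-body feature any base of ``iv`` falls in."""
    if not gene.interval.overlaps(iv):
        return None
    if any(b.overlaps(iv) for b in gene.utr5):
        return "5utr"
    if any(b.overlaps(iv) for b in _coding_blocks(gene)):
        return "exon"
    if any(b.overlaps(iv) for b in gene.utr3):
        return "3utr"
    return "intron"


def _classify_one(
    peak: Peak, chrom_genes: Sequence[GeneModel], overlap_mode: str
) -> PeakLocationCall:
    mid = peak.midpoint
    best: tuple[int, str, str] | None = None  # (priority, gene_id, category)
    for gene in chrom_genes:
        if overlap_mode == "midpoint":
            feature = _feature_at(gene, mid)
        else:
            feature = _feature_over_span(gene, peak.interval)
        if feature is None:
            continue
        cand = (_PRIORITY[feature], gene.gene_id, feature)
        if best is None or cand < best:
            best = cand
    if best is not None:
        return PeakLocationCall(peak.peak_id, best[2], best[1], 0)
    nearest: tuple[int, str, str] | None = None  # (gap, gene_id, side)
    for gene in chrom_genes:
        rel = _flank_relation(gene, mid)
        if rel is None:
            continue
        side, gap = rel
        cand = (gap, gene.gene_id, side)
        if nearest is None or cand < nearest:
            nearest = cand
    if nearest is None or nearest[0] > FAR_BIN_BP:
        gene_id = None if nearest is None else nearest[1]
        dist = 0 if nearest is None else nearest[0]
        if nearest is not None:
            dist = -dist if nearest[2] == "upstream" else dist
        return PeakLocationCall(peak.peak_id, "distal_gt_25kb", gene_id, dist)
    gap, gene_id, side = nearest
    bin_name = "0_5kb" if gap <= NEAR_BIN_BP else "5_25kb"
    signed = -gap if side == "upstream" else gap
    return PeakLocationCall(peak.peak_id, f"{side}_{bin_name}", gene_id, signed)


def summarize_locations(calls: Sequence[PeakLocationCall]) -> LocationSummary:
    """Per-category counts/fractions plus the aggregate gene-body fraction."""
    if not calls:
        raise ValueError("no location calls to summarize")
    counts = {c: 0 for c in CATEGORIES}
    for call in calls:
        counts[call.category] += 1
    n = len(calls)
    fractions = {c: counts[c] / n for c in CATEGORIES}
    gene_body = sum(fractions[c] for c in GENE_BODY_CATEGORIES)
    return LocationSummary(counts, fractions, gene_body, n)
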