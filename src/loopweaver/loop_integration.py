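"""Loop-mediated peak-gene assignment: the pipeline's central procedure.

Each chromatin loop is decomposed into a left anchor, a right anchor, and the
span between them. A ChIP peak can then relate to a gene in four ways:

* ``direct``       - the peak intersects the gene's promoter window
                     (TSS +/- halfwidth), no loop involved;
* ``anchor_anchor``- the peak overlaps one anchor and the gene's TSS lies in
                     the opposite anchor of the same loop;
* ``anchor_span``  - the peak overlaps an anchor and the gene's TSS lies
                     strictly inside that loop's span;
* ``span_anchor``  - the peak lies strictly inside the span and the gene's
                     TSS lies in either anchor.

Peak membership in an anchor is any-overlap (>= 1 bp); gene membership is
TSS containment. Span membership is the strict interior: a peak straddling an
anchor/span boundary counts as anchor, never both. A (peak, gene) pair may
hold several categories across loops; each qualifying
(peak, gene, category, loop) tuple is emitted exactly once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, Loop, Peak, group_by_chrom
from .cistrome_overlap import ClosestGeneAssignment, baseline_gene_set

CATEGORIES = ("direct", "anchor_anchor", "anchor_span", "span_anchor")
DEFAULT_PROMOTER_HALFWIDTH = 2_500
_CAT_ORDER = {c: i for i, c in enumerate(CATEGORIES)}


@dataclass(frozen=True)
class LoopParts:
    loop_id: str
    left_anchor: GenomicInterval
    right_anchor: GenomicInterval
    span: GenomicInterval | None  # None when anchors are adjacent (zero width)

    @property
    def chrom(self) -> str:
        return self.left_anchor.chrom

    @property
    def zero_span(self) -> bool:
        return self.span is None


@dataclass(frozen=True)
class AssignmentRecord:
    peak_id: str
    gene_id: str
    category: str
    loop_id: str | None  # None only for 'direct'
    peak_location: str   # left_anchor / right_anchor / span / promoter
    gene_location: str


@dataclass(frozen=True)
class CategoryTally:
    genes_total: dict[str, int]          # expressed genes with >=1 assignment
    genes_deg: dict[str, int]
    deg_genes: dict[str, frozenset[str]]  # per-category DEG gene ids
    union_deg_genes: frozenset[str]       # deduplicated across categories


@dataclass(frozen=True)
class CaptureComparison:
    genes_total: dict[str, int]
    genes_deg: dict[str, int]
    genes_deg_captured: dict[str, int]   # also found by closest-gene baseline
    union_deg: int
    union_captured: int


def derive_loop_parts(loops: Sequence[Loop]) -> list[LoopParts]:
    """Split each loop into anchors and the connecting span
    ``[left_anchor.end, right_anchor.start)``; adjacent anchors give a
    zero-width (None) span."""
    parts = []
    for lp in loops:
        if lp.left_anchor.end == lp.right_anchor.start:
            span = None
        else:
            span = GenomicInterval(lp.chrom, lp.left_anchor.end, lp.right_anchor.start)
        parts.append(LoopParts(lp.loop_id, lp.left_anchor, lp.right_anchor, span))
    return parts


def shared_loops(
    donor_loop_sets: Sequence[Sequence[Loop]],
    anchor_overlap_bp: int = 1,
    mode: str = "union",
) -> list[Loop]:
    """Loops present in every donor set: left anchors overlap by
    >= ``anchor_overlap_bp`` AND right anchors do, across all sets. The shared
    loop takes anchor-union coordinates (``mode='intersection'`` for the
    intersection instead)."""
    if len(donor_loop_sets) < 2:
        raise ValueError("shared_loops needs at least two donor loop sets")
    if mode not in {"union", "intersection"}:
        raise ValueError("mode must be 'union' or 'intersection'")
    current = list(donor_loop_sets[0])
    for other in donor_loop_sets[1:]:
        by_chrom = group_by_chrom(other, key=lambda lp: lp.chrom)
        nxt = []
        for lp in current:
            for cand in by_chrom.get(lp.chrom, []):
                if (
                    lp.left_anchor.overlap_bp(cand.left_anchor) >= anchor_overlap_bp
                    and lp.right_anchor.overlap_bp(cand.right_anchor) >= anchor_overlap_bp
                ):
                    nxt.append(_combine_loops(lp, cand, mode))
                    break
        current = nxt
    return current


def _combine_loops(a: Loop, b: Loop, mode: str) -> Loop:
    def comb(x: GenomicInterval, y: GenomicInterval) -> GenomicInterval:
        if mode == "union":
            return GenomicInterval(x.chrom, min(x.start, y.start), max(x.end, y.end))
        return GenomicInterval(x.chrom, max(x.start, y.start), min(x.end, y.end))

    return Loop(a.loop_id, a.chrom, comb(a.left_anchor, b.left_anchor),
                comb(a.right_anchor, b.right_anchor))


def classify_interactions(
    peaks: Sequence[Peak],
    loop_parts: Sequence[LoopParts],
    genes: Sequence[GeneModel],
    promoter_halfwidth: int = DEFAULT_PROMOTER_HALFWIDTH,
    return_diagnostics: bool = False,
):
    """Emit every qualifying (peak, gene, category, loop) tuple once.

    With ``return_diagnostics=True`` also returns the same-anchor side table
    (peak and gene TSS in the same anchor: no category by definition).
    """
    records: dict[tuple, AssignmentRecord] = {}
    diagnostics: set[AssignmentRecord] = set()

    def emit(rec: AssignmentRecord) -> None:
        # one record per (peak, gene, category, loop); first (leftmost) wins
        records.setdefault((rec.peak_id, rec.gene_id, rec.category, rec.loop_id), rec)

    peaks_by_chrom = group_by_chrom(peaks, key=lambda p: p.chrom)
    peak_trees: dict[str, IntervalTree] = {}
    for chrom, plist in peaks_by_chrom.items():
        tree = IntervalTree()
        for p in plist:
            tree.addi(p.interval.start, p.interval.end, p)
        peak_trees[chrom] = tree
    genes_by_chrom = group_by_chrom(genes, key=lambda g: g.chrom)

    # direct: peak overlaps [TSS - hw, TSS + hw), independent of loops
    for gene in genes:
        tree = peak_trees.get(gene.chrom)
        if tree is None:
            continue
        prom = gene.promoter(promoter_halfwidth)
        for iv in tree.overlap(prom.start, prom.end):
            emit(
                AssignmentRecord(iv.data.peak_id, gene.gene_id, "direct",
                                 None, "promoter", "promoter")
            )

    for part in loop_parts:
        tree = peak_trees.get(part.chrom)
        chrom_genes = genes_by_chrom.get(part.chrom, [])
        if tree is None and not chrom_genes:
            continue
        peaks_left = _peaks_overlapping(tree, part.left_anchor)
        peaks_right = _peaks_overlapping(tree, part.right_anchor)
        anchor_ids = {p.peak_id for p in peaks_left} | {p.peak_id for p in peaks_right}
        peaks_span = [
            p
            for p in _peaks_overlapping(tree, part.span)
            if p.peak_id not in anchor_ids
            and part.span is not None
            and part.span.contains(p.interval)
        ]
        genes_left = [g for g in chrom_genes if part.left_anchor.contains_point(g.tss)]
        genes_right = [g for g in chrom_genes if part.right_anchor.contains_point(g.tss)]
        genes_span = (
            [g for g in chrom_genes if part.span.contains_point(g.tss)]
            if part.span is not None
            else []
        )
        for plist, glist, ploc, gloc in (
            (peaks_left, genes_right, "left_anchor", "right_anchor"),
            (peaks_right, genes_left, "right_anchor", "left_anchor"),
        ):
            for p in plist:
                for g in glist:
                    emit(AssignmentRecord(
                        p.peak_id, g.gene_id, "anchor_anchor", part.loop_id, ploc, gloc
                    ))
        for plist, ploc in ((peaks_left, "left_anchor"), (peaks_right, "right_anchor")):
            for p in plist:
                for g in genes_span:
                    emit(AssignmentRecord(
                        p.peak_id, g.gene_id, "anchor_span", part.loop_id, ploc, "span"
                    ))
        for p in peaks_span:
            for glist, gloc in ((genes_left, "left_anchor"), (genes_right, "right_anchor")):
                for g in glist:
                    emit(AssignmentRecord(
                        p.peak_id, g.gene_id, "span_anchor", part.loop_id, "span", gloc
                    ))
        for plist, glist, loc in (
            (peaks_left, genes_left, "left_anchor"),
            (peaks_right, genes_right, "right_anchor"),
        ):
            for p in plist:
                for g in glist:
                    diagnostics.add(AssignmentRecord(
                        p.peak_id, g.gene_id, "same_anchor", part.loop_id, loc, loc
                    ))

    ordered = sorted(
        records.values(),
        key=lambda r: (_CAT_ORDER[r.category], r.peak_id, r.gene_id, r.loop_id or ""),
    )
    if return_diagnostics:
        ordered_diag = sorted(
            diagnostics, key=lambda r: (r.peak_id, r.gene_id, r.loop_id or "")
        )
        return ordered, ordered_diag
    return ordered


def _peaks_overlapping(
    tree: IntervalTree | None, region: GenomicInterval | None
) -> list[Peak]:
    if tree is None or region is None:
        return []
    hits = [iv.data for iv in tree.overlap(region.start, region.end)]
    return sorted(hits, key=lambda p: (p.interval.start, p.peak_id))


def integrate_with_deg(
    assignments: Sequence[AssignmentRecord],
    deg_genes: set[str],
    expressed_genes: set[str],
) -> CategoryTally:
    """Per-category tallies of expressed genes with >= 1 assignment and, of
    those, DEG; plus the cross-category union of DEG genes (each gene counted
    once in the union however many categories it holds)."""
    assigned_ids = {r.gene_id for r in assignments}
    if assigned_ids:
        known = len(assigned_ids & (expressed_genes | deg_genes))
        if known / len(assigned_ids) < 0.5:
            raise ValueError(
                "gene namespace mismatch: more than half of assigned gene ids "
                "are absent from the expression data"
            )
    genes_total, genes_deg, per_cat_deg = {}, {}, {}
    for cat in CATEGORIES:
        cat_genes = {
            r.gene_id for r in assignments
            if r.category == cat and r.gene_id in expressed_genes
        }
        cat_deg = frozenset(cat_genes & deg_genes)
        genes_total[cat] = len(cat_genes)
        genes_deg[cat] = len(cat_deg)
        per_cat_deg[cat] = cat_deg
    union = frozenset().union(*per_cat_deg.values()) if per_cat_deg else frozenset()
    return CategoryTally(genes_total, genes_deg, per_cat_deg, union)


def compare_with_closest_gene(
    tally: CategoryTally,
    closest_assignments: Sequence[ClosestGeneAssignment],
) -> CaptureComparison:
    """How many loop-identified DEG genes the closest-gene baseline also finds.

    The baseline set is every gene that is the nearest gene (by TSS/TES
    distance) to at least one peak within the distance cap.
    """
    baseline = baseline_gene_set(closest_assignments)
    captured = {
        cat: len(genes & baseline) for cat, genes in tally.deg_genes.items()
    }
    union = tally.union_deg_genes
    return CaptureComparison(
        genes_total=dict(tally.genes_total),
        genes_deg=dict(tally.genes_deg),
        genes_deg_captured=captured,
        union_deg=len(union),
        union_captured=len(union & baseline),
    )
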