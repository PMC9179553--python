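"""Peak-set algebra: shared-peak overlap between cistromes and the
closest-gene (TSS/TES within 100 kb) baseline assignment.

Overlap semantics are literal coordinates with a configurable minimum
intersection (default 1 bp); shared peaks are reported as maximal merged
unions of every peak involved in a qualifying overlap.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from intervaltree import IntervalTree

from .core import GeneModel, GenomicInterval, Peak, group_by_chrom

DEFAULT_MAX_DISTANCE = 100_000


@dataclass(frozen=True)
class OverlapResult:
    shared: tuple[Peak, ...]       # merged union intervals of overlapping peaks
    only_a: tuple[Peak, ...]
    only_b: tuple[Peak, ...]
    n_a_overlapping: int           # original A peaks intersecting >=1 B peak
    n_b_overlapping: int
    fraction_of_b_overlapped: float

    @property
    def venn_counts(self) -> dict[str, int]:
        return {
            "only_a": len(self.only_a),
            "shared": len(self.shared),
            "only_b": len(self.only_b),
        }


@dataclass(frozen=True)
class ClosestGeneAssignment:
    peak_id: str
    gene_id: str | None
    distance_bp: int
    within_100kb: bool


def overlap_peak_sets(
    a: Sequence[Peak], b: Sequence[Peak], min_overlap_bp: int = 1
) -> OverlapResult:
    """Intersect two peak sets; a pair overlaps when the intersection is at
    least ``min_overlap_bp``. Peaks touching no peak of the other set are
    reported as only_a/only_b; all others are merged into union intervals."""
    if min_overlap_bp < 1:
        raise ValueError("min_overlap_bp must be >= 1")
    trees_b = _build_trees(b)
    trees_a = _build_trees(a)
    a_hit = [_hits_tree(p, trees_b, min_overlap_bp) for p in a]
    b_hit = [_hits_tree(p, trees_a, min_overlap_bp) for p in b]
    only_a = tuple(p for p, hit in zip(a, a_hit) if not hit)
    only_b = tuple(p for p, hit in zip(b, b_hit) if not hit)
    involved = [p for p, hit in zip(a, a_hit) if hit] + [
        p for p, hit in zip(b, b_hit) if hit
    ]
    shared = tuple(_merge_union(involved))
    n_b_overlapping = sum(b_hit)
    fraction = n_b_overlapping / len(b) if b else 0.0
    return OverlapResult(
        shared, only_a, only_b, sum(a_hit), n_b_overlapping, fraction
    )


def _build_trees(peaks: Sequence[Peak]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for p in peaks:
        trees.setdefault(p.chrom, IntervalTree()).addi(
            p.interval.start, p.interval.end, p
        )
    return trees


def _hits_tree(
    peak: Peak, trees: dict[str, IntervalTree], min_overlap_bp: int
) -> bool:
    tree = trees.get(peak.chrom)
    if tree is None:
        return False
    for iv in tree.overlap(peak.interval.start, peak.interval.end):
        if min(iv.end, peak.interval.end) - max(iv.begin, peak.interval.start) >= min_overlap_bp:
            return True
    return False


def _merge_union(peaks: Sequence[Peak]) -> list[Peak]:
    """Merge overlapping intervals into maximal unions (1 bp contact merges)."""
    by_chrom = group_by_chrom(peaks, key=lambda p: p.chrom)
    merged: list[Peak] = []
    for chrom in sorted(by_chrom):
        spans = sorted((p.interval.start, p.interval.end) for p in by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s < cur_e:  # half-open: touching intervals stay separate
                cur_e = max(cur_e, e)
            else:
                merged.append(_merged_peak(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append(_merged_peak(chrom, cur_s, cur_e))
    return merged


def _merged_peak(chrom: str, start: int, end: int) -> Peak:
    return Peak(GenomicInterval(chrom, start, end), f"merged:{chrom}:{start}-{end}")


def closest_gene_within(
    peaks: Sequence[Peak],
    genes: Sequence[GeneModel],
    max_distance: int = DEFAULT_MAX_DISTANCE,
) -> list[ClosestGeneAssignment]:
    """Assign each peak the nearest gene by min distance to its TSS or TES.

    Distance is 0 when the peak contains the TSS or TES; otherwise the gap
    from the nearest peak edge (last included base on the right). Ties go to
    the smaller gene id; ``within_100kb`` is inclusive of ``max_distance``.
    """
    if not genes:
        raise ValueError("closest_gene_within requires a non-empty gene set")
    genes_by_chrom = group_by_chrom(genes, key=lambda g: g.chrom)
    out = []
    for peak in peaks:
        best: tuple[int, str] | None = None
        for gene in genes_by_chrom.get(peak.chrom, []):
            d = min(
                peak.interval.distance_to_point(gene.tss),
                peak.interval.distance_to_point(gene.tes),
            )
            cand = (d, gene.gene_id)
            if best is None or cand < best:
                best = cand
        if best is None:
            out.append(ClosestGeneAssignment(peak.peak_id, None, 0, False))
        else:
            d, gene_id = best
            out.append(
                ClosestGeneAssignment(peak.peak_id, gene_id, d, d <= max_distance)
            )
    return out


def baseline_gene_set(assignments: Sequence[ClosestGeneAssignment]) -> set[str]:
    """Genes that are the nearest gene to >=1 peak within the distance cap."""
    return {
        a.gene_id for a in assignments if a.gene_id is not None and a.within_100kb
    }
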