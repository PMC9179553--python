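"""Independent naive oracles and random-instance generators for the tests.

Every function here re-derives the expected answer by exhaustive enumeration
(all pairs, per-base membership, triple loops) with logic written separately
from the package implementations it checks.
"""

from __future__ import annotations

import numpy as np

from loopweaver.core import GeneModel, GenomicInterval, Loop, Peak


# ---------------------------------------------------------------------------
# random instances
# ---------------------------------------------------------------------------

def random_peaks(rng, n, chrom="chr1", max_pos=300_000, width_range=(100, 2_000)):
    peaks = []
    for i in range(n):
        w = int(rng.integers(*width_range))
        s = int(rng.integers(0, max(1, max_pos - w)))
        peaks.append(Peak(GenomicInterval(chrom, s, s + w), f"p{i:04d}",
                          float(rng.uniform(1, 100))))
    return peaks


def random_genes(rng, n, chrom="chr1", max_pos=300_000, body_range=(1_000, 12_000)):
    genes = []
    for i in range(n):
        body = int(rng.integers(*body_range))
        s = int(rng.integers(0, max(1, max_pos - body)))
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(1, 4))
        if n_exons == 1:
            exons = [GenomicInterval(chrom, s, s + body)]
        else:
            interior = np.arange(s + 50, s + body - 50, 25)
            cuts = sorted(int(x) for x in rng.choice(
                interior, size=2 * (n_exons - 1), replace=False))
            bounds = [s] + cuts + [s + body]
            exons = [GenomicInterval(chrom, bounds[2 * j], bounds[2 * j + 1])
                     for j in range(n_exons)]
        if rng.random() < 0.7 and body > 400:
            cds_lo, cds_hi = s + 150, s + body - 150
        else:
            cds_lo = cds_hi = None
        from loopweaver.io_formats import _derive_utrs

        utr5, utr3 = _derive_utrs(exons, cds_lo, cds_hi, strand)
        genes.append(GeneModel(
            gene_id=f"g{i:04d}", gene_name=f"G{i:04d}",
            interval=GenomicInterval(chrom, s, s + body, strand),
            strand=strand, exons=tuple(exons), utr5=utr5, utr3=utr3,
        ))
    return genes


def random_loops(rng, n, chrom="chr1", max_pos=300_000,
                 extent_range=(10_000, 80_000), anchor_range=(1_000, 5_000)):
    loops = []
    for i in range(n):
        extent = int(rng.integers(*extent_range))
        wl = int(rng.integers(*anchor_range))
        wr = int(rng.integers(*anchor_range))
        if wl + wr >= extent:
            extent = wl + wr + 1_000
        s = int(rng.integers(0, max(1, max_pos - extent)))
        loops.append(Loop(
            f"l{i:03d}", chrom,
            GenomicInterval(chrom, s, s + wl),
            GenomicInterval(chrom, s + extent - wr, s + extent),
        ))
    return loops


# ---------------------------------------------------------------------------
# naive oracles
# ---------------------------------------------------------------------------

def brute_overlap_pairs(a, b, min_overlap_bp=1):
    """All (peak_a_id, peak_b_id) pairs with intersection >= min_overlap_bp."""
    pairs = set()
    for pa in a:
        for pb in b:
            if pa.chrom != pb.chrom:
                continue
            lo = max(pa.interval.start, pb.interval.start)
            hi = min(pa.interval.end, pb.interval.end)
            if hi - lo >= min_overlap_bp:
                pairs.add((pa.peak_id, pb.peak_id))
    return pairs


def brute_point_distance(start, end, pos):
    if start <= pos < end:
        return 0
    return start - pos if pos < start else pos - (end - 1)


def brute_closest(peaks, genes, max_distance=100_000):
    """Per peak: (gene_id, distance, within) by exhaustive min over genes."""
    out = {}
    for p in peaks:
        best = None
        for g in genes:
            if g.chrom != p.chrom:
                continue
            d = min(
                brute_point_distance(p.interval.start, p.interval.end, g.tss),
                brute_point_distance(p.interval.start, p.interval.end, g.tes),
            )
            if best is None or (d, g.gene_id) < best:
                best = (d, g.gene_id)
        if best is None:
            out[p.peak_id] = (None, 0, False)
        else:
            out[p.peak_id] = (best[1], best[0], best[0] <= max_distance)
    return out


def brute_annotate(peaks, genes):
    """Midpoint location category per peak via per-base feature sets."""
    feature_sets = []
    for g in genes:
        utr5 = set()
        for b in g.utr5:
            utr5.update(range(b.start, b.end))
        utr3 = set()
        for b in g.utr3:
            utr3.update(range(b.start, b.end))
        exonic = set()
        for b in g.exons:
            exonic.update(range(b.start, b.end))
        coding = exonic - utr5 - utr3
        body = set(range(g.interval.start, g.interval.end))
        feature_sets.append((g, utr5, coding, utr3, body))
    priority = {"5utr": 0, "exon": 1, "3utr": 2, "intron": 3}
    out = {}
    for p in peaks:
        mid = (p.interval.start + p.interval.end) // 2
        best = None
        for g, utr5, coding, utr3, body in feature_sets:
            if g.chrom != p.chrom or mid not in body:
                continue
            if mid in utr5:
                cat = "5utr"
            elif mid in coding:
                cat = "exon"
            elif mid in utr3:
                cat = "3utr"
            else:
                cat = "intron"
            cand = (priority[cat], g.gene_id, cat)
            if best is None or cand < best:
                best = cand
        if best is not None:
            out[p.peak_id] = (best[2], best[1], 0)
            continue
        nearest = None
        for g, *_ in feature_sets:
            if g.chrom != p.chrom:
                continue
            iv = g.interval
            if iv.start <= mid < iv.end:
                continue
            if mid < iv.start:
                gap = iv.start - mid
                side = "upstream" if g.strand == "+" else "downstream"
            else:
                gap = mid - (iv.end - 1)
                side = "downstream" if g.strand == "+" else "upstream"
            cand = (gap, g.gene_id, side)
            if nearest is None or cand < nearest:
                nearest = cand
        if nearest is None:
            out[p.peak_id] = ("distal_gt_25kb", None, 0)
        elif nearest[0] > 25_000:
            signed = -nearest[0] if nearest[2] == "upstream" else nearest[0]
            out[p.peak_id] = ("distal_gt_25kb", nearest[1], signed)
        else:
            gap, gid, side = nearest
            bin_name = "0_5kb" if gap <= 5_000 else "5_25kb"
            signed = -gap if side == "upstream" else gap
            out[p.peak_id] = (f"{side}_{bin_name}", gid, signed)
    return out


def brute_classify(peaks, loops, genes, promoter_halfwidth=2_500):
    """(peak, gene, category, loop) tuples via an exhaustive triple loop."""
    tuples = set()
    for p in peaks:
        ps, pe = p.interval.start, p.interval.end
        for g in genes:
            if g.chrom != p.chrom:
                continue
            if ps < g.tss + promoter_halfwidth and pe > g.tss - promoter_halfwidth:
                tuples.add((p.peak_id, g.gene_id, "direct", None))
        for lp in loops:
            if lp.chrom != p.chrom:
                continue
            la, ra = lp.left_anchor, lp.right_anchor
            in_left = min(pe, la.end) - max(ps, la.start) >= 1
            in_right = min(pe, ra.end) - max(ps, ra.start) >= 1
            span_lo, span_hi = la.end, ra.start
            in_span = (
                not in_left and not in_right
                and span_hi > span_lo
                and ps >= span_lo and pe <= span_hi
            )
            for g in genes:
                if g.chrom != lp.chrom:
                    continue
                t = g.tss
                g_left = la.start <= t < la.end
                g_right = ra.start <= t < ra.end
                g_span = span_lo <= t < span_hi
                if (in_left and g_right) or (in_right and g_left):
                    tuples.add((p.peak_id, g.gene_id, "anchor_anchor", lp.loop_id))
                if (in_left or in_right) and g_span:
                    tuples.add((p.peak_id, g.gene_id, "anchor_span", lp.loop_id))
                if in_span and (g_left or g_right):
                    tuples.add((p.peak_id, g.gene_id, "span_anchor", lp.loop_id))
    return tuples


def brute_shared_loops(set_a, set_b, anchor_overlap_bp=1):
    """Loop ids of set_a with a partner in set_b overlapping on both anchors."""
    shared = set()
    for la in set_a:
        for lb in set_b:
            if la.chrom != lb.chrom:
                continue
            left_ov = (min(la.left_anchor.end, lb.left_anchor.end)
                       - max(la.left_anchor.start, lb.left_anchor.start))
            right_ov = (min(la.right_anchor.end, lb.right_anchor.end)
                        - max(la.right_anchor.start, lb.right_anchor.start))
            if left_ov >= anchor_overlap_bp and right_ov >= anchor_overlap_bp:
                shared.add(la.loop_id)
    return shared
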