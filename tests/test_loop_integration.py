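"""Loop anatomy, shared loops, four-way classification, DEG integration."""

import numpy as np
import pytest

from loopweaver.core import GeneModel, GenomicInterval, Loop, Peak
from loopweaver.loop_integration import (
    classify_interactions,
    compare_with_closest_gene,
    derive_loop_parts,
    integrate_with_deg,
    shared_loops,
)
from loopweaver.cistrome_overlap import ClosestGeneAssignment, closest_gene_within
from oracles import (
    brute_classify,
    brute_shared_loops,
    random_genes,
    random_loops,
    random_peaks,
)


def loop(s1, e1, s2, e2, loop_id="l1", chrom="chr1"):
    return Loop(loop_id, chrom, GenomicInterval(chrom, s1, e1),
                GenomicInterval(chrom, s2, e2))


def simple_gene(tss, gene_id, chrom="chr1", strand="+"):
    if strand == "+":
        iv = GenomicInterval(chrom, tss, tss + 5_000, "+")
    else:
        iv = GenomicInterval(chrom, tss - 4_999, tss + 1, "-")
    return GeneModel(gene_id, gene_id, iv, strand, (GenomicInterval(chrom, iv.start, iv.end),))


def peak(start, end, peak_id="p1", chrom="chr1"):
    return Peak(GenomicInterval(chrom, start, end), peak_id)


class TestDeriveLoopParts:
    def test_span_between_anchor_ends(self):
        (parts,) = derive_loop_parts([loop(100_000, 110_000, 495_000, 505_000)])
        assert parts.span == GenomicInterval("chr1", 110_000, 495_000)

    def test_adjacent_anchors_flagged_zero_span(self):
        (parts,) = derive_loop_parts([loop(0, 10, 10, 20)])
        assert parts.zero_span and parts.span is None

    def test_definition_holds_on_random_loops(self):
        loops = random_loops(np.random.default_rng(0), 100)
        for lp, parts in zip(loops, derive_loop_parts(loops)):
            if parts.span is not None:
                assert parts.span.start == lp.left_anchor.end
                assert parts.span.end == lp.right_anchor.start


class TestSharedLoops:
    def test_identical_loop_retained_unchanged(self):
        lp = loop(0, 10_000, 50_000, 60_000)
        (shared,) = shared_loops([[lp], [lp]])
        assert shared.left_anchor == lp.left_anchor
        assert shared.right_anchor == lp.right_anchor

    def test_one_sided_anchor_overlap_not_shared(self):
        a = loop(0, 10_000, 50_000, 60_000)
        b = loop(5_000, 15_000, 80_000, 90_000)  # right anchors disjoint
        assert shared_loops([[a], [b]]) == []

    def test_union_coordinates_taken(self):
        a = loop(0, 10_000, 50_000, 60_000, "a")
        b = loop(2_000, 12_000, 48_000, 58_000, "b")
        (shared,) = shared_loops([[a], [b]])
        assert shared.left_anchor == GenomicInterval("chr1", 0, 12_000)
        assert shared.right_anchor == GenomicInterval("chr1", 48_000, 60_000)

    @pytest.mark.parametrize("seed", range(3))
    def test_jittered_sets_match_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(300 + seed)
        a = random_loops(rng, 60, max_pos=2_000_000, extent_range=(20_000, 150_000))
        b = random_loops(rng, 60, max_pos=2_000_000, extent_range=(20_000, 150_000))
        got = {lp.loop_id for lp in shared_loops([a, b])}
        assert got == brute_shared_loops(a, b)


class TestClassifyExamples:
    LOOP = loop(100_000, 110_000, 495_000, 505_000)

    def classify(self, peaks, genes):
        return classify_interactions(peaks, derive_loop_parts([self.LOOP]), genes)

    def test_peak_in_left_anchor_gene_in_right_is_anchor_anchor(self):
        records = self.classify(
            [peak(102_000, 102_500)], [simple_gene(500_000, "g1")]
        )
        (r,) = records
        assert r.category == "anchor_anchor"
        assert r.peak_location == "left_anchor" and r.gene_location == "right_anchor"

    def test_peak_in_span_same_gene_is_span_anchor(self):
        (r,) = self.classify([peak(300_000, 300_200)], [simple_gene(500_000, "g1")])
        assert r.category == "span_anchor"

    def test_promoter_overlap_is_direct_regardless_of_loops(self):
        records = self.classify(
            [peak(499_000, 499_500)], [simple_gene(500_000, "g1")]
        )
        cats = {r.category for r in records}
        assert "direct" in cats
        direct = next(r for r in records if r.category == "direct")
        assert direct.loop_id is None

    def test_gene_in_span_peak_in_anchor_is_anchor_span(self):
        (r,) = self.classify([peak(102_000, 102_400)], [simple_gene(300_000, "g1")])
        assert r.category == "anchor_span"

    def test_same_anchor_pair_reported_only_as_diagnostic(self):
        records, diag = classify_interactions(
            [peak(102_000, 102_400)], derive_loop_parts([self.LOOP]),
            [simple_gene(105_000, "g1")], return_diagnostics=True,
        )
        assert records == []
        assert len(diag) == 1 and diag[0].category == "same_anchor"

    def test_peak_straddling_anchor_span_boundary_counts_as_anchor(self):
        (r,) = self.classify([peak(109_500, 110_500)], [simple_gene(300_000, "g1")])
        assert r.category == "anchor_span" and r.peak_location == "left_anchor"


class TestClassifyOracle:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_brute_force(self, seed):
        rng = np.random.default_rng(500 + seed)
        genes = random_genes(rng, 40, max_pos=280_000)
        peaks = random_peaks(rng, 60, max_pos=280_000)
        loops = random_loops(rng, 15, max_pos=280_000)  # may overlap / nest
        records = classify_interactions(peaks, derive_loop_parts(loops), genes)
        got = {(r.peak_id, r.gene_id, r.category, r.loop_id) for r in records}
        assert got == brute_classify(peaks, loops, genes)

    def test_order_permutation_gives_identical_records(self):
        rng = np.random.default_rng(42)
        genes = random_genes(rng, 30)
        peaks = random_peaks(rng, 40)
        loops = random_loops(rng, 10)
        parts = derive_loop_parts(loops)
        base = classify_interactions(peaks, parts, genes)
        perm = classify_interactions(
            list(reversed(peaks)), list(reversed(parts)), list(reversed(genes))
        )
        assert base == perm

    def test_promoter_halfwidth_monotonicity(self):
        rng = np.random.default_rng(43)
        genes = random_genes(rng, 30)
        peaks = random_peaks(rng, 60)
        parts = derive_loop_parts(random_loops(rng, 8))
        narrow = {
            (r.peak_id, r.gene_id) for r in
            classify_interactions(peaks, parts, genes, promoter_halfwidth=1_000)
            if r.category == "direct"
        }
        wide = {
            (r.peak_id, r.gene_id) for r in
            classify_interactions(peaks, parts, genes, promoter_halfwidth=5_000)
            if r.category == "direct"
        }
        assert narrow <= wide

    def test_anchor_widening_monotonicity(self):
        rng = np.random.default_rng(44)
        genes = random_genes(rng, 30, max_pos=250_000)
        peaks = random_peaks(rng, 60, max_pos=250_000)
        loops = random_loops(rng, 8, max_pos=250_000)
        widened = [
            Loop(lp.loop_id, lp.chrom,
                 GenomicInterval(lp.chrom, max(0, lp.left_anchor.start - 500),
                                 lp.left_anchor.end + 500),
                 GenomicInterval(lp.chrom, lp.right_anchor.start - 500,
                                 lp.right_anchor.end + 500))
            for lp in loops
            if lp.left_anchor.end + 500 <= lp.right_anchor.start - 500
        ]
        kept = [lp for lp in loops if lp.loop_id in {w.loop_id for w in widened}]
        # the span shrinks as anchors widen, so only records whose gene
        # reference is an anchor are guaranteed to survive widening
        anchor_cats = {"anchor_anchor"}
        before = {
            (r.peak_id, r.gene_id, r.category, r.loop_id) for r in
            classify_interactions(peaks, derive_loop_parts(kept), genes)
            if r.category in anchor_cats
        }
        after = {
            (r.peak_id, r.gene_id, r.category, r.loop_id) for r in
            classify_interactions(peaks, derive_loop_parts(widened), genes)
            if r.category in anchor_cats
        }
        assert before <= after


class TestIntegrateWithDeg:
    def records_for(self, pairs, category="anchor_anchor"):
        from loopweaver.loop_integration import AssignmentRecord

        return [
            AssignmentRecord(p, g, category, "l1", "left_anchor", "right_anchor")
            for p, g in pairs
        ]

    def test_simple_counting(self):
        recs = self.records_for([("p1", "a"), ("p2", "b"), ("p3", "c")])
        tally = integrate_with_deg(recs, deg_genes={"b"},
                                   expressed_genes={"a", "b", "c"})
        assert tally.genes_total["anchor_anchor"] == 3
        assert tally.genes_deg["anchor_anchor"] == 1

    def test_gene_in_two_categories_counted_once_in_union(self):
        recs = (self.records_for([("p1", "a")], "anchor_anchor")
                + self.records_for([("p2", "a")], "span_anchor"))
        tally = integrate_with_deg(recs, {"a"}, {"a"})
        assert tally.genes_deg["anchor_anchor"] == 1
        assert tally.genes_deg["span_anchor"] == 1
        assert len(tally.union_deg_genes) == 1

    def test_unexpressed_genes_excluded(self):
        recs = self.records_for([("p1", "a"), ("p2", "b")])
        tally = integrate_with_deg(recs, set(), {"a"})
        assert tally.genes_total["anchor_anchor"] == 1

    def test_namespace_mismatch_errors(self):
        recs = self.records_for([("p1", "x"), ("p2", "y"), ("p3", "z")])
        with pytest.raises(ValueError, match="namespace"):
            integrate_with_deg(recs, {"q"}, {"q", "r"})


class TestCaptureComparison:
    def test_loop_method_finds_distal_gene_baseline_misses(self):
        # DEG gene on the far anchor 400 kb from the peak; a non-DEG gene
        # 10 kb away captures the baseline assignment instead
        lp = loop(100_000, 110_000, 495_000, 505_000)
        peaks = [peak(102_000, 102_400)]
        far_deg = simple_gene(500_000, "deg_far")
        near_bg = simple_gene(92_000, "bg_near", strand="-")
        genes = [far_deg, near_bg]
        records = classify_interactions(peaks, derive_loop_parts([lp]), genes)
        tally = integrate_with_deg(records, {"deg_far"},
                                   {"deg_far", "bg_near"})
        closest = closest_gene_within(peaks, genes)
        capture = compare_with_closest_gene(tally, closest)
        assert tally.genes_deg["anchor_anchor"] == 1
        assert capture.genes_deg_captured["anchor_anchor"] == 0
        assert capture.union_deg == 1 and capture.union_captured == 0

    def test_direct_category_fully_captured(self):
        g = simple_gene(50_000, "g1")
        p = peak(49_900, 50_100)
        records = classify_interactions([p], [], [g])
        tally = integrate_with_deg(records, {"g1"}, {"g1"})
        capture = compare_with_closest_gene(
            tally, closest_gene_within([p], [g])
        )
        assert capture.genes_deg["direct"] == 1
        assert capture.genes_deg_captured["direct"] == 1
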