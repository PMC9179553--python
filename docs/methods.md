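# Methods

## Coordinate conventions

All in-memory intervals are 0-based half-open (BED convention); GTF input
(1-based inclusive) is converted at the I/O boundary. The TSS is the first
transcribed base (`start` on `+`, `end − 1` on `−`); the TES is the last
transcribed base, so distances measured rightwards use `end − 1`. With
multi-transcript genes the longest transcript represents the gene (ties go
to the lexicographically smallest transcript id): assignments in this
pipeline are per-gene, not per-transcript. Chromosome names match as exact
strings; an optional `chr`-prefix normalisation flag exists on the readers
because silent `chr1`/`1` aliasing is a classic error source.

## Loop-mediated classification

A loop contributes three parts: left anchor, right anchor, and the span
`[left_anchor.end, right_anchor.start)` (zero-width spans are legal and
flagged). The four categories are defined in the README; the numerical
choices behind them:

- **Promoter window** for `direct`: TSS ± 2500 bp (configurable). There is
  no universal numeric definition of "promoter"; ±2.5 kb is a common ChIP
  annotation default and keeps `direct` a strict subset of what a 100-kb
  closest-gene pass can see.
- **Asymmetric membership**: peaks join an anchor by any 1-bp overlap (a
  binding event touching the anchor is in contact), while genes join by TSS
  containment (a gene is regulated at its promoter, so the TSS is the
  reference point). Span membership for genes is TSS-in-span; for peaks it
  is whole-interval containment with anchor precedence, so one peak is never
  counted as both anchor and span for the same loop.
- `span_anchor` accepts the gene TSS in *either* anchor.
- A peak and a TSS in the *same* anchor produce no category (that geometry
  is usually promoter-proximal and covered by `direct`); such pairs are
  available as a diagnostic side table.
- Loops shared between donors require both anchors to overlap (≥ 1 bp by
  default) and take anchor-union coordinates; an intersection mode exists.
  Union widening can only add anchor-peak and anchor-TSS memberships; it can
  shrink the span, which is why the monotonicity guarantee covers
  anchor-based records only.

The classifier is exact: the test suite checks it tuple-for-tuple against an
exhaustive (peak × loop × gene) enumeration on hundreds of random instances,
including overlapping and nested loops.

## Closest-gene baseline and capture comparison

The baseline assigns each peak to the gene minimising
`min(d(peak, TSS), d(peak, TES))`, distance 0 when the peak contains the
point, ties to the smaller gene id, with a cap of 100 kb (inclusive). The
capture comparison counts, per category, the expressed genes with ≥ 1
assignment, those that are DEG, and the DEG genes that are also the nearest
gene to at least one peak within the cap. `direct` genes are captured by
construction whenever the promoter peak's nearest gene is its own target —
true on all generated landscapes because planted items keep ≥ 10 kb of
clearance.

## Peak location annotation

Each peak is reduced to its midpoint, making the nine location categories a
true partition. Gene-body features are tested in the priority
5′UTR > coding exon > 3′UTR > intron ("exon" means the coding portion; UTRs
are derived from the CDS extent when present, so the three exonic classes
are disjoint). Outside any gene body, the peak falls into strand-aware
upstream/downstream bins (0–5 kb], (5–25 kb] measured from the TSS or TES
respectively, else distal. Only the > 25 kb distal boundary is externally
fixed; the 5 kb inner edge is a conventional annotation default and is
documented as such. An `overlap_mode="any"` flag lets any overlapping base
claim a gene-body feature instead; it is a convenience and breaks the exact
partition property that midpoint mode guarantees.

## Differential expression

The stage is deliberately literal about its three rules:

1. **Expression filter.** Threshold `t = 0.01 × mean(all RPKM values)`
   computed before any removal; genes with `MAX < t` are dropped (strict
   `<`; MAX exactly at `t` is kept). A dataset with mean RPKM 2.0 yields the
   cutoff 0.02.
2. **Baseline zeros.** In the vehicle group only, zero entries become
   `0.0005 × MAX(gene)` so baseline ratios are finite. Genes with MAX = 0
   must have been filtered and are an error here.
3. **DEG gate.** `is_deg ⇔ |log2 fold| ≥ 1 AND BH-adjusted p < 0.05`, with
   fold the ratio of arithmetic group means of the zero-replaced RPKM.

Significance uses a one-way ANOVA model on `log2(RPKM + 1e-3)` across all
treatment groups; each contrast is a t-test on the difference of group means
with the model's pooled within-group variance (df = N − k). With n = 3 per
group this pooled error term is what makes the test usable at all — a
two-sample test with 2+2 df has too little power at σ_log2 = 0.25 to reach
the sensitivity the planted-recovery checks demand, while the ANOVA-contrast
form (the construction commercial ANOVA packages use for fold-change
contrasts) does. The overall F p-value is reported per gene alongside the
contrast p. BH adjustment is per contrast across retained genes. ε = 1e-3
bounds the influence of zero-adjacent values. Donors are always analysed
separately and their DEG lists unioned; the API will not pool donors into
one test. Sample exclusion (e.g. PCA outliers) is an explicit argument,
never re-derived automatically.

## Compartments

Eigenvector bins (default 100 kb) are labelled A for oriented values > 0,
B for < 0, NA for exactly 0 or missing. Because the eigenvector's sign is
arbitrary per chromosome, the default orientation flips each chromosome so
the positive side is the gene-dense (TSS per bp) side — the standard "A =
active/gene-rich" convention — making labels invariant to a global sign
flip; `as_is` takes signs literally. Peaks map to the bin containing their
midpoint, so each peak has exactly one label, and `fraction_B` is computed
over A+B-assigned peaks only.

## Synthetic landscapes

The generator's defaults describe one hormone-response study: 2 chromosomes
× 20 Mb, 200 genes, 24 loops of 150–800 kb extent with 5–15 kb anchors,
300 peaks of which 30/25/25/40 are planted as
direct/anchor-anchor/anchor-span/span-anchor (the rest unassigned), 68 % of
peaks in the B compartment, and expression with 40 up- and 30 down-regulated
genes at true fold 4, lognormal noise σ_log2 = 0.25, n = 3 replicates per
group (V, E2, E2+MPA), progestin attenuation exponent 0.5 (E2+MPA applies
`fold^0.5`), and 1 % injected vehicle zeros. Loop extents start at 150 kb so
anchor-to-opposite-anchor targets genuinely exceed the 100 kb baseline cap —
the landscape always contains loop-only targets.

Placement enforces exclusion zones that make ground truth exact: loops never
overlap and are separated by 150 kb empty gaps; each planted loop hosts one
partner gene and peaks of one category, with margins (anchor-interior
placement, ≥ 10 kb span offsets) that keep peaks out of promoter windows;
background genes and unassigned peaks live behind the last loop, buffered
110 kb from it and spaced ≥ 10 kb apart. B-compartment bins are chosen by an
exact subset-sum over per-bin peak counts, so the planted B fraction is hit
exactly, not approximately. A feasibility validator rejects impossible
specs (category mixes needing more loops than exist, geometry that does not
fit the chromosome, more DEG genes than genes) before anything is written.

What the simulator does *not* emulate — and what passing tests therefore do
not show about real data: nested/overlapping loops in planted regions (the
classifier itself is exercised on nested random loops in the oracle tests,
but planted truth uses non-nested loops), irregular peak shapes and widths,
mappability gaps, donor-specific loop sets beyond uniform anchor jitter
(± 2 kb), compartment structure correlated with gene density, and
library-quality differences between donors. Real analyses should treat the
closure results as verification of the algorithms, not as evidence about
biological recovery rates.

## Pipeline and determinism

`run_pipeline` executes acquire → DEG → annotation → closest-gene → loop
integration → compartments, logs every parameter actually used, and writes
sha256 checksums of every output file into `report.json`. No output embeds
timestamps, so a rerun with the same config and seed is byte-identical. A
stage failure aborts with the stage named (CLI exit code 3; config
validation failures exit 2) and leaves a `FAILED_<stage>` marker beside any
partial outputs.

## Problem sizes in the shipped checks

The oracle-equivalence checks run 100 random instances (25 seeds × 4
operations, up to 900 peaks / 300 genes / 60 loops each) against naive
all-pairs or per-base enumerations; closure runs the full pipeline over 20
landscape configurations spanning all category mixes including zero counts;
the DEG Monte-Carlo uses 500 replicates of a 140-gene matrix (100 null, 20
fold-4, 20 fold-1.5). These sizes give exact (not sampled) agreement checks
on every instance while keeping the whole suite fast enough to run on every
change.

## Known limitations

- `fold_change` is a ratio of arithmetic means, not of geometric means; with
  n = 3 it is noticeably noisier than the log-scale estimate the t-test uses,
  and the 2-fold gate inherits that noise.
- The filter threshold is recomputed from whatever matrix it is given;
  re-filtering an already-filtered matrix can in principle remove borderline
  genes whose MAX sits within the (tiny) upward shift of the dataset mean.
- The closest-gene baseline considers TSS and TES only, not gene bodies, per
  its definition.
- `overlap_peak_sets` reports both original-coordinate counts and merged
  union intervals because published overlap percentages rarely state which
  counting they used.
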