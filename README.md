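# loopweaver

Chromatin-loop-aware assignment of nuclear-receptor ChIP-seq peaks to
hormone-responsive genes.

Estrogen and progesterone receptors (ESR1, PGR) regulate endometrial
epithelial genes both from promoters and from distal enhancers that contact
their targets through 3D chromatin loops. The common shortcut — assign each
ChIP peak to its closest gene within 100 kb — misses targets that are only
reachable through a loop. `loopweaver` implements the loop-aware alternative
as a reusable, tested pipeline for anyone integrating ChIP peaks (BED), Hi-C
loops (BEDPE), gene models (BED12/GTF), an A/B compartment eigenvector
(bedGraph), and hormone-treatment RNA-seq (RPKM TSV).

## The method

Each loop is split into a **left anchor**, a **right anchor**, and the
**span** between them (`[left_anchor.end, right_anchor.start)`). A peak can
then relate to a gene in four ways:

| category | peak | gene (TSS) |
|---|---|---|
| `direct` | overlaps TSS ± 2.5 kb | promoter itself |
| `anchor_anchor` | in one anchor | in the opposite anchor |
| `anchor_span` | in an anchor | inside the span |
| `span_anchor` | inside the span | in either anchor |

Peak membership in an anchor is any-overlap (≥ 1 bp); gene membership is TSS
containment; a peak straddling an anchor/span boundary counts as anchor.
Every qualifying (peak, gene, category, loop) tuple is reported once.

Around this core the package provides:

- **`transcript_filtering`** — the literal RNA-seq rules: drop genes whose
  maximum RPKM (MAX) is < 1 % of the dataset-mean RPKM; replace vehicle-group
  zeros with 0.05 % of MAX; call a DEG at ≥ 2-fold and BH-FDR p < 0.05 using
  an ANOVA-contrast t-test on log2(RPKM + 1e-3); analyse donors separately,
  then union their DEG lists.
- **`peak_annotation`** — PAVIS-style location categories (5′UTR / exon /
  3′UTR / intron / upstream & downstream 0–5 kb, 5–25 kb / distal > 25 kb) by
  peak midpoint.
- **`cistrome_overlap`** — shared-peak algebra between two cistromes (merged
  union coordinates, Venn counts) and the closest-gene (TSS/TES ≤ 100 kb)
  baseline.
- **`compartment_assignment`** — A/B labels from a signed 100-kb eigenvector
  (orientable by gene density) and per-peak compartment fractions.
- **`synthetic_data`** — a landscape simulator that plants peaks, loops,
  compartments, and estrogen-induced (and progestin-attenuated) expression
  with machine-readable ground truth for every downstream statistic.
- **`pipeline`** / the `loopweaver` CLI — the end-to-end orchestration with a
  deterministic, checksummed report.

## Worked example

Run the whole pipeline on a simulated landscape (300 peaks, 200 genes, 24
loops, two emulated donors):

```bash
printf 'outdir: out\nseed: 5\nsimulate: {}\n' > run.yaml
loopweaver run --config run.yaml
```

The report ends with the loop-integration table and compartment fractions:

```
[loop_integration]
  n_assignments = 120
  category           expressed  DEG  captured_by_closest
  direct                    30   30   30
  anchor_anchor              5    5    0
  anchor_span                5    5    1
  span_anchor                8    8    0
  union                     -   48   31

[compartments]
  n_peaks_A = 96
  n_peaks_B = 204
  n_peaks_NA = 0
  fraction_B = 0.68
```

Reading it: 120 (peak, gene, category, loop) tuples were found — exactly the
planted ones. All 30 promoter-`direct` DEG genes are also found by the
closest-gene baseline (the two methods coincide there by construction), but
of the 48 differentially expressed genes the loop method identifies in
total, the baseline captures only 31: the anchor-to-anchor and span-to-anchor
targets sit beyond the 100 kb cap and are invisible without the loops.
68 % of peaks fall in the B (inactive) compartment, matching the planted
fraction.

The same stages are available individually (`loopweaver simulate / deg /
annotate / overlap / closest / integrate / compartments`) and as library
functions (`loopweaver.classify_interactions`, `loopweaver.call_deg`, ...).

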