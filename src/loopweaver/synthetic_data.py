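"""Synthetic regulatory landscapes with machine-readable ground truth.

The generator emits the same data classes the real analysis consumes — gene
models (BED12), chromatin loops (BEDPE), ChIP peaks (BED), a signed
compartment eigenvector (bedGraph), and an RPKM expression matrix with a
V / E2 / E2+MPA design — while recording exactly which (peak, gene, category)
tuples, compartment labels, and differential-expression calls it planted.

Planted placements enforce exclusion zones so the loop classifier recovers
the planted tuples and nothing else:

* loops never overlap or nest and are separated by wide empty gaps;
* each planted loop hosts one partner gene and peaks of a single category;
* background genes and unassigned peaks live in a zone behind the last loop,
  buffered >100 kb from any loop gene, spaced >=10 kb apart so no peak ever
  strays into another gene's promoter window.

Expression emulates an estrogen-response experiment: a lognormal baseline,
an E2 group multiplying planted up-genes by ``true_fold`` (down-genes by its
reciprocal), and an E2+MPA group applying ``true_fold ** attenuation_factor``
— the progestin attenuation pattern — plus a small fraction of injected
baseline zeros to exercise the zero-replacement rule.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, GeneModel, GenomicInterval, Loop, Peak
from .io_formats import (
    _derive_utrs,
    write_bed,
    write_bedgraph,
    write_bedpe,
    write_expression_table,
    write_gene_models_bed12,
)

MAX_PEAKS_PER_LOOP = 5
PEAK_WIDTH = 400
ANCHOR_PEAK_MARGIN = 200
LOOP_GAP = 150_000
CHROM_HEAD = 100_000
BACKGROUND_BUFFER = 110_000  # keeps background peaks >100 kb from loop genes
SPAN_PEAK_OFFSET = 10_000
SPAN_PEAK_SPACING = 2_000
GROUPS = ("V", "E2", "E2+MPA")


@dataclass(frozen=True)
class DegSpec:
    """Planted differential-expression structure for one donor."""

    n_up: int = 40
    n_down: int = 30
    true_fold: float = 4.0
    noise_sigma_log2: float = 0.25
    n_replicates: int = 3
    attenuation_factor: float = 0.5
    baseline_zero_fraction: float = 0.01


@dataclass(frozen=True)
class CategoryMix:
    """Target counts of planted peaks per loop-interaction category; peaks
    beyond the planted total are 'unassigned' (outside loops and promoters)."""

    direct: int = 30
    anchor_anchor: int = 25
    anchor_span: int = 25
    span_anchor: int = 40

    @property
    def planted_total(self) -> int:
        return self.direct + self.anchor_anchor + self.anchor_span + self.span_anchor


@dataclass(frozen=True)
class LandscapeSpec:
    n_chromosomes: int = 2
    chrom_length: int = 20_000_000
    n_genes: int = 200
    n_loops: int = 24
    loop_extent_range: tuple[int, int] = (150_000, 800_000)
    anchor_width_range: tuple[int, int] = (5_000, 15_000)
    n_peaks: int = 300
    category_mix: CategoryMix = field(default_factory=CategoryMix)
    fraction_peaks_in_B: float = 0.68
    bin_size: int = 100_000
    deg_spec: DegSpec = field(default_factory=DegSpec)
    seed: int = 0


@dataclass
class GroundTruth:
    """Planted facts, serialized alongside the generated files."""

    peak_truth: pd.DataFrame       # peak_id, category, partner_gene, loop_id
    expected_tuples: set[tuple]    # (peak_id, gene_id, category, loop_id|None)
    peak_compartments: dict[str, str]
    fraction_B: float
    partner_genes: list[str]       # planted target genes, in planting order
    loop_only_genes: list[str]     # targets >100 kb from every peak


@dataclass
class Landscape:
    spec: LandscapeSpec
    genes: list[GeneModel]
    loops: list[Loop]
    peaks: list[Peak]
    eigen: list[tuple[GenomicInterval, float]]
    truth: GroundTruth

    def simulate_expression(self, seed: int | None = None, donor: str = "donor1"):
        """Expression for this landscape with planted targets preferred as DEG."""
        return simulate_expression(
            self.spec, self.genes, seed=seed,
            preferred_genes=self.truth.partner_genes, donor=donor,
        )

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.bed12",
            "loops": outdir / "loops.bedpe",
            "peaks": outdir / "peaks.bed",
            "eigenvector": outdir / "eigenvector.bedgraph",
            "peak_truth": outdir / "truth_peaks.tsv",
            "truth_summary": outdir / "truth_summary.json",
        }
        write_gene_models_bed12(self.genes, paths["genes"])
        write_bedpe(self.loops, paths["loops"])
        write_bed(self.peaks, paths["peaks"], dialect="bed6")
        write_bedgraph(self.eigen, paths["eigenvector"])
        self.truth.peak_truth.to_csv(paths["peak_truth"], sep="\t", index=False)
        summary = {
            "fraction_B": self.truth.fraction_B,
            "n_expected_tuples": len(self.truth.expected_tuples),
            "partner_genes": self.truth.partner_genes,
            "loop_only_genes": self.truth.loop_only_genes,
            "spec": _spec_to_dict(self.spec),
        }
        paths["truth_summary"].write_text(json.dumps(summary, indent=2, sort_keys=True))
        return paths


def _spec_to_dict(spec: LandscapeSpec) -> dict:
    return dataclasses.asdict(spec)


def spec_from_dict(data: dict) -> LandscapeSpec:
    data = dict(data)
    if "category_mix" in data and isinstance(data["category_mix"], dict):
        data["category_mix"] = CategoryMix(**data["category_mix"])
    if "deg_spec" in data and isinstance(data["deg_spec"], dict):
        data["deg_spec"] = DegSpec(**data["deg_spec"])
    for key in ("loop_extent_range", "anchor_width_range"):
        if key in data:
            data[key] = tuple(data[key])
    return LandscapeSpec(**data)


# ---------------------------------------------------------------------------
# feasibility
# ---------------------------------------------------------------------------

def validate_spec(spec: LandscapeSpec) -> None:
    """Reject impossible geometry or category mixes before anything is built."""
    mix, deg = spec.category_mix, spec.deg_spec
    if min(mix.direct, mix.anchor_anchor, mix.anchor_span, mix.span_anchor) < 0:
        raise ValueError("category counts must be non-negative")
    if mix.planted_total > spec.n_peaks:
        raise ValueError(
            f"planted category counts ({mix.planted_total}) exceed n_peaks "
            f"({spec.n_peaks})"
        )
    if not 0.0 <= spec.fraction_peaks_in_B <= 1.0:
        raise ValueError("fraction_peaks_in_B must be in [0, 1]")
    if deg.true_fold < 1.0:
        raise ValueError("true_fold must be >= 1")
    if not 0.0 <= deg.attenuation_factor <= 1.0:
        raise ValueError("attenuation_factor must be in [0, 1]")
    if deg.n_up + deg.n_down > spec.n_genes:
        raise ValueError("n_up + n_down exceeds n_genes")
    n_loops_needed = sum(
        -(-count // MAX_PEAKS_PER_LOOP)
        for count in (mix.anchor_anchor, mix.anchor_span, mix.span_anchor)
    )
    if n_loops_needed > spec.n_loops:
        raise ValueError(
            f"category mix needs {n_loops_needed} loops but spec has {spec.n_loops}"
        )
    lo_extent, hi_extent = spec.loop_extent_range
    lo_anchor, hi_anchor = spec.anchor_width_range
    if lo_anchor < 2 * ANCHOR_PEAK_MARGIN + MAX_PEAKS_PER_LOOP * 2 * PEAK_WIDTH:
        raise ValueError("anchors too narrow to host planted peaks")
    if lo_extent < 2 * hi_anchor + 40_000:
        raise ValueError("loop extents too small for the anchor widths (span < 40 kb)")
    n_planted_genes = mix.direct + n_loops_needed
    if n_planted_genes > spec.n_genes:
        raise ValueError("not enough genes for planted targets")
    # coarse geometry bound; exact placement re-checks and errors before writing
    per_chrom_loops = -(-spec.n_loops // spec.n_chromosomes)
    loop_budget = CHROM_HEAD + per_chrom_loops * (hi_extent + LOOP_GAP) + BACKGROUND_BUFFER
    if loop_budget > spec.chrom_length:
        raise ValueError("too many / too large loops for chrom_length")


# ---------------------------------------------------------------------------
# landscape generation
# ---------------------------------------------------------------------------

def generate_landscape(spec: LandscapeSpec) -> Landscape:
    """Deterministically build a landscape for ``spec`` (same spec + seed =>
    identical output, byte-level after :meth:`Landscape.write`)."""
    validate_spec(spec)
    rng = np.random.default_rng(spec.seed)
    mix = spec.category_mix

    loop_plans = _plan_loops(spec, rng)
    genes: list[GeneModel] = []
    peaks: list[Peak] = []
    loops: list[Loop] = []
    truth_rows: list[dict] = []
    loop_only: list[str] = []
    partner_order: list[str] = []
    gene_counter = peak_counter = 0

    def next_gene_id():
        nonlocal gene_counter
        gene_counter += 1
        return f"gene_{gene_counter:04d}"

    def next_peak_id():
        nonlocal peak_counter
        peak_counter += 1
        return f"peak_{peak_counter:05d}"

    chrom_names = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    cursors = {c: CHROM_HEAD for c in chrom_names}

    for i, plan in enumerate(loop_plans):
        chrom = chrom_names[i % spec.n_chromosomes]
        extent = int(rng.integers(*spec.loop_extent_range))
        w_left = int(rng.integers(*spec.anchor_width_range))
        w_right = int(rng.integers(*spec.anchor_width_range))
        start = cursors[chrom]
        if start + extent + LOOP_GAP + BACKGROUND_BUFFER > spec.chrom_length:
            raise ValueError(
                f"loops do not fit on {chrom}: needed beyond {spec.chrom_length} bp"
            )
        cursors[chrom] = start + extent + LOOP_GAP
        left = GenomicInterval(chrom, start, start + w_left)
        right = GenomicInterval(chrom, start + extent - w_right, start + extent)
        loop_id = f"loop_{i + 1:03d}"
        loops.append(Loop(loop_id, chrom, left, right))
        category, k = plan
        if category == "empty" or k == 0:
            continue
        gene_id = next_gene_id()
        partner_order.append(gene_id)
        span_lo, span_hi = left.end, right.start
        if category == "anchor_anchor":
            tss = (right.start + right.end) // 2
            peak_region = left
            loop_only.append(gene_id)
        elif category == "anchor_span":
            tss = (span_lo + span_hi) // 2
            peak_region = left
        else:  # span_anchor
            tss = (right.start + right.end) // 2
            peak_region = None
            loop_only.append(gene_id)
        genes.append(_make_gene(rng, chrom, tss, gene_id))
        if peak_region is not None:
            positions = _anchor_peak_positions(peak_region, k)
        else:
            positions = [
                span_lo + SPAN_PEAK_OFFSET + j * (PEAK_WIDTH + SPAN_PEAK_SPACING)
                for j in range(k)
            ]
        for pos in positions:
            pid = next_peak_id()
            peaks.append(
                Peak(GenomicInterval(chrom, pos, pos + PEAK_WIDTH), pid,
                     float(np.round(rng.uniform(5, 100), 2)))
            )
            truth_rows.append(
                {"peak_id": pid, "category": category,
                 "partner_gene": gene_id, "loop_id": loop_id}
            )

    # background zone: direct pairs, background genes, unassigned peaks
    n_unassigned = spec.n_peaks - mix.planted_total
    n_background_genes = spec.n_genes - gene_counter - mix.direct
    if n_background_genes < 0:
        raise ValueError("not enough genes for planted targets")
    items = (
        ["direct"] * mix.direct
        + ["gene"] * n_background_genes
        + ["peak"] * n_unassigned
    )
    items = [items[j] for j in rng.permutation(len(items))]
    chrom_iter = 0
    bg_cursors = {c: cursors[c] + BACKGROUND_BUFFER for c in chrom_names}
    for item in items:
        placed = False
        for _ in range(spec.n_chromosomes):
            chrom = chrom_names[chrom_iter % spec.n_chromosomes]
            chrom_iter += 1
            pos = bg_cursors[chrom] + int(rng.integers(10_000, 20_000))
            footprint = 10_000 if item != "peak" else PEAK_WIDTH
            if pos + footprint > spec.chrom_length - 1_000:
                continue
            bg_cursors[chrom] = pos + footprint
            placed = True
            break
        if not placed:
            raise ValueError("background items do not fit on the chromosomes")
        if item in ("direct", "gene"):
            gene_id = next_gene_id()
            gene = _make_gene(rng, chrom, pos + 2_500, gene_id)
            genes.append(gene)
            if item == "direct":
                partner_order.append(gene_id)
                pid = next_peak_id()
                p_start = gene.tss - PEAK_WIDTH // 2
                peaks.append(
                    Peak(GenomicInterval(chrom, p_start, p_start + PEAK_WIDTH), pid,
                         float(np.round(rng.uniform(5, 100), 2)))
                )
                truth_rows.append(
                    {"peak_id": pid, "category": "direct",
                     "partner_gene": gene_id, "loop_id": ""}
                )
        else:
            pid = next_peak_id()
            peaks.append(
                Peak(GenomicInterval(chrom, pos, pos + PEAK_WIDTH), pid,
                     float(np.round(rng.uniform(5, 100), 2)))
            )
            truth_rows.append(
                {"peak_id": pid, "category": "unassigned",
                 "partner_gene": "", "loop_id": ""}
            )

    eigen, peak_compartments, fraction_b = _build_compartments(spec, peaks, rng)

    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    peaks.sort(key=lambda p: (p.chrom, p.interval.start, p.peak_id))
    peak_truth = pd.DataFrame(
        truth_rows, columns=["peak_id", "category", "partner_gene", "loop_id"]
    ).sort_values("peak_id", kind="mergesort").reset_index(drop=True)
    expected = {
        (r.peak_id, r.partner_gene, r.category, r.loop_id or None)
        for r in peak_truth.itertuples(index=False)
        if r.category != "unassigned"
    }
    truth = GroundTruth(
        peak_truth=peak_truth,
        expected_tuples=expected,
        peak_compartments=peak_compartments,
        fraction_B=fraction_b,
        partner_genes=partner_order,
        loop_only_genes=loop_only,
    )
    return Landscape(spec, genes, loops, peaks, eigen, truth)


def _plan_loops(spec: LandscapeSpec, rng) -> list[tuple[str, int]]:
    """Assign each loop a category and a planted peak count (<= 5 per loop)."""
    plans: list[tuple[str, int]] = []
    mix = spec.category_mix
    for category, total in (
        ("anchor_anchor", mix.anchor_anchor),
        ("anchor_span", mix.anchor_span),
        ("span_anchor", mix.span_anchor),
    ):
        remaining = total
        while remaining > 0:
            k = min(MAX_PEAKS_PER_LOOP, remaining)
            plans.append((category, k))
            remaining -= k
    if len(plans) > spec.n_loops:
        raise ValueError("category mix needs more loops than spec provides")
    plans += [("empty", 0)] * (spec.n_loops - len(plans))
    order = rng.permutation(len(plans))
    return [plans[j] for j in order]


def _anchor_peak_positions(anchor: GenomicInterval, k: int) -> list[int]:
    usable_lo = anchor.start + ANCHOR_PEAK_MARGIN
    usable_hi = anchor.end - ANCHOR_PEAK_MARGIN - PEAK_WIDTH
    if k == 1:
        return [(usable_lo + usable_hi) // 2]
    step = (usable_hi - usable_lo) // (k - 1)
    return [usable_lo + j * step for j in range(k)]


def _make_gene(rng, chrom: str, tss: int, gene_id: str) -> GeneModel:
    """A compact plus-strand gene: TSS at ``tss``, 8 kb body, 1-3 exons,
    CDS interior so both UTR classes are populated."""
    body_len = 8_000
    start, end = tss, tss + body_len
    n_exons = int(rng.integers(1, 4))
    if n_exons == 1:
        exons = [GenomicInterval(chrom, start, end)]
    else:
        cuts = sorted(
            int(x) for x in rng.choice(
                np.arange(start + 1_000, end - 1_000, 500),
                size=2 * (n_exons - 1), replace=False,
            )
        )
        bounds = [start] + cuts + [end]
        exons = [
            GenomicInterval(chrom, bounds[2 * j], bounds[2 * j + 1])
            for j in range(n_exons)
        ]
    cds_lo, cds_hi = start + 500, end - 500
    utr5, utr3 = _derive_utrs(exons, cds_lo, cds_hi, "+")
    return GeneModel(
        gene_id=gene_id, gene_name=gene_id,
        interval=GenomicInterval(chrom, start, end, "+"),
        strand="+", exons=tuple(exons), utr5=utr5, utr3=utr3,
    )


def _build_compartments(spec: LandscapeSpec, peaks, rng):
    """Tile bins, choose a bin subset whose peak count is exactly the planted
    B total, and draw signed eigenvalues accordingly."""
    bin_size = spec.bin_size
    peak_bins: dict[tuple[str, int], list[str]] = {}
    for p in peaks:
        key = (p.chrom, p.midpoint // bin_size)
        peak_bins.setdefault(key, []).append(p.peak_id)
    k_b = round(spec.fraction_peaks_in_B * len(peaks))
    order = sorted(peak_bins, key=lambda key: (-len(peak_bins[key]), key))
    # exact subset-sum over per-bin peak counts so the B fraction is exact
    reachable: dict[int, list[tuple[str, int]]] = {0: []}
    for key in order:
        count = len(peak_bins[key])
        for total in sorted(reachable, reverse=True):
            new_total = total + count
            if new_total <= k_b and new_total not in reachable:
                reachable[new_total] = reachable[total] + [key]
    if k_b not in reachable:
        raise ValueError(
            "cannot hit fraction_peaks_in_B exactly with the realized peak "
            "binning; adjust the spec"
        )
    b_bins: set[tuple[str, int]] = set(reachable[k_b])
    eigen: list[tuple[GenomicInterval, float]] = []
    peak_comp: dict[str, str] = {}
    for c in range(spec.n_chromosomes):
        chrom = f"chr{c + 1}"
        n_bins = -(-spec.chrom_length // bin_size)
        for b in range(n_bins):
            lo = b * bin_size
            hi = min(lo + bin_size, spec.chrom_length)
            key = (chrom, b)
            has_peaks = key in peak_bins
            if not has_peaks and rng.random() < 0.05:
                continue  # leave occasional gaps in peak-free territory
            if key in b_bins:
                value = -float(np.round(rng.uniform(0.2, 1.0), 4))
            elif has_peaks:
                value = float(np.round(rng.uniform(0.2, 1.0), 4))
            else:
                value = float(np.round(rng.uniform(0.2, 1.0), 4))
                if rng.random() < 0.5:
                    value = -value
            eigen.append((GenomicInterval(chrom, lo, hi), value))
            if has_peaks:
                label = "B" if key in b_bins else "A"
                for pid in peak_bins[key]:
                    peak_comp[pid] = label
    fraction_b = k_b / len(peaks) if peaks else 0.0
    return eigen, peak_comp, fraction_b


# ---------------------------------------------------------------------------
# donors & expression
# ---------------------------------------------------------------------------

def jitter_loops(loops, jitter_bp: int, seed: int) -> list[Loop]:
    """A second 'donor' loop set: anchors shifted uniformly within
    +/- ``jitter_bp`` (shift bounded so left/right stay valid)."""
    rng = np.random.default_rng(seed)
    out = []
    for lp in loops:
        shift_l = int(rng.integers(-jitter_bp, jitter_bp + 1))
        shift_r = int(rng.integers(-jitter_bp, jitter_bp + 1))
        left = GenomicInterval(
            lp.chrom, max(0, lp.left_anchor.start + shift_l),
            max(1, lp.left_anchor.end + shift_l),
        )
        right_start = max(left.end, lp.right_anchor.start + shift_r)
        right = GenomicInterval(
            lp.chrom, right_start,
            max(right_start + 1, lp.right_anchor.end + shift_r),
        )
        out.append(Loop(lp.loop_id, lp.chrom, left, right))
    return out


def simulate_expression(
    spec: LandscapeSpec,
    genes: list[GeneModel],
    seed: int | None = None,
    up_genes: list[str] | None = None,
    down_genes: list[str] | None = None,
    preferred_genes: list[str] | None = None,
    fold_overrides: dict[str, float] | None = None,
    donor: str = "donor1",
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """RPKM matrix (V / E2 / E2+MPA, ``n_replicates`` each) plus gene truth.

    Planted up-genes are multiplied by ``true_fold`` in E2 (down-genes by the
    reciprocal); E2+MPA applies ``true_fold ** attenuation_factor``. When gene
    lists are not given, planted loop/promoter target genes are preferred as
    DEG so expression truth lines up with the peak-assignment truth.
    """
    deg = spec.deg_spec
    if deg.n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    gene_ids = [g.gene_id for g in genes]
    if up_genes is None or down_genes is None:
        up_genes, down_genes = _default_deg_genes(
            spec, gene_ids, preferred_genes or [], rng
        )
    regulation = pd.Series("null", index=gene_ids)
    regulation.loc[list(up_genes)] = "up"
    regulation.loc[list(down_genes)] = "down"
    fold = pd.Series(1.0, index=gene_ids)
    fold.loc[list(up_genes)] = deg.true_fold
    fold.loc[list(down_genes)] = 1.0 / deg.true_fold
    if fold_overrides:
        for g, f in fold_overrides.items():
            fold.loc[g] = f
            regulation.loc[g] = "up" if f > 1 else ("down" if f < 1 else "null")
    regulated = regulation != "null"
    base_log2 = np.where(
        regulated, rng.normal(4.0, 1.0, len(gene_ids)),
        rng.normal(3.0, 1.5, len(gene_ids)),
    )
    log2_fold = np.log2(fold.to_numpy())
    effect = {
        "V": np.zeros(len(gene_ids)),
        "E2": log2_fold,
        "E2+MPA": deg.attenuation_factor * log2_fold,
    }
    columns, data = [], []
    for group in GROUPS:
        for r in range(deg.n_replicates):
            columns.append(f"{group}_{r + 1}")
            noise = rng.normal(0.0, deg.noise_sigma_log2, len(gene_ids))
            data.append(2.0 ** (base_log2 + effect[group] + noise))
    values = pd.DataFrame(
        np.column_stack(data), index=pd.Index(gene_ids, name="gene_id"),
        columns=columns,
    )
    if deg.baseline_zero_fraction > 0:
        v_cols = [c for c in columns if c.startswith("V_")]
        mask = rng.random((len(gene_ids), len(v_cols))) < deg.baseline_zero_fraction
        sub = values[v_cols].to_numpy()
        sub[mask] = 0.0
        values[v_cols] = sub
    values = values.round(6)
    design = pd.DataFrame(
        {"group": [c.rsplit("_", 1)[0] for c in columns],
         "donor": donor},
        index=pd.Index(columns, name="sample"),
    )
    gene_truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "regulation": regulation.to_numpy(),
            "true_fold_e2": fold.to_numpy(),
            "true_fold_e2mpa": fold.to_numpy() ** deg.attenuation_factor,
        }
    )
    return ExpressionMatrix(values, design), gene_truth


def _default_deg_genes(spec, gene_ids, preferred, rng):
    # planted targets first so peak-assignment and expression truths align
    preferred = [g for g in preferred if g in set(gene_ids)]
    others = [g for g in gene_ids if g not in set(preferred)]
    pool = preferred + [others[j] for j in rng.permutation(len(others))]
    deg = spec.deg_spec
    up = pool[: deg.n_up]
    down = pool[deg.n_up: deg.n_up + deg.n_down]
    return up, down


def write_expression(
    matrix: ExpressionMatrix, gene_truth: pd.DataFrame, outdir: str | Path,
    prefix: str = "expression",
) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": outdir / f"{prefix}_matrix.tsv",
        "design": outdir / f"{prefix}_design.tsv",
        "gene_truth": outdir / f"truth_{prefix}_genes.tsv",
    }
    write_expression_table(matrix, paths["matrix"], paths["design"])
    gene_truth.to_csv(paths["gene_truth"], sep="\t", index=False)
    return paths
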