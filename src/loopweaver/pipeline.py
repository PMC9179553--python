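"""End-to-end orchestration: simulate-or-load, DEG, annotation, baseline,
loop integration, compartments — with a single deterministic report.

The report carries every parameter actually used, per-stage summaries, a
capture table (per category: expressed genes / DEG / DEG also found by the
closest-gene baseline), and sha256 checksums of every file written, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import (
    cistrome_overlap,
    compartment_assignment,
    io_formats,
    loop_integration,
    peak_annotation,
    synthetic_data,
    transcript_filtering,
)

EXIT_VALIDATION = 2
EXIT_STAGE = 3


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    simulate: dict | None = None          # LandscapeSpec field overrides
    inputs: dict | None = None            # paths: peaks/loops/genes/eigenvector/expression
    promoter_halfwidth: int = 2_500
    max_distance: int = 100_000
    bin_size: int = 100_000
    fold_cutoff: float = 2.0
    fdr_cutoff: float = 0.05
    orientation: str = "as_is"
    baseline_group: str = "V"
    contrast: tuple[str, str] = ("E2", "V")
    anchor_overlap_bp: int = 1
    donor_jitter_bp: int = 2_000

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "contrast" in data:
            data["contrast"] = tuple(data["contrast"])
        return cls(**data)

    def validate(self) -> None:
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("config needs exactly one of 'simulate' or 'inputs'")
        if self.promoter_halfwidth <= 0 or self.max_distance <= 0 or self.bin_size <= 0:
            raise ConfigError("window parameters must be positive")
        if self.fold_cutoff < 1 or not 0 < self.fdr_cutoff < 1:
            raise ConfigError("fold_cutoff must be >= 1 and fdr_cutoff in (0, 1)")
        if self.orientation not in {"as_is", "by_gene_density"}:
            raise ConfigError("orientation must be 'as_is' or 'by_gene_density'")
        if self.inputs is not None:
            for key in ("peaks", "genes"):
                if key not in self.inputs:
                    raise ConfigError(f"inputs missing required key {key!r}")
            for key, value in self.inputs.items():
                paths = value if isinstance(value, list) else [value]
                for p in paths:
                    if isinstance(p, dict):
                        p_list = [p.get("matrix"), p.get("design")]
                    else:
                        p_list = [p]
                    for one in p_list:
                        if isinstance(one, str) and not Path(one).exists():
                            raise ConfigError(f"input file does not exist: {one}")


@dataclass
class PipelineResult:
    report: dict
    landscape: synthetic_data.Landscape | None
    assignments: list
    tally: loop_integration.CategoryTally
    capture: loop_integration.CaptureComparison
    fractions: compartment_assignment.CompartmentFractions
    deg_genes: set[str]
    expressed_genes: set[str]


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute every stage in dependency order; deterministic given config."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"parameters": _params_dict(config), "stages": {}}
    written: list[Path] = []
    stage = "acquire_inputs"
    try:
        data = _acquire(config, outdir, written)
        landscape = data.get("landscape")
        report["stages"]["acquire_inputs"] = data["summary"]

        stage = "differential_expression"
        deg_genes, expressed, deg_summary = _deg_stage(config, data, outdir, written)
        report["stages"]["differential_expression"] = deg_summary

        stage = "peak_annotation"
        calls = peak_annotation.annotate_peak_location(data["peaks"], data["genes"])
        loc_summary = peak_annotation.summarize_locations(calls)
        io_formats.write_table(calls, outdir / "peak_locations.tsv",
                               peak_annotation.PeakLocationCall)
        written.append(outdir / "peak_locations.tsv")
        report["stages"]["peak_annotation"] = {
            "counts": loc_summary.counts,
            "gene_body_fraction": loc_summary.gene_body_fraction,
        }

        stage = "closest_gene_baseline"
        closest = cistrome_overlap.closest_gene_within(
            data["peaks"], data["genes"], config.max_distance
        )
        io_formats.write_table(closest, outdir / "closest_genes.tsv",
                               cistrome_overlap.ClosestGeneAssignment)
        written.append(outdir / "closest_genes.tsv")
        report["stages"]["closest_gene_baseline"] = {
            "n_within_cap": sum(a.within_100kb for a in closest),
            "max_distance": config.max_distance,
        }

        stage = "loop_integration"
        parts = loop_integration.derive_loop_parts(data["loops"])
        assignments = loop_integration.classify_interactions(
            data["peaks"], parts, data["genes"], config.promoter_halfwidth
        )
        tally = loop_integration.integrate_with_deg(
            assignments, deg_genes, expressed
        )
        capture = loop_integration.compare_with_closest_gene(tally, closest)
        io_formats.write_table(assignments, outdir / "assignments.tsv",
                               loop_integration.AssignmentRecord)
        written.append(outdir / "assignments.tsv")
        capture_table = {
            cat: {
                "genes_expressed": capture.genes_total[cat],
                "genes_deg": capture.genes_deg[cat],
                "deg_captured_by_closest": capture.genes_deg_captured[cat],
            }
            for cat in loop_integration.CATEGORIES
        }
        capture_table["union"] = {
            "genes_deg": capture.union_deg,
            "deg_captured_by_closest": capture.union_captured,
        }
        (outdir / "capture_comparison.json").write_text(
            json.dumps(capture_table, indent=2, sort_keys=True)
        )
        written.append(outdir / "capture_comparison.json")
        report["stages"]["loop_integration"] = {
            "n_assignments": len(assignments),
            "capture_table": capture_table,
        }

        stage = "compartments"
        track = compartment_assignment.label_compartments(
            data["eigen"], config.bin_size, config.orientation,
            genes=data["genes"] if config.orientation == "by_gene_density" else None,
        )
        fractions = compartment_assignment.peaks_in_compartments(data["peaks"], track)
        compartment_assignment.write_compartment_bed(
            track, outdir / "compartments.bed"
        )
        written.append(outdir / "compartments.bed")
        report["stages"]["compartments"] = {
            "n_peaks_A": fractions.n_peaks_A,
            "n_peaks_B": fractions.n_peaks_B,
            "n_peaks_NA": fractions.n_peaks_NA,
            "fraction_B": fractions.fraction_B,
        }
    except Exception as exc:
        (outdir / f"FAILED_{stage}").write_text(f"{type(exc).__name__}: {exc}\n")
        raise StageError(stage, exc) from exc

    report["checksums"] = {
        p.name: _sha256(p) for p in sorted(set(written), key=lambda p: p.name)
    }
    (outdir / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True, default=_jsonify)
    )
    (outdir / "report.txt").write_text(_text_report(report))
    return PipelineResult(
        report, landscape, assignments, tally, capture, fractions,
        deg_genes, expressed,
    )


def _acquire(config: RunConfig, outdir: Path, written: list[Path]) -> dict:
    if config.simulate is not None:
        overrides = dict(config.simulate)
        overrides.setdefault("seed", config.seed)
        spec = synthetic_data.spec_from_dict(overrides)
        landscape = synthetic_data.generate_landscape(spec)
        sim_dir = outdir / "sim"
        paths = landscape.write(sim_dir)
        written.extend(paths.values())
        donor2_loops = synthetic_data.jitter_loops(
            landscape.loops, config.donor_jitter_bp, spec.seed + 3
        )
        loops = loop_integration.shared_loops(
            [landscape.loops, donor2_loops], config.anchor_overlap_bp
        )
        expr = {
            "donor1": landscape.simulate_expression(seed=spec.seed + 1),
            "donor2": landscape.simulate_expression(seed=spec.seed + 2,
                                                    donor="donor2"),
        }
        for donor, (matrix, truth) in expr.items():
            p = synthetic_data.write_expression(matrix, truth, sim_dir, prefix=donor)
            written.extend(p.values())
        return {
            "landscape": landscape,
            "peaks": landscape.peaks,
            "genes": landscape.genes,
            "loops": loops,
            "eigen": landscape.eigen,
            "expression": {d: m for d, (m, _) in expr.items()},
            "summary": {
                "mode": "simulate",
                "n_peaks": len(landscape.peaks),
                "n_genes": len(landscape.genes),
                "n_loops_shared": len(loops),
                "seed": spec.seed,
            },
        }
    inputs = config.inputs
    peaks = io_formats.read_bed(inputs["peaks"], inputs.get("peaks_dialect", "bed6"))
    genes = io_formats.read_gene_models(
        inputs["genes"], inputs.get("genes_format", "bed12")
    )
    loop_files = inputs.get("loops", [])
    if isinstance(loop_files, str):
        loop_files = [loop_files]
    loop_sets = [io_formats.read_bedpe(p) for p in loop_files]
    if len(loop_sets) > 1:
        loops = loop_integration.shared_loops(loop_sets, config.anchor_overlap_bp)
    elif loop_sets:
        loops = loop_sets[0]
    else:
        loops = []
    eigen = (
        io_formats.read_bedgraph_eigenvector(inputs["eigenvector"], config.bin_size)
        if "eigenvector" in inputs
        else []
    )
    expression = {}
    for entry in inputs.get("expression", []):
        donor = entry.get("donor", f"donor{len(expression) + 1}")
        matrix = io_formats.read_expression_table(entry["matrix"], entry["design"])
        if entry.get("exclude_samples"):
            matrix = matrix.drop_samples(entry["exclude_samples"])
        expression[donor] = matrix
    return {
        "landscape": None,
        "peaks": peaks,
        "genes": genes,
        "loops": loops,
        "eigen": eigen,
        "expression": expression,
        "summary": {
            "mode": "load",
            "n_peaks": len(peaks),
            "n_genes": len(genes),
            "n_loops": len(loops),
        },
    }


def _deg_stage(config: RunConfig, data: dict, outdir: Path, written: list[Path]):
    """Per-donor filter -> zero replacement -> contrast test, then union."""
    per_donor: dict = {}
    expressed: set[str] = set()
    summary: dict[str, Any] = {"per_donor": {}}
    for donor, matrix in data["expression"].items():
        filtered = transcript_filtering.filter_low_expression(matrix)
        replaced = transcript_filtering.replace_vehicle_zeros(
            filtered.matrix, config.baseline_group
        )
        table = transcript_filtering.call_deg(
            replaced, config.contrast, config.fold_cutoff, config.fdr_cutoff
        )
        per_donor[donor] = table
        expressed.update(replaced.gene_ids)
        path = outdir / f"deg_{donor}.tsv"
        io_formats.write_table(table, path)
        written.append(path)
        summary["per_donor"][donor] = {
            "filter_threshold": filtered.threshold,
            "n_retained": len(replaced.gene_ids),
            "n_deg": int(table["is_deg"].sum()),
        }
    if not per_donor:
        return set(), set(), {"per_donor": {}, "n_union_deg": 0}
    union = transcript_filtering.union_deg(per_donor)
    path = outdir / "deg_union.tsv"
    io_formats.write_table(union, path)
    written.append(path)
    deg_genes = set(union["gene_id"])
    summary["n_union_deg"] = len(deg_genes)
    summary["contrast"] = list(config.contrast)
    return deg_genes, expressed, summary


def _params_dict(config: RunConfig) -> dict:
    out = dataclasses.asdict(config)
    out["contrast"] = list(config.contrast)
    return out


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if isinstance(obj, Path):
        return str(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _text_report(report: dict) -> str:
    lines = ["loopweaver pipeline report", "=" * 26, ""]
    lines.append("parameters:")
    for k, v in sorted(report["parameters"].items()):
        lines.append(f"  {k} = {v}")
    for stage, summary in report["stages"].items():
        lines.append("")
        lines.append(f"[{stage}]")
        for k, v in summary.items():
            if k == "capture_table":
                lines.append("  category           expressed  DEG  captured_by_closest")
                for cat, row in v.items():
                    if cat == "union":
                        lines.append(
                            f"  union                     -  {row['genes_deg']:>3}"
                            f"  {row['deg_captured_by_closest']:>3}"
                        )
                    else:
                        lines.append(
                            f"  {cat:<18} {row['genes_expressed']:>9}"
                            f"  {row['genes_deg']:>3}"
                            f"  {row['deg_captured_by_closest']:>3}"
                        )
            else:
                lines.append(f"  {k} = {v}")
    lines.append("")
    return "\n".join(lines)
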