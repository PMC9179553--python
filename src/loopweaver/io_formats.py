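"""Readers and writers for the text formats the pipeline consumes and emits.

BED-family inputs are 0-based half-open and pass through unchanged; GTF input
(1-based inclusive) is converted at this boundary. Every reader either keeps a
record or reports why it dropped it — silent drops are limited to the rules
stated per format (e.g. inter-chromosomal BEDPE rows), and counts are logged.
"""

from __future__ import annotations

import dataclasses
import logging
import typing
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pandas as pd

from .core import GenomicInterval, GeneModel, Loop, Peak, ExpressionMatrix

logger = logging.getLogger(__name__)

_MISSING = ""  # on-disk encoding of None in record tables


def _ensure_chr(chrom: str) -> str:
    return chrom if chrom.startswith("chr") else "chr" + chrom


def _data_lines(path: str | Path):
    """Yield (line_number, stripped fields) skipping comments/blank/track lines."""
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            yield ln, line.split("\t")


def _parse_int(text: str, path, ln: int, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"{path}:{ln}: malformed {what} {text!r}") from None


# ---------------------------------------------------------------------------
# BED / narrowPeak peaks
# ---------------------------------------------------------------------------

def read_bed(
    path: str | Path,
    dialect: str = "bed6",
    chr_normalize: bool = False,
) -> list[Peak]:
    """Read peaks from BED3/BED6/narrowPeak. Nameless peaks get generated ids."""
    if dialect not in {"bed3", "bed6", "narrowPeak"}:
        raise ValueError(f"unknown BED dialect {dialect!r}")
    min_cols = {"bed3": 3, "bed6": 3, "narrowPeak": 10}[dialect]
    peaks: list[Peak] = []
    seen_ids: set[str] = set()
    for ln, fields in _data_lines(path):
        if len(fields) < min_cols:
            raise ValueError(
                f"{path}:{ln}: expected >= {min_cols} columns, got {len(fields)}"
            )
        chrom = fields[0]
        if chr_normalize:
            chrom = _ensure_chr(chrom)
        start = _parse_int(fields[1], path, ln, "start")
        end = _parse_int(fields[2], path, ln, "end")
        if end <= start:
            raise ValueError(f"{path}:{ln}: end {end} <= start {start}")
        name = fields[3] if len(fields) > 3 and fields[3] not in ("", ".") else None
        peak_id = name or f"{chrom}:{start}-{end}"
        if peak_id in seen_ids:
            raise ValueError(f"{path}:{ln}: duplicate peak id {peak_id!r}")
        seen_ids.add(peak_id)
        score: float | None = None
        summit: int | None = None
        strand = "."
        if len(fields) > 5 and fields[5] in ("+", "-", "."):
            strand = fields[5]
        if dialect == "narrowPeak":
            score = float(fields[6])  # signalValue
            summit_raw = _parse_int(fields[9], path, ln, "summit")
            summit = None if summit_raw < 0 else summit_raw
        elif len(fields) > 4 and fields[4] not in ("", "."):
            score = float(fields[4])
        peaks.append(
            Peak(GenomicInterval(chrom, start, end, strand), peak_id, score, summit)
        )
    return peaks


def write_bed(peaks: Sequence[Peak], path: str | Path, dialect: str = "bed6") -> None:
    with open(path, "w") as fh:
        for p in peaks:
            iv = p.interval
            if dialect == "bed3":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
            elif dialect == "bed6":
                score = "." if p.score is None else _fmt_num(p.score)
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t{score}\t{iv.strand}\n"
                )
            elif dialect == "narrowPeak":
                signal = 0.0 if p.score is None else p.score
                summit = -1 if p.summit_offset is None else p.summit_offset
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peak_id}\t0\t{iv.strand}"
                    f"\t{_fmt_num(signal)}\t-1\t-1\t{summit}\n"
                )
            else:
                raise ValueError(f"unknown BED dialect {dialect!r}")


def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(float(x))


# ---------------------------------------------------------------------------
# BEDPE loops
# ---------------------------------------------------------------------------

def read_bedpe(path: str | Path, chr_normalize: bool = False) -> list[Loop]:
    """Read loops; drops inter-chromosomal rows (logged) and rejects rows whose
    anchors overlap after left/right ordering (warned)."""
    loops: list[Loop] = []
    n_interchrom = 0
    for ln, fields in _data_lines(path):
        if len(fields) < 6:
            raise ValueError(f"{path}:{ln}: BEDPE needs >= 6 columns")
        chrom1, chrom2 = fields[0], fields[3]
        if chr_normalize:
            chrom1, chrom2 = _ensure_chr(chrom1), _ensure_chr(chrom2)
        if chrom1 != chrom2:
            n_interchrom += 1
            continue
        s1 = _parse_int(fields[1], path, ln, "start1")
        e1 = _parse_int(fields[2], path, ln, "end1")
        s2 = _parse_int(fields[4], path, ln, "start2")
        e2 = _parse_int(fields[5], path, ln, "end2")
        if (s1, e1) > (s2, e2):
            s1, e1, s2, e2 = s2, e2, s1, e1
        name = fields[6] if len(fields) > 6 and fields[6] not in ("", ".") else None
        loop_id = name or f"{chrom1}:{s1}-{e1}..{s2}-{e2}"
        if e1 > s2:
            logger.warning(
                "%s:%d: anchors overlap after ordering, rejecting loop %s",
                path, ln, loop_id,
            )
            continue
        loops.append(
            Loop(loop_id, chrom1,
                 GenomicInterval(chrom1, s1, e1), GenomicInterval(chrom1, s2, e2))
        )
    if n_interchrom:
        logger.info("%s: dropped %d inter-chromosomal record(s)", path, n_interchrom)
    return loops


def write_bedpe(loops: Sequence[Loop], path: str | Path) -> None:
    with open(path, "w") as fh:
        for lp in loops:
            la, ra = lp.left_anchor, lp.right_anchor
            fh.write(
                f"{lp.chrom}\t{la.start}\t{la.end}\t{lp.chrom}\t{ra.start}\t{ra.end}"
                f"\t{lp.loop_id}\n"
            )


# ---------------------------------------------------------------------------
# Gene models (BED12 / GTF)
# ---------------------------------------------------------------------------

def read_gene_models(
    path: str | Path,
    format: str = "bed12",
    chr_normalize: bool = False,
) -> list[GeneModel]:
    """Read gene models; one model per gene id (longest transcript wins,
    ties broken by lexicographically smallest transcript id)."""
    if format == "bed12":
        candidates = _read_bed12(path, chr_normalize)
    elif format == "gtf":
        candidates = _read_gtf(path, chr_normalize)
    else:
        raise ValueError(f"unknown gene-model format {format!r}")
    best: dict[str, tuple] = {}
    for tx_id, gene in candidates:
        key = (-gene.interval.width, tx_id)
        if gene.gene_id not in best or key < best[gene.gene_id][0]:
            best[gene.gene_id] = (key, gene)
    genes = [g for _, g in best.values()]
    genes.sort(key=lambda g: (g.chrom, g.interval.start, g.gene_id))
    return genes


def _derive_utrs(
    exons: list[GenomicInterval], cds_lo: int | None, cds_hi: int | None, strand: str
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    """Exonic sequence outside the CDS extent, split 5'/3' strand-aware."""
    if cds_lo is None or cds_hi is None or cds_lo >= cds_hi:
        return (), ()
    left, right = [], []
    for ex in exons:
        if ex.start < cds_lo:
            left.append(GenomicInterval(ex.chrom, ex.start, min(ex.end, cds_lo)))
        if ex.end > cds_hi:
            right.append(GenomicInterval(ex.chrom, max(ex.start, cds_hi), ex.end))
    if strand == "+":
        return tuple(left), tuple(right)
    return tuple(right), tuple(left)


def _read_bed12(path, chr_normalize):
    out = []
    for ln, fields in _data_lines(path):
        if len(fields) < 12:
            raise ValueError(f"{path}:{ln}: BED12 needs 12 columns")
        chrom = _ensure_chr(fields[0]) if chr_normalize else fields[0]
        start = _parse_int(fields[1], path, ln, "start")
        end = _parse_int(fields[2], path, ln, "end")
        name = fields[3]
        strand = fields[5]
        thick_start = _parse_int(fields[6], path, ln, "thickStart")
        thick_end = _parse_int(fields[7], path, ln, "thickEnd")
        n_blocks = _parse_int(fields[9], path, ln, "blockCount")
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise ValueError(f"{path}:{ln}: blockCount inconsistent with block lists")
        if starts[0] != 0 or starts[-1] + sizes[-1] != end - start:
            raise ValueError(
                f"{path}:{ln}: blockSizes/blockStarts inconsistent with end"
            )
        exons = [
            GenomicInterval(chrom, start + off, start + off + size)
            for off, size in zip(starts, sizes)
        ]
        utr5, utr3 = _derive_utrs(
            exons,
            thick_start if thick_start < thick_end else None,
            thick_end if thick_start < thick_end else None,
            strand,
        )
        gene = GeneModel(
            gene_id=name, gene_name=name,
            interval=GenomicInterval(chrom, start, end, strand),
            strand=strand, exons=tuple(exons), utr5=utr5, utr3=utr3,
        )
        out.append((name, gene))
    return out


def _read_gtf(path, chr_normalize):
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", verbose=False,
    )
    out = []
    for tx in db.features_of_type(("transcript", "mRNA")):
        tx_id = tx.attributes.get("transcript_id", [tx.id])[0]
        gene_id = tx.attributes.get("gene_id", [tx_id])[0]
        gene_name = tx.attributes.get("gene_name", [gene_id])[0]
        chrom = _ensure_chr(tx.seqid) if chr_normalize else tx.seqid
        exons, cds_lo, cds_hi = [], None, None
        for child in db.children(tx, featuretype=("exon", "CDS"), order_by="start"):
            lo, hi = child.start - 1, child.end  # 1-based inclusive -> half-open
            if child.featuretype == "exon":
                exons.append(GenomicInterval(chrom, lo, hi))
            else:
                cds_lo = lo if cds_lo is None else min(cds_lo, lo)
                cds_hi = hi if cds_hi is None else max(cds_hi, hi)
        if not exons:
            continue
        body = GenomicInterval(chrom, tx.start - 1, tx.end, tx.strand)
        utr5, utr3 = _derive_utrs(exons, cds_lo, cds_hi, tx.strand)
        gene = GeneModel(
            gene_id=gene_id, gene_name=gene_name, interval=body,
            strand=tx.strand, exons=tuple(exons), utr5=utr5, utr3=utr3,
        )
        out.append((tx_id, gene))
    return out


def write_gene_models_bed12(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models as BED12; CDS extent (thickStart/End) is reconstructed
    from the UTR blocks so that UTR derivation round-trips."""
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            utr_all = list(g.utr5) + list(g.utr3)
            if utr_all:
                coding = _subtract_blocks(list(g.exons), utr_all)
                if coding:
                    thick_start, thick_end = coding[0].start, coding[-1].end
                else:
                    thick_start = thick_end = iv.start
            else:
                thick_start = thick_end = iv.start
            sizes = ",".join(str(e.width) for e in g.exons)
            starts = ",".join(str(e.start - iv.start) for e in g.exons)
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t{g.strand}"
                f"\t{thick_start}\t{thick_end}\t0\t{len(g.exons)}\t{sizes}\t{starts}\n"
            )


def _subtract_blocks(
    blocks: list[GenomicInterval], cuts: list[GenomicInterval]
) -> list[GenomicInterval]:
    out = []
    for b in blocks:
        pieces = [(b.start, b.end)]
        for c in cuts:
            nxt = []
            for lo, hi in pieces:
                if c.end <= lo or c.start >= hi:
                    nxt.append((lo, hi))
                    continue
                if lo < c.start:
                    nxt.append((lo, c.start))
                if c.end < hi:
                    nxt.append((c.end, hi))
            pieces = nxt
        out.extend(GenomicInterval(b.chrom, lo, hi) for lo, hi in pieces)
    return sorted(out, key=lambda x: x.start)


# ---------------------------------------------------------------------------
# bedGraph eigenvector track
# ---------------------------------------------------------------------------

def read_bedgraph_eigenvector(
    path: str | Path, bin_size: int, chr_normalize: bool = False
) -> list[tuple[GenomicInterval, float]]:
    """Read fixed-step signed eigenvector bins; gaps allowed, bins sorted.

    Every bin must be exactly ``bin_size`` wide except the highest-coordinate
    (terminal) bin of each chromosome, which may be shorter.
    """
    raw: list[tuple[GenomicInterval, float]] = []
    for ln, fields in _data_lines(path):
        if len(fields) < 4:
            raise ValueError(f"{path}:{ln}: bedGraph needs 4 columns")
        chrom = _ensure_chr(fields[0]) if chr_normalize else fields[0]
        start = _parse_int(fields[1], path, ln, "start")
        end = _parse_int(fields[2], path, ln, "end")
        value = float(fields[3])
        if start % bin_size != 0:
            raise ValueError(
                f"{path}:{ln}: bin start {start} not aligned to bin size {bin_size}"
            )
        raw.append((GenomicInterval(chrom, start, end), value))
    raw.sort(key=lambda bv: (bv[0].chrom, bv[0].start))
    last_start: dict[str, int] = {}
    for iv, _ in raw:
        last_start[iv.chrom] = max(last_start.get(iv.chrom, -1), iv.start)
    for iv, _ in raw:
        if iv.width != bin_size and iv.start != last_start[iv.chrom]:
            raise ValueError(
                f"{path}: bin {iv.chrom}:{iv.start}-{iv.end} has width {iv.width}, "
                f"expected {bin_size} (only the terminal bin may be shorter)"
            )
    return raw


def write_bedgraph(
    bins: Sequence[tuple[GenomicInterval, float]], path: str | Path
) -> None:
    ordered = sorted(bins, key=lambda bv: (bv[0].chrom, bv[0].start))
    with open(path, "w") as fh:
        for iv, value in ordered:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{value!r}\n")


# ---------------------------------------------------------------------------
# Expression matrix + design
# ---------------------------------------------------------------------------

def read_expression_table(
    path: str | Path, design_path: str | Path
) -> ExpressionMatrix:
    """Read a genes x samples RPKM TSV plus a sample->group/donor design TSV."""
    values = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    design = pd.read_csv(design_path, sep="\t", comment="#")
    if "sample" not in design.columns or "group" not in design.columns:
        raise ValueError(f"{design_path}: design needs 'sample' and 'group' columns")
    if "donor" not in design.columns:
        design["donor"] = "donor1"
    design = design.set_index("sample")
    return ExpressionMatrix(values, design[["group", "donor"]])


def write_expression_table(
    matrix: ExpressionMatrix, path: str | Path, design_path: str | Path
) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")
    design = matrix.design.reset_index()
    design.columns = ["sample", "group", "donor"]
    design.to_csv(design_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Generic record tables (flat dataclasses <-> TSV)
# ---------------------------------------------------------------------------

def write_table(records, path: str | Path, record_type: type | None = None) -> None:
    """Write a result table as TSV with deterministic column order and row sort.

    ``records`` is a list of flat dataclass instances (or a DataFrame, written
    as-is). Columns follow dataclass field order; rows are sorted by all
    columns; ``None`` is encoded as an empty field. ``record_type`` is required
    only for empty lists (to emit the header).
    """
    if records is None:
        raise ValueError("records must not be None")
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep="\t", index=False)
        return
    records = list(records)
    if records:
        record_type = type(records[0])
    if record_type is None or not dataclasses.is_dataclass(record_type):
        raise ValueError("record_type required for empty record lists")
    cols = [f.name for f in dataclasses.fields(record_type)]
    rows = [
        {c: _MISSING if v is None else v
         for c, v in zip(cols, dataclasses.astuple(r))}
        for r in records
    ]
    df = pd.DataFrame(rows, columns=cols)
    if len(df):
        df = df.sort_values(by=cols, key=lambda s: s.astype(str), kind="mergesort")
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path, record_type: type) -> list:
    """Inverse of :func:`write_table` for a flat dataclass type."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    hints = typing.get_type_hints(record_type)
    out = []
    for row in df.itertuples(index=False):
        kwargs = {}
        for f in dataclasses.fields(record_type):
            raw = getattr(row, f.name)
            kwargs[f.name] = _coerce(raw, hints[f.name])
        out.append(record_type(**kwargs))
    return out


def _coerce(raw: str, hint):
    import types

    origin = typing.get_origin(hint)
    if origin is typing.Union or origin is types.UnionType:
        args = [a for a in typing.get_args(hint) if a is not type(None)]
        if raw == _MISSING:
            return None
        hint = args[0]
    if hint is int:
        return int(raw)
    if hint is float:
        return float(raw)
    if hint is bool:
        return raw == "True"
    return raw
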