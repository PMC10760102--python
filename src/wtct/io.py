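"""Readers and writers for the external file formats the pipeline touches.

Supported formats: BED3+/BED6, ENCODE narrowPeak (10 columns, qValue in
column 9 as -log10), tab-separated tables with a header, minimal GTF, GMT
gene sets, chromatin-state BED segmentations and plain expression matrices.
Everything is parsed into the validated value objects of
:mod:`wtct.models`; coordinates are 0-based half-open internally, and the
minimal-GTF reader is the single 1-based conversion point.
"""
from __future__ import annotations

import logging
import math
import re
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .models import (
    DEGRecord,
    GeneModel,
    GenomicInterval,
    NESRecord,
    Peak,
    StateSegment,
)

logger = logging.getLogger(__name__)

PEAK_FORMATS = ("bed", "narrowpeak", "tsv")
GENE_FORMATS = ("bed6", "gtf_min")

_GTF_GENE_ID = re.compile(r'gene_id\s+"([^"]+)"')


class FormatError(ValueError):
    """A malformed input file; the message carries the line number."""


def _lines(path: str | Path):
    """Yield (1-based line number, tab-split fields), skipping comments."""
    with open(path, encoding="utf-8", newline="") as fh:
        for i, raw in enumerate(fh, start=1):
            line = raw.rstrip("\r\n")
            if not line or line.startswith(("#", "track ", "browser ")):
                continue
            yield i, line.split("\t")


def _to_int(value: str, what: str, path, lineno) -> int:
    try:
        return int(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-integer {what}: {value!r}"
        ) from None


def _to_float(value: str, what: str, path, lineno) -> float:
    try:
        return float(value)
    except ValueError:
        raise FormatError(
            f"{path}:{lineno}: non-numeric {what}: {value!r}"
        ) from None


def neglog10_padj(padj: float) -> float:
    """-log10 of an adjusted p in (0,1]; exact zeros are clamped."""
    if padj < 0 or padj > 1:
        raise ValueError(f"adjusted p outside [0,1]: {padj}")
    if padj == 0:
        clamped = np.nextafter(0.0, 1.0)
        logger.warning("adjusted p of 0 clamped to %.3g before -log10", clamped)
        padj = clamped
    return -math.log10(padj)


def _interval(fields, path, lineno, strand=".") -> GenomicInterval:
    start = _to_int(fields[1], "start", path, lineno)
    end = _to_int(fields[2], "end", path, lineno)
    try:
        return GenomicInterval(fields[0], start, end, strand)
    except ValueError as exc:
        raise FormatError(f"{path}:{lineno}: {exc}") from None


def read_peaks(
    path: str | Path,
    format: str = "bed",
    padj_column: int | str | None = None,
    source: str = "",
) -> list[Peak]:
    """Read peaks from BED3+, narrowPeak or a tab-separated table.

    ``padj_column`` names the adjusted-p column: a 1-based ordinal for
    header-less files, a header name for ``tsv`` files with a header.
    narrowPeak carries -log10(q) directly in column 9. A ``tsv`` file whose
    header includes ``neglog_padj`` (as written by :func:`write_peaks`) is
    read back verbatim.
    """
    if format not in PEAK_FORMATS:
        raise ValueError(f"unknown peak format: {format!r}")
    if format == "tsv" and not isinstance(padj_column, int):
        return _read_peaks_tsv_header(path, padj_column, source)

    peaks: list[Peak] = []
    seen: set[str] = set()
    for lineno, fields in _lines(path):
        if format == "narrowpeak":
            if len(fields) != 10:
                raise FormatError(
                    f"{path}:{lineno}: narrowPeak requires 10 columns, "
                    f"got {len(fields)}"
                )
            strand = fields[5] if fields[5] in "+-." else "."
            iv = _interval(fields, path, lineno, strand)
            name = fields[3]
            nlp = _to_float(fields[8], "qValue", path, lineno)
            if nlp < 0:
                raise FormatError(
                    f"{path}:{lineno}: missing/negative narrowPeak qValue"
                )
        else:  # bed, or tsv with ordinal padj column
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: fewer than 3 columns"
                )
            iv = _interval(fields, path, lineno)
            name = fields[3] if len(fields) > 3 else f"peak_{len(peaks) + 1}"
            if padj_column is not None:
                col = int(padj_column) - 1
                if col >= len(fields):
                    raise FormatError(
                        f"{path}:{lineno}: padj column {padj_column} "
                        f"beyond {len(fields)} fields"
                    )
                padj = _to_float(fields[col], "adjusted p", path, lineno)
                try:
                    nlp = neglog10_padj(padj)
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: {exc}") from None
            else:
                nlp = 0.0
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate peak name {name!r}")
        seen.add(name)
        peaks.append(Peak(iv, name, nlp, source))
    return peaks


def _read_peaks_tsv_header(path, padj_column, source) -> list[Peak]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str},
                     float_precision="round_trip")
    for col in ("chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    direct = "neglog_padj" in df.columns
    pcol = padj_column or ("padj" if "padj" in df.columns else None)
    if not direct and pcol is None:
        raise FormatError(f"{path}: no neglog_padj or padj column")
    if pcol is not None and not direct and pcol not in df.columns:
        raise FormatError(f"{path}: missing column {pcol!r}")
    peaks: list[Peak] = []
    seen: set[str] = set()
    def text(value, default):
        return default if value is None or pd.isna(value) else str(value)

    for i, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict()
        name = text(row.get("name"), f"peak_{i - 1}")
        strand = text(row.get("strand"), ".")
        try:
            iv = GenomicInterval(
                str(row["chrom"]), int(row["start"]), int(row["end"]),
                strand if strand in "+-." else ".",
            )
            nlp = (
                float(row["neglog_padj"])
                if direct
                else neglog10_padj(float(row[pcol]))
            )
            peak = Peak(iv, name, nlp, text(row.get("source"), source))
        except ValueError as exc:
            raise FormatError(f"{path}:{i}: {exc}") from None
        if name in seen:
            raise FormatError(f"{path}:{i}: duplicate peak name {name!r}")
        seen.add(name)
        peaks.append(peak)
    return peaks


def write_peaks(peaks: Iterable[Peak], path: str | Path) -> None:
    """Write peaks as a headered TSV that round-trips field-for-field."""
    rows = [
        (
            p.interval.chrom, p.interval.start, p.interval.end, p.name,
            p.interval.strand, repr(p.neglog_padj), p.source,
        )
        for p in peaks
    ]
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "strand", "neglog_padj",
                 "source"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_genes(path: str | Path, format: str = "bed6") -> list[GeneModel]:
    """Read a gene catalog from BED6 or minimal GTF (gene lines)."""
    if format not in GENE_FORMATS:
        raise ValueError(f"unknown gene format: {format!r}")
    genes: list[GeneModel] = []
    seen: set[str] = set()
    n_dot = 0
    for lineno, fields in _lines(path):
        if format == "bed6":
            if len(fields) < 6:
                raise FormatError(
                    f"{path}:{lineno}: bed6 requires 6 columns "
                    "(missing strand?)"
                )
            strand = fields[5]
            if strand == ".":
                n_dot += 1
            elif strand not in "+-":
                raise FormatError(f"{path}:{lineno}: invalid strand {strand!r}")
            iv = _interval(fields, path, lineno, strand)
            gene_id = fields[3]
        else:  # gtf_min: 1-based inclusive -> 0-based half-open
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: GTF requires 9 columns")
            if fields[2] != "gene":
                continue
            start = _to_int(fields[3], "start", path, lineno) - 1
            end = _to_int(fields[4], "end", path, lineno)
            strand = fields[6] if fields[6] in "+-." else "."
            if strand == ".":
                n_dot += 1
            try:
                iv = GenomicInterval(fields[0], start, end, strand)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            m = _GTF_GENE_ID.search(fields[8])
            if not m:
                raise FormatError(f"{path}:{lineno}: no gene_id attribute")
            gene_id = m.group(1)
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        genes.append(GeneModel(gene_id, iv))
    if n_dot:
        logger.warning(
            "%s: %d gene(s) with '.' strand treated as plus-strand",
            path, n_dot,
        )
    return genes


def write_genes(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{g.gene_id}\t0\t"
                f"{iv.strand}\n"
            )


DEFAULT_DE_COLUMNS = {
    "gene": "gene_id",
    "log_fc": "log_fc",
    "log_pv": "log_pv",
    "padj": "padj",
}


def read_de_table(
    path: str | Path,
    columns: Mapping[str, str] | None = None,
) -> list[DEGRecord]:
    """Read a differential-expression table (TSV with header).

    ``columns`` maps the roles gene/log_fc/log_pv/padj to header names.
    Rows with missing values in any mapped column are dropped (count
    logged); duplicate genes are an error.
    """
    colmap = dict(DEFAULT_DE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in colmap.values() if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    sub = df[[colmap["gene"], colmap["log_fc"], colmap["log_pv"],
              colmap["padj"]]]
    n_na = int(sub.isna().any(axis=1).sum())
    if n_na:
        logger.warning("%s: dropped %d row(s) with missing values", path, n_na)
        sub = sub.dropna()
    if sub.empty:
        logger.warning("%s: empty differential-expression table", path)
        return []
    records: list[DEGRecord] = []
    seen: set[str] = set()
    for gene, lfc, lpv, padj in sub.itertuples(index=False):
        gene = str(gene)
        if gene in seen:
            raise FormatError(f"{path}: duplicate gene {gene!r}")
        seen.add(gene)
        try:
            records.append(DEGRecord(gene, float(lfc), float(lpv), float(padj)))
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from None
    return records


def write_de_table(records: Iterable[DEGRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.gene_id, repr(r.log_fc), repr(r.log_pv), repr(r.padj))
         for r in records],
        columns=["gene_id", "log_fc", "log_pv", "padj"],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_segments(path: str | Path) -> list[StateSegment]:
    """Read a chromatin-state segmentation (BED4: chrom start end state)."""
    segments: list[StateSegment] = []
    for lineno, fields in _lines(path):
        if len(fields) < 4:
            raise FormatError(f"{path}:{lineno}: segmentation needs 4 columns")
        segments.append(StateSegment(_interval(fields, path, lineno), fields[3]))
    return segments


def write_segments(segments: Iterable[StateSegment], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in segments:
            iv = s.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{s.state}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT gene sets: name, description, then members."""
    sets: dict[str, set[str]] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 3:
            raise FormatError(
                f"{path}:{lineno}: GMT needs name, description and members"
            )
        name = fields[0]
        if name in sets:
            raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
        sets[name] = {m for m in fields[2:] if m}
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_nes_table(
    path: str | Path,
    term_col: str = "term",
    nes_col: str = "nes",
    background_col: str | None = "background",
) -> list[NESRecord]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    for col in (term_col, nes_col):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    has_bg = background_col is not None and background_col in df.columns
    records: list[NESRecord] = []
    seen: set[tuple[str, str]] = set()
    for _, row in df.iterrows():
        bg = str(row[background_col]) if has_bg else ""
        key = (str(row[term_col]), bg)
        if key in seen:
            raise FormatError(f"{path}: duplicate (term, background) {key}")
        seen.add(key)
        records.append(NESRecord(str(row[term_col]), float(row[nes_col]), bg))
    return records


def read_expression_matrix(path: str | Path) -> pd.DataFrame:
    """Read a samples x genes matrix (TSV, header = gene ids, col 0 = sample)."""
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    if df.empty:
        raise FormatError(f"{path}: empty expression matrix")
    return df


def write_expression_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", lineterminator="\n")


def read_id_list(path: str | Path) -> list[str]:
    """One identifier per line; order preserved; duplicates are an error."""
    ids: list[str] = []
    seen: set[str] = set()
    for lineno, fields in _lines(path):
        token = fields[0].strip()
        if token in seen:
            raise FormatError(f"{path}:{lineno}: duplicate id {token!r}")
        seen.add(token)
        ids.append(token)
    return ids


def write_id_list(ids: Sequence[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.writelines(f"{i}\n" for i in ids)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lineno, fields in _lines(path):
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: chrom sizes need 2 columns")
        sizes[fields[0]] = _to_int(fields[1], "size", path, lineno)
    return sizes


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")
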