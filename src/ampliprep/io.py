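"""Readers and writers for the formats the pipeline touches.

FASTQ (optionally gzipped, Phred+33), QIIME-style sample-metadata TSV,
feature-table TSV (features as rows, samples as columns) and representative
sequence FASTA.  Gzip is detected from the file's magic bytes, never from
its extension.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path
from typing import Iterable, Iterator, TextIO

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import MetadataError, ParseError
from .types import MAX_PHRED, FastqRecord, FeatureTable, SampleMetadata

_GZIP_MAGIC = b"\x1f\x8b"

DEFAULT_ID_COL = "sample-id"
DEFAULT_BARCODE_COL = "barcode-sequence"


def _open_text_auto(path) -> TextIO:
    """Open plain or gzipped text, sniffing the gzip magic bytes."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == _GZIP_MAGIC:
        return gzip.open(path, "rt", encoding="ascii")
    return open(path, "rt", encoding="ascii")


def read_fastq(path, encoding: str = "phred+33") -> Iterator[FastqRecord]:
    """Stream :class:`FastqRecord` objects from a FASTQ(.gz) file.

    Only Phred+33 is supported; requesting ``phred+64`` raises immediately
    rather than silently mis-decoding qualities.  Malformed records raise
    :class:`ParseError` naming the offending line.
    """
    if encoding.lower().replace("_", "+") not in {"phred+33", "phred33"}:
        raise ValueError(
            f"unsupported quality encoding {encoding!r}: only Phred+33 FASTQ "
            "is accepted (Phred+64 is a legacy Illumina format; convert first)"
        )
    path = Path(path)
    with _open_text_auto(path) as fh:
        line_no = 0
        while True:
            header = fh.readline()
            if not header:
                return
            line_no += 1
            header = header.rstrip("\n")
            if not header.startswith("@"):
                raise ParseError(
                    f"expected '@' header, got {header[:30]!r}", path, line_no
                )
            seq = fh.readline().rstrip("\n")
            plus = fh.readline().rstrip("\n")
            qual = fh.readline().rstrip("\n")
            if not qual and not plus:
                raise ParseError("truncated record", path, line_no)
            line_no += 3
            if not plus.startswith("+"):
                raise ParseError(f"expected '+' separator, got {plus[:30]!r}", path, line_no - 1)
            if len(seq) != len(qual):
                raise ParseError(
                    f"read {header[1:]!r}: {len(seq)} bases but "
                    f"{len(qual)} quality characters",
                    path,
                    line_no,
                )
            try:
                quals = _decode_quals(qual)
            except ValueError as exc:
                raise ParseError(str(exc), path, line_no) from exc
            yield FastqRecord(header[1:], seq.upper(), quals)


def _decode_quals(qual: str) -> tuple[int, ...]:
    scores = tuple(ord(c) - 33 for c in qual)
    for q in scores:
        if not 0 <= q <= MAX_PHRED:
            raise ValueError(f"quality character outside Phred+33 range: score {q}")
    return scores


def write_fastq(records: Iterable[FastqRecord], path) -> int:
    """Write records as 4-line Phred+33 FASTQ; returns the record count.

    Gzip-compresses when the target path ends in ``.gz``.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    n = 0
    with opener(path, "wt", encoding="ascii") as fh:
        for rec in records:
            fh.write(format_fastq_record(rec))
            n += 1
    return n


def format_fastq_record(rec: FastqRecord) -> str:
    qual = "".join(chr(q + 33) for q in rec.quals)
    return f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n"


def read_metadata(
    path,
    id_col: str = DEFAULT_ID_COL,
    barcode_col: str = DEFAULT_BARCODE_COL,
) -> SampleMetadata:
    """Read a QIIME-style tab-separated sample-metadata file.

    The header must contain both named columns; rows starting with ``#``
    (QIIME type annotations) are skipped.  Barcode case is normalized to
    upper; duplicate ids/barcodes and unequal barcode lengths raise
    :class:`MetadataError`.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"cannot parse metadata TSV: {exc}", path) from exc
    for col in (id_col, barcode_col):
        if col not in df.columns:
            raise MetadataError(
                f"{path}: metadata is missing required column {col!r} "
                f"(found: {list(df.columns)})"
            )
    df = df[~df[id_col].astype(str).str.startswith("#")]
    pairs = [
        (str(row[id_col]).strip(), str(row[barcode_col]).strip())
        for _, row in df.iterrows()
    ]
    return SampleMetadata(pairs)


def read_feature_table(path, seqs_path=None) -> FeatureTable:
    """Read a feature table TSV (first column = feature ids, rest = samples).

    Cells must be integers; ragged rows or non-integer cells raise
    :class:`ParseError`.  A representative-sequence FASTA may be attached
    via ``seqs_path``.
    """
    path = Path(path)
    rows: list[list[str]] = []
    with _open_text_auto(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ParseError("empty feature table", path)
    header = rows[0]
    n_cols = len(header)
    sample_ids = header[1:]
    feature_ids: list[str] = []
    data: list[list[int]] = []
    for line_no, row in enumerate(rows[1:], start=2):
        if len(row) != n_cols:
            raise ParseError(
                f"ragged row: expected {n_cols} fields, got {len(row)}",
                path,
                line_no,
            )
        feature_ids.append(row[0])
        counts_row = []
        for cell in row[1:]:
            try:
                counts_row.append(int(cell))
            except ValueError:
                raise ParseError(
                    f"non-integer count {cell!r} in row {row[0]!r}", path, line_no
                ) from None
        data.append(counts_row)
    df = pd.DataFrame(data, index=feature_ids, columns=sample_ids, dtype="int64")
    feature_seqs = read_fasta(seqs_path) if seqs_path is not None else None
    try:
        return FeatureTable(df, feature_seqs)
    except ValueError as exc:
        raise ParseError(str(exc), path) from exc


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table as TSV; round-trips exactly with the reader."""
    table.counts.to_csv(path, sep="\t", index_label="feature-id")


def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered id -> uppercase-sequence map."""
    seqs: dict[str, str] = {}
    with _open_text_auto(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ParseError(f"duplicate sequence id {rec.id!r}", path)
            seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=fid, description="") for fid, seq in seqs.items()
    ]
    with open(path, "w", encoding="ascii") as fh:
        SeqIO.write(records, fh, "fasta-2line")
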