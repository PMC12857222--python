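"""Readers and writers for the plain-text formats the pipeline touches.

FASTQ parsing is delegated to Biopython's fast four-line iterator; this
module adds strict validation (record index in error messages, Phred+33
decoding, sequence/quality length agreement) and round-trip writers.
"""

from __future__ import annotations

import csv
import gzip
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass
from pathlib import Path
from typing import IO

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PHRED_OFFSET = 33


class SeqIOError(ValueError):
    """Raised for malformed input files."""


@dataclass
class Read:
    """One amplicon read: identifier, nucleotides, per-base Phred scores."""

    id: str
    seq: str
    quals: list[int]

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("read id must be non-empty")
        if len(self.quals) != len(self.seq):
            raise SeqIOError(
                f"read {self.id!r}: quality length {len(self.quals)} "
                f"!= sequence length {len(self.seq)}"
            )


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode, encoding="utf-8")


def read_fastq(path: str | Path) -> Iterator[Read]:
    """Yield reads from a four-line FASTQ file (Phred+33).

    Raises :class:`SeqIOError` naming the record index on malformed input.
    An empty file yields nothing.
    """
    index = 0
    with _open_text(path) as handle:
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                if len(seq) != len(qual):
                    raise SeqIOError(
                        f"{path}: record {index}: quality length differs from sequence"
                    )
                quals = [ord(c) - PHRED_OFFSET for c in qual]
                if any(q < 0 for q in quals):
                    raise SeqIOError(
                        f"{path}: record {index}: quality characters below Phred+33 range"
                    )
                yield Read(id=title.split()[0], seq=seq.upper(), quals=quals)
                index += 1
        except ValueError as exc:
            if isinstance(exc, SeqIOError):
                raise
            raise SeqIOError(f"{path}: record {index}: {exc}") from exc


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """Write reads as four-line FASTQ (Phred+33)."""
    with _open_text(path, "wt") as handle:
        for read in reads:
            qual = "".join(chr(q + PHRED_OFFSET) for q in read.quals)
            handle.write(f"@{read.id}\n{read.seq}\n+\n{qual}\n")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Parse FASTA into an id -> uppercase sequence map.

    Duplicate ids and empty sequences are rejected.
    """
    result: dict[str, str] = {}
    with _open_text(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in result:
                raise SeqIOError(f"{path}: duplicate FASTA id {record.id!r}")
            seq = str(record.seq).upper()
            if not seq:
                raise SeqIOError(f"{path}: empty sequence for FASTA id {record.id!r}")
            result[record.id] = seq
    return result


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    with _open_text(path, "wt") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


def write_table(
    records: Iterable[Mapping[str, object]],
    path: str | Path,
    columns: list[str],
) -> None:
    """Write records as a header-bearing TSV.

    All records are validated (every column present, no tabs/newlines in
    values) before anything is written, so a failure leaves no partial file.
    """
    rows: list[list[str]] = []
    for i, record in enumerate(records):
        row = []
        for col in columns:
            if col not in record:
                raise SeqIOError(f"record {i} is missing field {col!r}")
            value = record[col]
            text = "" if value is None else str(value)
            if "\t" in text or "\n" in text or "\r" in text:
                raise SeqIOError(f"record {i} field {col!r} contains a delimiter character")
            row.append(text)
        rows.append(row)
    with _open_text(path, "wt") as handle:
        handle.write("\t".join(columns) + "\n")
        for row in rows:
            handle.write("\t".join(row) + "\n")


def read_table(path: str | Path) -> list[dict[str, str]]:
    """Read a header-bearing TSV back into a list of string-valued dicts."""
    with _open_text(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        return [dict(row) for row in reader]
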