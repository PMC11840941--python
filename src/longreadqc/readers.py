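"""Streaming readers for text-based sequencing inputs.

FASTA and FASTQ parsing is delegated to htslib's kseq via
:class:`pysam.FastxFile` (gzip-transparent); this module adds the record
model and strict validation. ONT basecall summary ("seqtxt") files are
tab-separated tables with platform-dependent column names, matched here
against a configurable alias table.

Phred encoding is fixed at +33 (Sanger). +64 dialects are not
auto-detected: every modern long-read emitter writes +33, and silent
misdetection would corrupt every downstream quality statistic.
"""

from __future__ import annotations

import csv
import gzip
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pysam

from .errors import ParseError, UnsupportedDialectError

# Bases are upper-cased on read; U kept distinct from T (direct-RNA input
# is first-class). Anything outside this set is preserved but counts as N
# for composition purposes downstream.
VALID_BASES = frozenset("ACGTUN")


@dataclass
class SeqRecord:
    """One sequencing read: identifier, bases, optional per-base Phred scores."""

    read_id: str
    bases: str
    quals: list[int] | None = None
    source: str = "fasta"

    def __post_init__(self):
        if self.quals is not None and len(self.quals) != len(self.bases):
            raise ParseError(
                f"quality length {len(self.quals)} != sequence length "
                f"{len(self.bases)}", record=self.read_id)

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class SummaryRow:
    """One row of an ONT basecall summary file.

    Unrecognized columns are preserved verbatim in ``extra`` so the row
    round-trips.
    """

    read_id: str
    length: int
    mean_qscore: float | None = None
    passes_filtering: bool | None = None
    extra: dict[str, str] = field(default_factory=dict)


def _open_text(path) -> io.TextIOBase:
    """Open a possibly gzip-compressed text file (sniffed by magic bytes)."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "rt", encoding="utf-8")


def _check_first_header(path, expected: str, fmt: str) -> None:
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(expected):
                raise ParseError(
                    f"{fmt} record header must start with {expected!r}, "
                    f"got {line.rstrip()[:40]!r}", line=lineno)
            return
    # empty file: fine, zero records


def read_fasta(path) -> Iterator[SeqRecord]:
    """Stream records from a FASTA file (plain or gzipped).

    Multi-line sequences are concatenated; bases are upper-cased.
    Raises :class:`ParseError` when the first non-blank line is not a
    ``>`` header.
    """
    _check_first_header(path, ">", "FASTA")
    with pysam.FastxFile(str(path)) as fx:
        for entry in fx:
            seq = (entry.sequence or "").upper()
            if not seq:
                raise ParseError("empty sequence", record=entry.name)
            yield SeqRecord(entry.name, seq, None, source="fasta")


def read_fastq(path) -> Iterator[SeqRecord]:
    """Stream records from a strict 4-line FASTQ file (plain or
    gzipped), Phred+33.

    Modern long-read emitters write strictly 4-line records, so the
    parser enforces that layout; it raises :class:`ParseError` naming
    the read on quality-length mismatch and on truncation.
    """
    _check_first_header(path, "@", "FASTQ")
    with _open_text(path) as fh:
        lineno = 0
        while True:
            header = fh.readline()
            if header == "":
                return
            lineno += 1
            if header.strip() == "":
                continue
            if not header.startswith("@"):
                raise ParseError("FASTQ header must start with '@'",
                                 line=lineno)
            name = header[1:].rstrip("\n").split()[0] if \
                header[1:].strip() else ""
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            if qual == "" or plus == "" or seq == "":
                raise ParseError("truncated FASTQ record", record=name,
                                 line=lineno)
            lineno += 3
            if not plus.startswith("+"):
                raise ParseError("FASTQ separator line must start with '+'",
                                 record=name, line=lineno - 1)
            seq = seq.rstrip("\n").upper()
            qual = qual.rstrip("\n")
            if len(qual) != len(seq):
                raise ParseError(
                    f"quality length {len(qual)} != sequence length "
                    f"{len(seq)}", record=name)
            quals = [ord(c) - 33 for c in qual]
            if any(q < 0 for q in quals):
                raise ParseError("quality character below Phred+33 '!'",
                                 record=name)
            yield SeqRecord(name, seq, quals, source="fastq")


def write_fastq(records, path) -> None:
    """Serialize records as 4-line FASTQ (Phred+33). Inverse of read_fastq."""
    with open(path, "wt", encoding="utf-8") as fh:
        for rec in records:
            if rec.quals is None:
                raise ParseError("cannot write FASTQ without qualities",
                                 record=rec.read_id)
            qual = "".join(chr(q + 33) for q in rec.quals)
            fh.write(f"@{rec.read_id}\n{rec.bases}\n+\n{qual}\n")


# Canonical column -> accepted header aliases (matched case-insensitively).
# ONT basecall summaries never had a pinned schema; extend via the
# ``aliases`` argument of read_seqtxt for other dialects.
SEQTXT_ALIASES: dict[str, tuple[str, ...]] = {
    "read_id": ("read_id",),
    "length": ("sequence_length_template", "sequence_length"),
    "quality": ("mean_qscore_template", "mean_qscore"),
    "filter": ("passes_filtering",),
}

_TRUE = {"true", "t", "1", "yes", "pass"}
_FALSE = {"false", "f", "0", "no", "fail"}


def read_seqtxt(path, aliases: dict[str, tuple[str, ...]] | None = None,
                passes_only: bool = False) -> Iterator[SummaryRow]:
    """Stream rows from a tab-separated basecall summary file.

    Column names are matched case-insensitively against the alias table.
    With ``passes_only`` set, rows whose filter column is false are dropped.

    Raises :class:`UnsupportedDialectError` when no length (or read-id)
    column is present, listing the columns found.
    """
    table = aliases or SEQTXT_ALIASES
    with _open_text(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError("empty basecall summary file (no header)", line=1)
        lower = [h.strip().lower() for h in header]

        def find(canon: str) -> int | None:
            for alias in table.get(canon, ()):
                if alias.lower() in lower:
                    return lower.index(alias.lower())
            return None

        idx = {canon: find(canon) for canon in ("read_id", "length",
                                                "quality", "filter")}
        if idx["length"] is None or idx["read_id"] is None:
            missing = "length" if idx["length"] is None else "read_id"
            raise UnsupportedDialectError(
                f"basecall summary header lacks a recognized {missing} "
                f"column; found columns: {header}", line=1)
        known = {i for i in idx.values() if i is not None}

        for lineno, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and row[0].strip() == ""):
                continue
            if len(row) < len(header):
                raise ParseError(
                    f"row has {len(row)} fields, header has {len(header)}",
                    line=lineno)
            try:
                length = int(row[idx["length"]])
            except ValueError:
                raise ParseError(
                    f"non-integer length {row[idx['length']]!r}", line=lineno)
            if length < 0:
                raise ParseError(f"negative length {length}", line=lineno)
            qscore = None
            if idx["quality"] is not None and row[idx["quality"]].strip():
                try:
                    qscore = float(row[idx["quality"]])
                except ValueError:
                    raise ParseError(
                        f"non-numeric quality {row[idx['quality']]!r}",
                        line=lineno)
            passes = None
            if idx["filter"] is not None:
                raw = row[idx["filter"]].strip().lower()
                if raw in _TRUE:
                    passes = True
                elif raw in _FALSE:
                    passes = False
            if passes_only and passes is False:
                continue
            extra = {header[i]: row[i] for i in range(len(header))
                     if i not in known}
            yield SummaryRow(row[idx["read_id"]], length, qscore, passes, extra)
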