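"""Read- and base-level alignment accounting for SAM/BAM files.

Reads are classified into disjoint categories (unmapped > secondary >
supplementary > primary) and bases are accounted by CIGAR operation.
Mismatches are resolved from the most specific evidence available:
explicit =/X operations, then the MD tag, then NM arithmetic
(NM minus inserted minus deleted bases).

Each molecule is counted once: secondary and supplementary records
contribute to read category counts but not to length/GC statistics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pysam

from .errors import ParseError
from .stats import BasicStats, ReadSetAccumulator

READ_CATEGORIES = ("primary_mapped", "secondary", "supplementary", "unmapped",
                   "forward_strand", "reverse_strand")
BASE_CATEGORIES = ("aligned_match_ops", "matched", "mismatched", "inserted",
                   "deleted", "soft_clipped", "hard_clipped")

# pysam CIGAR op codes
_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)

_MD_TOKEN = re.compile(r"(\d+)|(\^[A-Za-z]+)|([A-Za-z])")


@dataclass
class CigarContribution:
    """Per-read base accounting from one alignment record."""

    aligned_match_ops: int = 0
    mismatched: int | None = 0   # None: unresolvable from available evidence
    inserted: int = 0
    deleted: int = 0
    soft_clipped: int = 0
    hard_clipped: int = 0

    @property
    def matched(self) -> int | None:
        if self.mismatched is None:
            return None
        return self.aligned_match_ops - self.mismatched


@dataclass
class AlignmentSummary:
    """Read/base alignment category counters plus mapped/unmapped stats."""

    read_counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in READ_CATEGORIES})
    base_counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in BASE_CATEGORIES})
    # duplicate/QC-fail flags co-occur with the categories above; kept as
    # a diagnostics row, still included in alignment stats
    duplicate_reads: int = 0
    qc_fail_reads: int = 0
    mismatch_unresolved_reads: int = 0
    mapped_acc: ReadSetAccumulator = field(default_factory=ReadSetAccumulator)
    unmapped_acc: ReadSetAccumulator = field(default_factory=ReadSetAccumulator)

    @property
    def mapped_stats(self) -> BasicStats:
        return self.mapped_acc.basic_stats()

    @property
    def unmapped_stats(self) -> BasicStats:
        return self.unmapped_acc.basic_stats()

    @property
    def per_read_qualities(self) -> list[float]:
        return self.mapped_acc.per_read_quality + self.unmapped_acc.per_read_quality


def classify_read(flag: int) -> tuple[str, str | None]:
    """Map a SAM flag to (category, strand-or-None).

    Precedence: unmapped (0x4) > secondary (0x100) > supplementary
    (0x800) > primary mapped. Strand (from 0x10) is reported for primary
    mapped reads only, keeping the category bars disjoint.
    """
    if flag & 0x4:
        return "unmapped", None
    if flag & 0x100:
        return "secondary", None
    if flag & 0x800:
        return "supplementary", None
    return "primary_mapped", "reverse" if flag & 0x10 else "forward"


def count_md_mismatches(md: str) -> int:
    """Number of mismatched reference bases encoded in an MD tag.

    Single letters are mismatches; ^-prefixed runs are deletions and are
    not counted.
    """
    mismatches = 0
    pos = 0
    for m in _MD_TOKEN.finditer(md):
        if m.start() != pos:
            raise ParseError(f"malformed MD string {md!r}")
        pos = m.end()
        if m.group(3):
            mismatches += 1
    if pos != len(md):
        raise ParseError(f"malformed MD string {md!r}")
    return mismatches


def accumulate_cigar(cigar: list[tuple[int, int]], nm: int | None = None,
                     md: str | None = None) -> CigarContribution:
    """Account one record's CIGAR into base categories.

    ``cigar`` is a pysam-style list of (op, length) tuples. N (skip) and
    P (pad) consume no counted bases. Mismatch evidence priority:
    explicit =/X ops, then MD, then NM - inserted - deleted; if NM is
    inconsistent (less than indel bases) the mismatch count is marked
    unresolvable rather than clamped.
    """
    c = CigarContribution()
    explicit_x = 0
    has_eq_x = False
    for op, length in cigar:
        if op in (_M, _EQ, _X):
            c.aligned_match_ops += length
            if op == _X:
                explicit_x += length
            if op in (_EQ, _X):
                has_eq_x = True
        elif op == _I:
            c.inserted += length
        elif op == _D:
            c.deleted += length
        elif op == _S:
            c.soft_clipped += length
        elif op == _H:
            c.hard_clipped += length
        elif op in (_N, _P):
            pass
        else:
            raise ParseError(f"unknown CIGAR op code {op}")
    if has_eq_x:
        c.mismatched = explicit_x
    elif md is not None:
        c.mismatched = count_md_mismatches(md)
    elif nm is not None:
        mm = nm - c.inserted - c.deleted
        c.mismatched = mm if mm >= 0 else None
    else:
        c.mismatched = None
    return c


def summarize_bam(path, thread_hint: int = 1, read_filter=None,
                  collect_read_ids: bool = False) -> AlignmentSummary:
    """Linear scan of a SAM/BAM file into an AlignmentSummary.

    No index is required. ``read_filter(read_id) -> bool`` restricts the
    summary to a subset of molecules (used for RRMS partitions);
    ``thread_hint`` sizes htslib's decompression pool and never changes
    results. Per-read qualities cover primary and unmapped records that
    carry quality strings; secondary/supplementary records count toward
    read categories only.
    """
    summary = AlignmentSummary()
    if collect_read_ids:
        summary.read_ids = set()
    with pysam.AlignmentFile(str(path), check_sq=False,
                             threads=max(1, thread_hint)) as bam:
        iterator = bam.fetch(until_eof=True)
        ordinal = 0
        while True:
            try:
                rec = next(iterator)
            except StopIteration:
                break
            except Exception as exc:
                raise ParseError(
                    f"failed reading alignment record {ordinal + 1}: {exc}")
            ordinal += 1
            if read_filter is not None and not read_filter(rec.query_name):
                continue
            if collect_read_ids:
                summary.read_ids.add(rec.query_name)
            category, strand = classify_read(rec.flag)
            summary.read_counts[category] += 1
            if strand is not None:
                summary.read_counts[f"{strand}_strand"] += 1
            if rec.flag & 0x400:
                summary.duplicate_reads += 1
            if rec.flag & 0x200:
                summary.qc_fail_reads += 1

            if category == "unmapped":
                if rec.query_sequence:
                    summary.unmapped_acc.add_sequence(
                        rec.query_sequence.upper(),
                        list(rec.query_qualities)
                        if rec.query_qualities is not None else None)
                continue

            nm = rec.get_tag("NM") if rec.has_tag("NM") else None
            md = rec.get_tag("MD") if rec.has_tag("MD") else None
            contrib = accumulate_cigar(rec.cigartuples or [], nm, md)
            summary.base_counts["aligned_match_ops"] += contrib.aligned_match_ops
            summary.base_counts["inserted"] += contrib.inserted
            summary.base_counts["deleted"] += contrib.deleted
            summary.base_counts["soft_clipped"] += contrib.soft_clipped
            summary.base_counts["hard_clipped"] += contrib.hard_clipped
            if contrib.mismatched is None:
                summary.mismatch_unresolved_reads += 1
            else:
                summary.base_counts["mismatched"] += contrib.mismatched
                summary.base_counts["matched"] += contrib.matched

            if category == "primary_mapped" and rec.query_sequence:
                summary.mapped_acc.add_sequence(
                    rec.query_sequence.upper(),
                    list(rec.query_qualities)
                    if rec.query_qualities is not None else None)
    return summary
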