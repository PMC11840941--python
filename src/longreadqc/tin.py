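"""Transcript integrity number (TIN) for RNA-seq BAMs.

TIN scores coverage uniformity across a transcript on a 0-100 scale.
Coverage c_i is measured at k positions sampled uniformly along the
mRNA; with p_i = c_i / sum(c) and Shannon entropy H = -sum p_i ln p_i,

    TIN = 100 * exp(H) / k

exp(H) is the effective number of uniformly covered positions, so a
perfectly uniform transcript scores 100 and coverage concentrated on a
single position scores 100/k. The sample-level median TIN is the usual
RNA-integrity summary.

Reads flagged unmapped, secondary, supplementary, duplicate or QC-fail
are excluded; so are aligned bases with Phred quality below 13, and a
position covered twice by one read (e.g. a chimeric overlap) counts
once.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pysam

from .errors import LongReadQCError, ParseError

_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)

#: Minimum per-base Phred quality for a base to support coverage.
MIN_BASE_QUALITY = 13

#: SAM flag bits excluding a read from TIN coverage.
_EXCLUDE_FLAGS = 0x4 | 0x100 | 0x800 | 0x400 | 0x200


@dataclass
class TranscriptModel:
    """A transcript as exon blocks on the reference (BED12 semantics)."""

    name: str
    chrom: str
    strand: str
    exon_blocks: list[tuple[int, int]]  # 0-based half-open, sorted

    @property
    def mrna_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def start(self) -> int:
        return self.exon_blocks[0][0]

    @property
    def end(self) -> int:
        return self.exon_blocks[-1][1]


@dataclass
class TINResult:
    transcript: str
    chrom: str
    tin: float
    mean_coverage: float
    n_positions_sampled: int
    n_reads: int


def parse_bed12(line: str, lineno: int | None = None) -> TranscriptModel:
    """Parse one BED12 line into a TranscriptModel.

    blockStarts are relative to chromStart; blockCount must match both
    list lengths and blocks must lie inside [chromStart, chromEnd).
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise ParseError(f"BED12 requires 12 fields, got {len(fields)}",
                         line=lineno)
    chrom, chrom_start, chrom_end, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    try:
        start = int(chrom_start)
        end = int(chrom_end)
        block_count = int(fields[9])
        sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
        starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    except ValueError as exc:
        raise ParseError(f"non-numeric BED12 field: {exc}", line=lineno)
    if len(sizes) != block_count or len(starts) != block_count:
        raise ParseError(
            f"blockCount {block_count} disagrees with {len(sizes)} sizes / "
            f"{len(starts)} starts", line=lineno)
    blocks = []
    for size, rel in zip(sizes, starts):
        lo = start + rel
        hi = lo + size
        if size < 1 or lo < start or hi > end:
            raise ParseError(
                f"block ({lo},{hi}) outside transcript span ({start},{end})",
                line=lineno)
        blocks.append((lo, hi))
    if blocks != sorted(blocks):
        raise ParseError("BED12 blocks not sorted", line=lineno)
    for (s0, e0), (s1, e1) in zip(blocks, blocks[1:]):
        if s1 < e0:
            raise ParseError("BED12 blocks overlap", line=lineno)
    return TranscriptModel(name=name, chrom=chrom, strand=strand,
                           exon_blocks=blocks)


def read_bed12(path) -> list[TranscriptModel]:
    models = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            models.append(parse_bed12(line, lineno))
    return models


def sample_positions(model: TranscriptModel, sample_size: int) -> list[int]:
    """Reference coordinates of uniformly spaced mRNA positions.

    If the mRNA has no more positions than ``sample_size``, every mRNA
    position is used; otherwise ``sample_size`` equally spaced indices
    including both ends, index_i = round(i * (L-1) / (k-1)), mapped
    through the exon blocks.
    """
    L = model.mrna_length
    if L <= sample_size:
        mrna_idx = range(L)
    else:
        k = sample_size
        mrna_idx = sorted({round(i * (L - 1) / (k - 1)) for i in range(k)})
    # walk blocks to convert mRNA index -> reference coordinate
    out = []
    block_iter = iter(model.exon_blocks)
    lo, hi = next(block_iter)
    offset = 0  # mRNA index of current block start
    for idx in mrna_idx:
        while idx >= offset + (hi - lo):
            offset += hi - lo
            lo, hi = next(block_iter)
        out.append(lo + (idx - offset))
    return out


def transcript_coverage(bam: pysam.AlignmentFile, model: TranscriptModel,
                        min_base_qual: int = MIN_BASE_QUALITY,
                        ) -> tuple[dict[int, int], int]:
    """Per-reference-position read-support counts over a transcript.

    Returns (coverage mapping ref_pos -> count, number of retained
    reads). Requires an indexed BAM for the region fetch.
    """
    coverage: dict[int, int] = {}
    n_reads = 0
    try:
        fetch = bam.fetch(model.chrom, model.start, model.end)
    except ValueError as exc:
        raise LongReadQCError(
            f"region fetch failed for {model.chrom}:{model.start}-{model.end}"
            f" ({exc}); is the BAM coordinate-sorted and indexed "
            "(samtools index)?")
    for rec in fetch:
        if rec.flag & _EXCLUDE_FLAGS:
            continue
        n_reads += 1
        quals = rec.query_qualities
        seen: set[int] = set()
        q = 0
        r = rec.reference_start
        for op, ln in rec.cigartuples or []:
            if op in (_M, _EQ, _X):
                for k in range(ln):
                    pos = r + k
                    if pos in seen:
                        continue
                    if quals is not None and quals[q + k] < min_base_qual:
                        continue
                    seen.add(pos)
                q += ln
                r += ln
            elif op in (_I, _S):
                q += ln
            elif op in (_D, _N):
                r += ln
        for pos in seen:
            coverage[pos] = coverage.get(pos, 0) + 1
    return coverage, n_reads


def compute_tin(coverage_at_samples) -> float:
    """Entropy-based uniformity score over sampled coverages (0-100)."""
    c = np.asarray(list(coverage_at_samples), dtype=np.float64)
    if c.size == 0:
        raise LongReadQCError("TIN of zero sampled positions is undefined")
    if np.any(c < 0):
        raise LongReadQCError("negative coverage counts")
    total = c.sum()
    if total == 0:
        return 0.0
    p = c[c > 0] / total
    entropy = float(-(p * np.log(p)).sum())
    return 100.0 * math.exp(entropy) / c.size


def summarize_tin(bam_path, bed12_path, sample_size: int = 100,
                  min_coverage: int = 10,
                  min_base_qual: int = MIN_BASE_QUALITY,
                  ) -> tuple[list[TINResult], dict[str, float | None]]:
    """Per-transcript TIN rows plus sample-level aggregates.

    Transcripts with fewer than ``min_coverage`` retained reads
    overlapping their span are excluded from scoring and from the
    aggregates. With zero scored transcripts the aggregates are None
    (missing), not zero.
    """
    models = read_bed12(bed12_path)
    results: list[TINResult] = []
    with pysam.AlignmentFile(str(bam_path)) as bam:
        valid = set(bam.references)
        for model in models:
            if model.chrom not in valid:
                continue
            coverage, n_reads = transcript_coverage(bam, model, min_base_qual)
            if n_reads < min_coverage:
                continue
            positions = sample_positions(model, sample_size)
            cov = [coverage.get(p, 0) for p in positions]
            results.append(TINResult(
                transcript=model.name, chrom=model.chrom,
                tin=compute_tin(cov),
                mean_coverage=float(np.mean(cov)),
                n_positions_sampled=len(positions),
                n_reads=n_reads))
    if results:
        tins = np.asarray([r.tin for r in results])
        aggregates = {
            "mean": float(tins.mean()),
            "median": float(np.median(tins)),
            "stdev": float(tins.std(ddof=1)) if tins.size > 1 else 0.0,
        }
    else:
        aggregates = {"mean": None, "median": None, "stdev": None}
    return results, aggregates


def write_tin_tsv(results: list[TINResult], path) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("transcript\tchrom\ttin\tmean_coverage\t"
                 "n_positions_sampled\tn_reads\n")
        for r in results:
            fh.write(f"{r.transcript}\t{r.chrom}\t{r.tin:.4f}\t"
                     f"{r.mean_coverage:.4f}\t{r.n_positions_sampled}\t"
                     f"{r.n_reads}\n")
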