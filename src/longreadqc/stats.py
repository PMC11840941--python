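"""Basic read/base statistics shared by every filetype report.

The statistics here are the classic long-read QC quantities: read and
base totals, length distribution summaries including N50, per-base
composition and GC content, and the Phred-domain per-read quality
conversion (per-base scores are converted to accuracies, averaged over
the read, and converted back to a Phred scale — averaging raw Phred
values would over-weight low-error bases).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigError, UndefinedStatisticError
from .readers import SeqRecord, SummaryRow

BASES = ("A", "C", "G", "T", "U", "N")

#: Ceiling for per-read quality when mean accuracy rounds to 1 (a Phred
#: score of 90 is an error rate of 1e-9, far beyond any basecaller).
DEFAULT_QUALITY_CEILING = 90.0

#: Per-base Phred scores above this are clipped into the last histogram bin.
MAX_PHRED = 93


@dataclass
class BasicStats:
    """Counts, length statistics, N50 and base composition for a read set."""

    n_reads: int = 0
    n_bases: int = 0
    max_len: int = 0
    mean_len: float = 0.0
    median_len: float = 0.0
    n50: int = 0
    base_counts: dict[str, int] = field(
        default_factory=lambda: {b: 0 for b in BASES})
    gc_percent: float = 0.0


@dataclass
class Histogram:
    """Binned counts with ascending edges; edges live in transformed space."""

    edges: list[float]
    counts: list[int]
    log_scale_hint: bool = False


def compute_n50(lengths: Sequence[int]) -> int:
    """N50: the largest length L such that reads >= L hold half the bases.

    Computed by sorting descending and returning the first length at
    which the running total reaches half the grand total (ties resolved
    with >=, the dominant community convention).
    """
    if len(lengths) == 0:
        raise UndefinedStatisticError("N50 of an empty length list")
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    half = arr.sum() / 2.0
    cum = np.cumsum(arr)
    return int(arr[int(np.searchsorted(cum, half))])


def read_mean_quality(quals: Sequence[int],
                      ceiling: float = DEFAULT_QUALITY_CEILING) -> float:
    """Phred-scaled per-read quality via mean per-base accuracy.

    Returns -10*log10(1 - mean_i(1 - 10^(-q_i/10))), clamped to
    ``ceiling`` when the mean accuracy reaches 1 within float precision.
    A constant-quality read is a fixed point of this transform.
    """
    if len(quals) == 0:
        raise UndefinedStatisticError("mean quality of an empty read")
    q = np.asarray(quals, dtype=np.float64)
    mean_err = float(np.mean(np.power(10.0, -q / 10.0)))
    if mean_err <= 0.0:
        return ceiling
    return min(-10.0 * math.log10(mean_err), ceiling)


def gc_content(bases: str) -> float | None:
    """Percent G+C over informative bases (A,C,G,T,U); N carries no
    composition information and is excluded from the denominator.

    Returns None (missing value) for an all-N sequence.
    """
    if len(bases) == 0:
        raise UndefinedStatisticError("GC content of an empty sequence")
    gc = bases.count("G") + bases.count("C")
    informative = sum(bases.count(b) for b in "ACGTU")
    if informative == 0:
        return None
    return 100.0 * gc / informative


class ReadSetAccumulator:
    """Single-pass accumulator over SeqRecord/SummaryRow streams.

    Collects everything a filetype report needs — basic stats, the
    length multiset, per-read GC and mean quality, and the per-base
    quality spectrum — so large files are traversed exactly once.
    """

    def __init__(self, quality_ceiling: float = DEFAULT_QUALITY_CEILING):
        self.lengths: list[int] = []
        self.base_counts: dict[str, int] = {b: 0 for b in BASES}
        self.per_read_gc: list[float] = []
        self.per_read_quality: list[float] = []
        self.base_quality_counts = np.zeros(MAX_PHRED + 1, dtype=np.int64)
        self._ceiling = quality_ceiling

    def add(self, rec) -> None:
        if isinstance(rec, SummaryRow):
            self.lengths.append(rec.length)
            if rec.mean_qscore is not None:
                self.per_read_quality.append(rec.mean_qscore)
            return
        self.add_sequence(rec.bases, rec.quals)

    def add_sequence(self, bases: str, quals=None) -> None:
        self.lengths.append(len(bases))
        for b in BASES:
            self.base_counts[b] += bases.count(b)
        # anything outside the alphabet counts as N for composition
        other = len(bases) - sum(bases.count(b) for b in BASES)
        if other:
            self.base_counts["N"] += other
        if bases:
            gc = gc_content(bases)
            if gc is not None:
                self.per_read_gc.append(gc)
        if quals:
            clipped = np.clip(np.asarray(quals, dtype=np.int64), 0, MAX_PHRED)
            self.base_quality_counts += np.bincount(
                clipped, minlength=MAX_PHRED + 1)
            self.per_read_quality.append(
                read_mean_quality(quals, self._ceiling))

    def basic_stats(self) -> BasicStats:
        if not self.lengths:
            return BasicStats()
        lengths = np.asarray(self.lengths, dtype=np.int64)
        n_bases = int(lengths.sum())
        counts = dict(self.base_counts)
        informative = sum(counts[b] for b in "ACGTU")
        gc = (100.0 * (counts["G"] + counts["C"]) / informative
              if informative else 0.0)
        return BasicStats(
            n_reads=len(lengths),
            n_bases=n_bases,
            max_len=int(lengths.max()),
            mean_len=n_bases / len(lengths),
            median_len=float(np.median(lengths)),
            n50=compute_n50(lengths),
            base_counts=counts,
            gc_percent=gc,
        )


def compute_basic_stats(records: Iterable) -> BasicStats:
    """Single-pass basic statistics over a record stream (zeroed if empty)."""
    acc = ReadSetAccumulator()
    for rec in records:
        acc.add(rec)
    return acc.basic_stats()


def build_histogram(values: Sequence[float], n_bins: int = 100,
                    transform: str = "linear") -> Histogram:
    """Equal-width histogram in linear or log10-transformed space.

    Bins span [min, max] of the (transformed) data; the final bin is
    right-closed so the maximum is counted. Identical values collapse to
    a single degenerate bin holding every observation.
    """
    if n_bins < 1:
        raise ConfigError(f"n_bins must be >= 1, got {n_bins}")
    if transform not in ("linear", "log10"):
        raise ConfigError(f"unknown transform {transform!r}")
    vals = np.asarray(values, dtype=np.float64)
    if vals.size == 0:
        return Histogram(edges=[0.0], counts=[],
                         log_scale_hint=transform == "log10")
    if transform == "log10":
        if np.any(vals <= 0):
            raise ConfigError("log10 histogram requires positive values")
        vals = np.log10(vals)
    lo, hi = float(vals.min()), float(vals.max())
    if lo == hi:
        return Histogram(edges=[lo, hi], counts=[int(vals.size)],
                         log_scale_hint=transform == "log10")
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(vals, bins=edges)
    return Histogram(edges=edges.tolist(), counts=counts.astype(int).tolist(),
                     log_scale_hint=transform == "log10")


def gc_histogram(per_read_gc: Sequence[float]) -> Histogram:
    """Fixed 101-bin GC histogram at integer percent, rounding half-up."""
    counts = [0] * 101
    for gc in per_read_gc:
        counts[min(100, int(math.floor(gc + 0.5)))] += 1
    edges = [i - 0.5 for i in range(102)]
    return Histogram(edges=edges, counts=counts)


def per_read_gc_histogram(records: Iterable) -> Histogram:
    """GC histogram across reads; all-N reads contribute nothing."""
    gcs = []
    for rec in records:
        if getattr(rec, "bases", None):
            gc = gc_content(rec.bases)
            if gc is not None:
                gcs.append(gc)
    return gc_histogram(gcs)
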