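# longreadqc

Quality control for long-read sequencing data. One package ingests the
major long-read formats — FASTA/FASTQ (optionally gzipped), ONT
basecall summary text, aligned and unaligned SAM/BAM (PacBio uBAM
included), FAST5 raw-signal containers, and POD5 (via the optional
`pod5` reader) with a companion basecalled BAM — and produces the
read-, base-, alignment-, modification-, transcript- and signal-level
metrics a sequencing run needs before any downstream analysis, as a
machine-readable summary text file and a self-contained HTML report
with pass/warn QC flags.

## What it computes

**Read/base statistics** (every filetype): read and base totals; max,
mean, median read length and the N50 — the largest length *L* such that
reads of length ≥ *L* hold at least half of all bases; per-base
composition over {A,C,G,T,U,N} and GC% (N excluded from the
denominator); length, base-quality, read-quality and per-read-GC
histograms. Per-read quality is computed in accuracy space:

    Q_read = −10·log10( 1 − mean_i(1 − 10^(−q_i/10)) )

so a constant-quality read maps to itself, and averaging never
over-weights high-quality bases the way a raw mean of Phred scores
would.

**Alignment accounting** (BAM): reads classified into disjoint
categories (unmapped ≻ secondary ≻ supplementary ≻ primary, strand for
primaries); bases classified from the CIGAR into aligned/insert/delete/
soft-clip/hard-clip, with mismatches resolved from the most specific
evidence available (`=`/`X` ops, else the MD tag, else NM − ins − del).

**Base modifications** (SAM MM/ML tags): delta-encoded calls expanded
in basecall orientation (reverse-complement aware), probability
`(b+0.5)/256` per ML byte; per modification code the total predictions,
predictions at or above a probability threshold (default 0.8), CpG
calls per reference strand (CpG defined on the reference sequence), and
a read-length-percentile probability profile.

**Transcript integrity (TIN)** (RNA-seq BAM + BED12): coverage is
measured at k positions sampled uniformly along the mRNA (default
k = 100) from reads that are not unmapped/secondary/supplementary/
duplicate/QC-fail, counting aligned bases with Phred ≥ 13 once per
read; with p_i the normalized coverage and H its Shannon entropy,

    TIN = 100 · exp(H) / k

(100 = perfectly uniform, 100/k = all coverage on one position).
Transcripts with fewer than `min_coverage` (default 10) retained reads
are not scored; the sample mean/median/stdev summarize RNA integrity.

**RRMS partitions**: ONT adaptive-sampling decision CSVs split reads
into accepted (`stop_receiving`) and rejected classes; full QC is run
on each partition and unclassified reads are flagged.

**Raw signal** (FAST5/POD5+BAM): picoampere conversion
`pA = (raw + offset)·range/digitisation`, and per-base signal
segmentation from the basecaller move table (stride + move bits, `mv`
tag or embedded Move dataset), yielding the signal-to-base
correspondence series used to inspect e.g. repeat motifs.

## Worked example

All inputs can be produced by the built-in fixture generators, so the
example is fully reproducible:

```python
from longreadqc import fixtures, summarize_bam

m = fixtures.generate_alignments("demo", n_primary=20, seed=11)
s = summarize_bam(m["files"]["bam"])
print(s.read_counts)
print({k: s.base_counts[k] for k in ("matched", "mismatched",
                                     "inserted", "deleted")})
print("mapped N50:", s.mapped_stats.n50)
```

prints

```
{'primary_mapped': 20, 'secondary': 2, 'supplementary': 2, 'unmapped': 3, 'forward_strand': 15, 'reverse_strand': 5}
{'matched': 23848, 'mismatched': 32, 'inserted': 46, 'deleted': 39}
mapped N50: 1460
```

i.e. 20 molecules aligned as primaries (15 forward, 5 reverse) plus 2
secondary and 2 supplementary records and 3 unmapped reads; of the
aligned bases 32 mismatch and 46/39 are inserted/deleted — exactly the
edit counts the generator planted — and half of all mapped bases live
in reads of at least 1460 bp.

The same run from the shell:

```
longreadqc bam demo/alignments.bam --ref demo/reference.fa -o demo_qc
```

writes `demo_qc/alignments_summary.txt` (one `key<TAB>value` metric per
line, floats at 4 decimals) and `demo_qc/alignments_report.html`, a
single self-contained page showing the same numbers plus inline
histograms and per-section pass/warn flags.

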