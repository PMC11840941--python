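# Methods

This note documents the statistics longreadqc computes, the conventions
it fixes where the field leaves choices open, what the synthetic
fixture generators emulate, and the package's known limitations.

## Read and base statistics

All filetype reports share a single-pass accumulator over the record
stream (bounded memory in file size; only the length multiset and
per-read scalars are retained, never the sequences).

**N50.** The largest length L such that reads of length ≥ L contain at
least half of all sequenced bases. The half-total tie is resolved with
`>=` (cumulative sum reaching exactly total/2 qualifies), the dominant
community convention; this matters only for contrived inputs but is
fixed so results are reproducible. Median of an even-count list is the
mean of the two central values.

**GC content.** 100·(G+C)/(A+C+G+T+U). N carries no composition
information and is excluded from the denominator; an all-N sequence has
no GC value and is reported as missing rather than 0. U is a
first-class base (direct-RNA reads) and is never folded into T.
Lower-case input is upper-cased on read; case is not preserved because
composition is all QC needs.

**Per-read quality.** Per-base Phred scores are converted to
accuracies, averaged over the read, and converted back:
Q = −10·log10(1 − mean(1 − 10^(−q/10))). Constant-quality reads are
fixed points of this transform, and the result always lies between the
minimum and maximum per-base score. When the mean accuracy reaches 1
within float precision the result is clamped to a configurable ceiling
(default 90 ≙ error rate 1e−9, far beyond any basecaller); the exact
ceiling is arbitrary and only prevents infinities.

**Histograms.** Equal-width bins in linear or log10-transformed space
spanning [min, max], final bin right-closed so the maximum is counted;
identical values collapse to one degenerate bin. Defaults: 100 bins for
lengths, integer-granularity bins for Phred scores, and a fixed
101-bin (0..100%, round-half-up) histogram for per-read GC.

**Phred encoding** is fixed at +33. +64 dialects are rejected rather
than auto-detected: every modern long-read emitter writes +33, and a
silent misdetection would corrupt every quality statistic. FASTQ is
parsed as strict 4-line records so that quality-length and truncation
errors can name the offending read.

## Alignment accounting

Read categories are made disjoint by precedence unmapped > secondary >
supplementary > primary (the flags can co-occur; bar charts need
disjoint classes). Strand is recorded for primary records only.
Duplicate- and QC-fail-flagged reads are tallied in a diagnostics row
but stay in the alignment statistics (they are excluded only from TIN).

Base accounting walks the CIGAR: M/=/X → aligned, I → inserted, D →
deleted, S/H → clipped; N and P contribute nothing. Mismatches use the
most specific evidence first: explicit =/X operations, else the MD tag,
else NM − inserted − deleted. An NM smaller than the indel bases is a
tag inconsistency; the read's mismatches are then recorded as
unresolvable rather than clamped to zero, and the count of such reads
is reported.

Secondary and supplementary records contribute to read-category counts
but not to length/GC/quality statistics, so each molecule is counted
once (on its primary record). The report surfaces this convention in
its provenance section.

## Base modifications (MM/ML)

MM items delta-encode calls over occurrences of a canonical base in the
read's basecall orientation; for flag-0x10 records decoding therefore
runs over the reverse complement of the stored SEQ, and positions map
back through p ↦ L−1−p. Each ML byte b becomes the midpoint probability
(b+0.5)/256, so all decoded probabilities lie in [1/512, 511/512].
Implicit '.'-mode positions are not synthesized as calls: only
explicitly listed predictions are counted, matching a "total
predictions" semantics. The threshold comparison is inclusive (a call
exactly at the threshold counts as modified).

Calls on aligned reads are anchored through the CIGAR; calls inside
insertions or clips get no reference position and are never CpG. CpG is
decided on the **reference** sequence — a '+' strand call at p needs
ref[p..p+1] = CG, a '−' strand call at p needs ref[p−1..p] = CG —
because per-site methylation pileups are defined against the reference,
not the read. The positional profile averages call probability within
each read-length percentile (0..100), using round(100·pos/(len−1)).

## Transcript integrity number

TIN scores coverage uniformity: with coverage c_i at k sampled mRNA
positions, p_i = c_i/Σc, H = −Σ p_i ln p_i, TIN = 100·exp(H)/k. The
entropy base cancels against its inverse, so any base gives the same
score; natural log is used. Zero total coverage scores 0. TIN is
permutation-invariant in the sampled positions and decreases (weakly)
whenever coverage mass moves from a lower-covered onto a higher-covered
position.

Sampling uses first-and-last-inclusive equal spacing,
index_i = round(i·(L−1)/(k−1)); when the mRNA has at most k positions,
all are used. Coverage counts reads that are not unmapped/secondary/
supplementary/duplicate/QC-fail, walking each read's CIGAR over
aligned (match/mismatch) columns, skipping bases below Phred 13 and
counting a position at most once per read. The `min_coverage` filter
(default 10) counts retained reads overlapping the transcript span —
not mean depth — mirroring a "minimum number of reads mapped to a
transcript" semantics. Defaults `sample_size=100`, `min_coverage=10`
are this package's choices. No background/intronic coverage correction
is applied; implementations that apply one can differ slightly on
noisy data. With zero scored transcripts the sample aggregates are
reported as missing, not zero.

## RRMS partitions

The decision CSV schema is configurable (column names and the accepted
vocabulary) because adaptive-sampling emitters vary; the default
accepts `stop_receiving` and rejects everything else. Duplicate ids
resolve last-wins, counting conflicting duplicates as warnings. Reads
absent from the CSV are excluded from both partition reports and
surfaced as an `unclassified` QC flag, so
accepted + rejected + unclassified always equals the number of distinct
molecules in the QC input.

## Raw signal

FAST5 single- and multi-read layouts are auto-detected from the HDF5
group structure; calibration (offset, range, digitisation) comes from
the channel metadata and pA = (raw + offset)·range/digitisation is the
only normalization applied (no median/MAD standardization — the QC goal
is faithful display, not comparison across channels). Move-table
semantics follow the de facto basecaller convention: the `mv` tag holds
the stride followed by per-step move bits, `ts` the number of samples
trimmed before the basecalled region; base i spans from the sample of
its move-1 to the next move-1, the last base running to the end of the
trace, so segments exactly tile [trim, len(raw)). POD5 container
decoding is delegated to the official `pod5` reader (optional
dependency); the pairing and segmentation logic is container-agnostic
and fully exercised through the FAST5 path.

## Reports and flags

A run computes one in-memory bundle; the summary text (versioned
`key<TAB>value` schema, floats at fixed 4 decimals, period decimal
separator) and the HTML report are both serialized from it with the
same formatter, which is what guarantees that every scalar in an HTML
table appears verbatim in the summary text. The HTML embeds histograms
as inline SVG and references no external resource. Flag thresholds
(median read quality < 10, unmapped fraction > 20%, median GC more than
15 points from 50, median TIN < 50 → warn) are deliberately
configurable defaults of this package's own design; the flagging
mechanism, not any particular cutoff, is the contract. `--threads` only
sizes htslib's decompression pool; results are defined single-threaded
and are byte-identical regardless of the hint.

## Synthetic fixtures

All test inputs are generated programmatically with ground truth
recorded at construction time (never recomputed from the files):

- **Read sets** draw log-normal lengths (median ~8 kb, matching ONT
  WGS libraries; bimodal and uniform regimes available) and per-read
  mean qualities around Phred 18 with per-base jitter, written as
  matched FASTA/FASTQ/seqtxt.
- **Aligned BAMs** plant exact per-read edits (mismatches, insertions,
  deletions on a coarse grid so events never collide) against a random
  reference and write CIGAR/NM/MD consistently with them, plus
  secondary, hard-clipped supplementary, and unmapped records; a subset
  of reads uses explicit =/X CIGARs to exercise that evidence path.
- **Modification BAMs** plant CpG sites with non-colliding flanks and
  per-site high/low probability bytes on both strands, plus non-CpG
  cytosine calls (one above threshold) so the CpG counters are strictly
  below the above-threshold totals; the manifest records the exact
  per-site pileup.
- **RNA-seq BAMs** realize uniform (TIN→100), 3'-biased (TIN≈33) and
  single-spike (TIN=100/k) coverage over a spliced two-exon transcript,
  plus a sparse transcript below any sensible `min_coverage`.
- **Signal files** synthesize per-base current levels (well-separated
  DAC means per base, 1–3 move steps of 5 samples dwell, small integer
  noise, a leading trimmed segment) written to both FAST5 layouts and a
  basecalled BAM with mv/ts tags, with a repeating 3-base motif so
  per-base mean levels are periodic by construction.

What the generators do **not** emulate: basecaller error
autocorrelation and homopolymer-dependent error rates, real pore noise
spectra, reference repeats/mappability, or multi-contig references.
Passing tests therefore demonstrate the correctness of the accounting
and the formulas under controlled conditions, not the tool's behavior
on every pathology of real data. Problem sizes used by the default test
run and the acceptance script (≈100-read sets, 200 planted alignments,
~30 CpG sites × 12 reads, depth-20 transcripts, 500 random move tables,
200 TIN-bias replicates) were chosen as the smallest sizes at which
each property is non-trivially exercised.

## Numerical and degenerate-input choices

Empty inputs yield zeroed statistics (not errors) except where a
statistic is genuinely undefined (N50/mean quality of an empty list),
which raises. All-identical histogram inputs produce one degenerate
bin. TIN of an all-zero coverage vector is 0 by definition. Decoded
modification probabilities are exact rationals of the byte encoding, so
threshold comparisons are reproducible. Summary floats are serialized
at 4 decimals; equality contracts between HTML and summary text compare
the serialized strings, never re-parsed floats.
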