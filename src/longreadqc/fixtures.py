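"""Synthetic fixture generation for every supported input format.

Each generator writes files plus a ground-truth manifest recorded at
construction time (never recomputed from the files), so every statistic
the QC modules emit can be verified against planted truth. Generation
is fully deterministic given the seed.

Default regimes emulate the data types the tool targets: ONT
whole-genome runs (log-normal read lengths, median ~8 kb, per-base
Phred around 15-25), adaptive-sampling runs with long accepted and
short rejected fragments, 5mC MM/ML tags over CpG sites, spliced
RNA-seq coverage, and nanopore traces with per-base dwell times of a
few samples at 4 kHz. What the generators do NOT emulate: basecaller
error-profile autocorrelation, homopolymer-dependent error rates, and
pore-level signal noise structure.
"""

from __future__ import annotations

import csv
import gzip
import json
import math
from pathlib import Path

import h5py
import numpy as np
import pysam

from .errors import ConfigError

BASES = "ACGT"


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


def _random_seq(rng, length: int, gc: float = 0.5) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list(BASES), size=length, p=p))


def _brute_force_n50(lengths) -> int:
    # independent prefix-scan oracle, recorded into the manifest
    total = sum(lengths)
    acc = 0
    for ln in sorted(lengths, reverse=True):
        acc += ln
        if acc >= total / 2:
            return ln
    return 0


def _mean_qscore(quals) -> float:
    # accuracy-domain average, written at generation time
    err = sum(10.0 ** (-q / 10.0) for q in quals) / len(quals)
    return -10.0 * math.log10(err) if err > 0 else 90.0


def _draw_lengths(rng, n: int, spec: dict) -> list[int]:
    kind = spec.get("kind", "lognormal")
    if kind == "lognormal":
        mu = spec.get("mean_log", math.log(8000.0))
        sigma = spec.get("sd_log", 0.7)
        lens = rng.lognormal(mu, sigma, size=n)
    elif kind == "uniform":
        lens = rng.uniform(spec.get("low", 500), spec.get("high", 20000),
                           size=n)
    elif kind == "constant":
        lens = np.full(n, spec.get("value", 1000), dtype=float)
    elif kind == "bimodal":
        short = rng.lognormal(math.log(spec.get("short", 800)), 0.3,
                              size=n // 2)
        long_ = rng.lognormal(math.log(spec.get("long", 15000)), 0.3,
                              size=n - n // 2)
        lens = rng.permutation(np.concatenate([short, long_]))
    else:
        raise ConfigError(f"unknown length distribution {kind!r}")
    lens = np.maximum(1, np.round(lens)).astype(int)
    if np.any(lens < 1):
        raise ConfigError("length distribution produced non-positive lengths")
    return lens.tolist()


def generate_read_set(outdir, n: int = 100, length_dist: dict | None = None,
                      quality_dist: dict | None = None, gc_target: float = 0.5,
                      seed: int = 0, gzipped: bool = False) -> dict:
    """Write matched FASTA + FASTQ + seqtxt files and their manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    length_dist = length_dist or {"kind": "lognormal"}
    quality_dist = quality_dist or {"mean": 18.0, "sd": 4.0}
    lengths = _draw_lengths(rng, n, length_dist)

    reads = []
    for i, ln in enumerate(lengths):
        seq = _random_seq(rng, ln, gc_target)
        read_q = float(np.clip(rng.normal(quality_dist["mean"],
                                          quality_dist["sd"]), 2, 50))
        quals = np.clip(np.round(rng.normal(read_q, 3.0, size=ln)),
                        1, 50).astype(int).tolist()
        gc = 100.0 * (seq.count("G") + seq.count("C")) / ln
        reads.append({
            "read_id": f"read_{i:05d}", "length": ln, "gc": gc,
            "mean_qscore": _mean_qscore(quals), "seq": seq, "quals": quals,
            "passes_filtering": bool(read_q >= 7.0),
        })

    fasta = outdir / ("reads.fasta.gz" if gzipped else "reads.fasta")
    fastq = outdir / ("reads.fastq.gz" if gzipped else "reads.fastq")
    seqtxt = outdir / "sequencing_summary.txt"
    opener = (lambda p: gzip.open(p, "wt")) if gzipped else (
        lambda p: open(p, "wt"))
    with opener(fasta) as fh:
        for r in reads:
            fh.write(f">{r['read_id']}\n{r['seq']}\n")
    with opener(fastq) as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r["quals"])
            fh.write(f"@{r['read_id']}\n{r['seq']}\n+\n{qual}\n")
    with open(seqtxt, "wt") as fh:
        fh.write("read_id\tsequence_length_template\tmean_qscore_template\t"
                 "passes_filtering\tchannel\n")
        for i, r in enumerate(reads):
            fh.write(f"{r['read_id']}\t{r['length']}\t"
                     f"{r['mean_qscore']:.6f}\t"
                     f"{'TRUE' if r['passes_filtering'] else 'FALSE'}\t"
                     f"{i % 512}\n")

    base_counts = {b: 0 for b in "ACGTUN"}
    for r in reads:
        for b in "ACGT":
            base_counts[b] += r["seq"].count(b)
    manifest = {
        "format": "read_set",
        "files": {"fasta": str(fasta), "fastq": str(fastq),
                  "seqtxt": str(seqtxt)},
        "n_reads": n,
        "n_bases": int(sum(lengths)),
        "n50": _brute_force_n50(lengths),
        "max_len": int(max(lengths)) if lengths else 0,
        "base_counts": base_counts,
        "reads": [{k: r[k] for k in ("read_id", "length", "gc", "mean_qscore",
                                     "passes_filtering")} for r in reads],
    }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# aligned BAM with planted edits

def _write_reference(outdir, rng, length: int = 20000,
                     name: str = "chr_syn") -> tuple[Path, str]:
    seq = _random_seq(rng, length)
    path = Path(outdir) / "reference.fa"
    with open(path, "wt") as fh:
        fh.write(f">{name}\n")
        for i in range(0, length, 70):
            fh.write(seq[i:i + 70] + "\n")
    pysam.faidx(str(path))
    return path, seq


def _plant_read(ref_seq: str, start: int, aln_len: int, n_mismatch: int,
                ins_events: list[tuple[int, int]],
                del_events: list[tuple[int, int]], rng,
                soft_clip: tuple[int, int] = (0, 0),
                explicit_ops: bool = False) -> dict:
    """Construct one aligned read with exactly the requested edits.

    ``ins_events``/``del_events`` are (reference-offset, length) pairs;
    deletions must not overlap each other or mismatch positions.
    Returns seq/cigar/NM/MD plus the planted edit counts.
    """
    region = ref_seq[start:start + aln_len]
    deleted = set()
    for off, ln in del_events:
        deleted.update(range(off, off + ln))
    candidates = [i for i in range(aln_len) if i not in deleted]
    mism = set(rng.choice(candidates, size=n_mismatch, replace=False)
               .tolist()) if n_mismatch else set()
    ins_at = dict(ins_events)  # offset -> length, inserted before offset

    cols = []  # (op, read_base or None, ref_base or None)
    for off in range(aln_len):
        if off in ins_at:
            for _ in range(ins_at[off]):
                cols.append(("I", rng.choice(list(BASES)), None))
        rb = region[off]
        if off in deleted:
            cols.append(("D", None, rb))
        elif off in mism:
            alt = rng.choice([b for b in BASES if b != rb])
            cols.append(("X", alt, rb))
        else:
            cols.append(("M", rb, rb))
    if aln_len in ins_at:
        for _ in range(ins_at[aln_len]):
            cols.append(("I", rng.choice(list(BASES)), None))

    seq = "".join(c[1] for c in cols if c[1] is not None)
    left, right = soft_clip
    seq = _random_seq(rng, left) + seq + _random_seq(rng, right)

    # CIGAR: collapse columns; M/X merge unless explicit =/X ops requested
    cigar = []

    def push(op, ln=1):
        if cigar and cigar[-1][0] == op:
            cigar[-1][1] += ln
        else:
            cigar.append([op, ln])

    if left:
        push(4, left)
    for op, _, _ in cols:
        if op == "I":
            push(1)
        elif op == "D":
            push(2)
        elif explicit_ops:
            push(8 if op == "X" else 7)
        else:
            push(0)
    if right:
        push(4, right)

    # MD: matches run / mismatch letter / ^deletion run (insertions skipped)
    md = ""
    run = 0
    in_del = False
    for op, _, rb in cols:
        if op == "I":
            continue
        if op == "D":
            if not in_del:
                md += str(run) + "^"
                run = 0
                in_del = True
            md += rb
            continue
        if in_del:
            in_del = False
        if op == "M":
            run += 1
        else:  # X
            md += str(run) + rb
            run = 0
    md += str(run)
    ins_bases = sum(ln for _, ln in ins_events)
    del_bases = sum(ln for _, ln in del_events)
    return {
        "seq": seq,
        "cigar": [tuple(c) for c in cigar],
        "nm": n_mismatch + ins_bases + del_bases,
        "md": md,
        "n_mismatch": n_mismatch,
        "ins_bases": ins_bases,
        "del_bases": del_bases,
        "aligned_len": aln_len - del_bases,
        "soft_clip": left + right,
    }


def generate_alignments(outdir, n_primary: int = 20, error_spec=None,
                        extras=None, seed: int = 0, ref_length: int = 20000,
                        length_range=(300, 2000), with_md: bool = True,
                        rrms_plan: bool = False) -> dict:
    """Write a sorted+indexed BAM with planted edits and exact manifest.

    ``error_spec`` is (n_mismatch, n_insertions, n_deletions) maxima per
    read; ``extras`` is (n_secondary, n_supplementary, n_unmapped).
    With ``rrms_plan`` the read set is split into long accepted and
    short rejected molecules and a decision CSV is written alongside.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    error_spec = error_spec or (3, 2, 2)
    extras = extras or (2, 2, 3)
    ref_path, ref_seq = _write_reference(outdir, rng, ref_length)

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr_syn", "LN": ref_length}]}
    reads = []
    rrms_rows = []
    for i in range(n_primary):
        rid = f"aln_{i:04d}"
        if rrms_plan:
            accepted = i % 2 == 0
            lo, hi = (2000, 6000) if accepted else (200, 600)
            rrms_rows.append((rid, "stop_receiving" if accepted else "unblock"))
        else:
            lo, hi = length_range
        aln_len = int(rng.integers(lo, hi))
        start = int(rng.integers(0, ref_length - aln_len - 50))
        n_mm = int(rng.integers(0, error_spec[0] + 1))
        n_ins = int(rng.integers(0, error_spec[1] + 1))
        n_del = int(rng.integers(0, error_spec[2] + 1))
        # place non-overlapping indel events on a coarse grid
        slots = rng.permutation(np.arange(1, aln_len // 10 - 1)) * 10
        ins_events = [(int(slots[j]), int(rng.integers(1, 4)))
                      for j in range(n_ins)]
        del_events = [(int(slots[n_ins + j]), int(rng.integers(1, 4)))
                      for j in range(n_del)]
        soft = (int(rng.integers(0, 20)), int(rng.integers(0, 20))) \
            if rng.random() < 0.4 else (0, 0)
        planted = _plant_read(ref_seq, start, aln_len, n_mm, ins_events,
                              del_events, rng, soft,
                              explicit_ops=(i % 7 == 0))
        reverse = bool(rng.random() < 0.5)
        planted.update({"read_id": rid, "start": start, "flag":
                        16 if reverse else 0, "category": "primary_mapped",
                        "strand": "reverse" if reverse else "forward"})
        reads.append(planted)

    n_sec, n_sup, n_unmapped = extras
    records = []
    for r in reads:
        rec = pysam.AlignedSegment()
        rec.query_name = r["read_id"]
        rec.query_sequence = r["seq"]
        rec.flag = r["flag"]
        rec.reference_id = 0
        rec.reference_start = r["start"]
        rec.mapping_quality = 60
        rec.cigartuples = r["cigar"]
        rec.query_qualities = np.clip(
            np.round(rng.normal(20, 3, len(r["seq"]))), 2, 40).astype(
                int).tolist()
        rec.set_tag("NM", r["nm"])
        if with_md and not any(op in (7, 8) for op, _ in r["cigar"]):
            rec.set_tag("MD", r["md"])
        records.append(rec)

    # secondary: duplicate alignments of existing molecules, no seq
    for j in range(n_sec):
        src = reads[j % len(reads)]
        rec = pysam.AlignedSegment()
        rec.query_name = src["read_id"]
        rec.flag = src["flag"] | 0x100
        rec.reference_id = 0
        rec.reference_start = (src["start"] + 977) % (ref_length - 3000)
        rec.mapping_quality = 0
        aligned = src["aligned_len"]
        rec.cigartuples = [(0, aligned + src["soft_clip"])]
        records.append(rec)
    # supplementary: hard-clipped tail alignments
    for j in range(n_sup):
        src = reads[(j + 1) % len(reads)]
        rec = pysam.AlignedSegment()
        rec.query_name = src["read_id"]
        rec.flag = src["flag"] | 0x800
        rec.reference_id = 0
        rec.reference_start = (src["start"] + 1499) % (ref_length - 3000)
        rec.mapping_quality = 30
        piece = max(50, len(src["seq"]) // 4)
        rec.query_sequence = src["seq"][:piece]
        rec.cigartuples = [(0, piece), (5, len(src["seq"]) - piece)]
        rec.set_tag("NM", 0)
        records.append(rec)
    unmapped_reads = []
    for j in range(n_unmapped):
        rid = f"unm_{j:04d}"
        ln = int(rng.integers(200, 900))
        seq = _random_seq(rng, ln)
        quals = np.clip(np.round(rng.normal(12, 3, ln)), 2, 40).astype(int)
        rec = pysam.AlignedSegment()
        rec.query_name = rid
        rec.flag = 4
        rec.query_sequence = seq
        rec.query_qualities = quals.tolist()
        records.append(rec)
        unmapped_reads.append({"read_id": rid, "length": ln,
                               "mean_qscore": _mean_qscore(quals.tolist())})
        if rrms_plan:
            rrms_rows.append((rid, "unblock"))

    unsorted = outdir / "unsorted.bam"
    bam_path = outdir / "alignments.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in records:
            bam.write(rec)
    pysam.sort("-o", str(bam_path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam_path))

    csv_path = None
    if rrms_plan:
        csv_path = outdir / "rrms_decisions.csv"
        write_rrms_csv(rrms_rows, csv_path)

    manifest = {
        "format": "aligned_bam",
        "files": {"bam": str(bam_path), "reference": str(ref_path),
                  **({"rrms_csv": str(csv_path)} if csv_path else {})},
        "read_counts": {
            "primary_mapped": n_primary, "secondary": n_sec,
            "supplementary": n_sup, "unmapped": n_unmapped,
            "forward_strand": sum(1 for r in reads
                                  if r["strand"] == "forward"),
            "reverse_strand": sum(1 for r in reads
                                  if r["strand"] == "reverse"),
        },
        "base_counts": {
            "mismatched": sum(r["n_mismatch"] for r in reads),
            "inserted": sum(r["ins_bases"] for r in reads),
            "deleted": sum(r["del_bases"] for r in reads),
        },
        "reads": [{k: r[k] for k in ("read_id", "start", "n_mismatch",
                                     "ins_bases", "del_bases", "nm",
                                     "category", "strand")} for r in reads],
        "unmapped_reads": unmapped_reads,
        "rrms": {"accepted": [rid for rid, d in rrms_rows
                              if d == "stop_receiving"],
                 "rejected": [rid for rid, d in rrms_rows
                              if d != "stop_receiving"]} if rrms_plan else None,
    }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def write_rrms_csv(rows, path, extra_conflicts=0) -> None:
    """Write an adaptive-sampling decision CSV (read_id, decision)."""
    with open(path, "wt", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["read_id", "decision", "channel"])
        for i, (rid, decision) in enumerate(rows):
            writer.writerow([rid, decision, i % 512])


# ---------------------------------------------------------------------------
# BAM with MM/ML modification tags

def generate_modified_bam(outdir, n_reads: int = 12, n_cpg_sites: int = 30,
                          seed: int = 0, ref_length: int = 6000,
                          high_prob_byte: int = 230,
                          low_prob_byte: int = 51) -> dict:
    """BAM with planted 5mC MM/ML calls over reference CpG sites.

    Reads align perfectly (pure M CIGARs) on both strands. Each read
    calls every CpG cytosine it covers on its own strand, high- or
    low-probability per a fixed per-site plan, plus occasional non-CpG
    cytosine calls. The manifest records the exact per-site pileup of
    above-threshold (>= 0.8) calls per strand.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    seq = list(_random_seq(rng, ref_length))
    # plant CpG sites on a coarse grid so contexts never collide
    site_pos = sorted(rng.choice(np.arange(10, ref_length // 20 - 2) * 20,
                                 size=n_cpg_sites, replace=False).tolist())
    for p in site_pos:
        seq[p], seq[p + 1] = "C", "G"
        # keep flanks non-C/G so no accidental CpG overlaps the site
        if seq[p - 1] == "C":
            seq[p - 1] = "A"
        if seq[p + 2] == "G":
            seq[p + 2] = "T"
    ref_seq = "".join(seq)
    ref_path = Path(outdir) / "reference.fa"
    with open(ref_path, "wt") as fh:
        fh.write(">chr_syn\n")
        for i in range(0, ref_length, 70):
            fh.write(ref_seq[i:i + 70] + "\n")
    pysam.faidx(str(ref_path))

    site_high = {p: bool(rng.random() < 0.7) for p in site_pos}

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr_syn", "LN": ref_length}]}
    pileup_fwd: dict[int, int] = {}
    pileup_rev: dict[int, int] = {}
    total_calls = 0
    above = 0
    records = []
    for i in range(n_reads):
        rid = f"mod_{i:04d}"
        aln_len = int(rng.integers(1500, 3500))
        start = int(rng.integers(0, ref_length - aln_len))
        reverse = i % 2 == 1
        stored = ref_seq[start:start + aln_len]  # pure-M perfect alignment
        basecall = (stored.translate(str.maketrans("ACGT", "TGCA"))[::-1]
                    if reverse else stored)
        # modified cytosines in basecall orientation
        covered = [p for p in site_pos if start <= p and p + 1 < start + aln_len]
        call_plan = []  # (basecall_pos, byte, ref_pos or None, strand)
        for p in covered:
            byte = high_prob_byte if site_high[p] else low_prob_byte
            if not reverse:
                call_plan.append((p - start, byte, p, "+"))
            else:
                # the C in basecall orientation pairs with the ref G at p+1
                bpos = aln_len - 1 - (p + 1 - start)
                call_plan.append((bpos, byte, p + 1, "-"))
        # some non-CpG cytosine calls, one of them above threshold, so the
        # CpG counters stay strictly below the above-threshold totals
        c_positions = [j for j, b in enumerate(basecall) if b == "C"]
        planned = {bp for bp, _, _, _ in call_plan}

        def ref_context_is_cpg(bpos: int) -> bool:
            if not reverse:
                rp = start + bpos
                return ref_seq[rp:rp + 2] == "CG"
            rp = start + (aln_len - 1 - bpos)
            return rp >= 1 and ref_seq[rp - 1:rp + 1] == "CG"

        extra = [j for j in c_positions
                 if j not in planned and not ref_context_is_cpg(j)][:3]
        for k, j in enumerate(extra):
            byte = high_prob_byte if k == 0 else low_prob_byte
            call_plan.append((j, byte, None, "+" if not reverse else "-"))
        call_plan.sort()
        # MM delta encoding over C occurrences in basecall orientation
        deltas = []
        prev_occ = -1
        occ_index = {pos: k for k, pos in enumerate(c_positions)}
        for bp, _, _, _ in call_plan:
            k = occ_index[bp]
            deltas.append(k - prev_occ - 1)
            prev_occ = k
        mm = "C+m," + ",".join(str(d) for d in deltas) + ";" if deltas else ""
        ml = [byte for _, byte, _, _ in call_plan]

        for bp, byte, ref_pos, strand in call_plan:
            total_calls += 1
            prob = (byte + 0.5) / 256.0
            if prob >= 0.8:
                above += 1
                if ref_pos is not None:
                    target = pileup_fwd if strand == "+" else pileup_rev
                    target[ref_pos] = target.get(ref_pos, 0) + 1

        rec = pysam.AlignedSegment()
        rec.query_name = rid
        rec.flag = 16 if reverse else 0
        rec.reference_id = 0
        rec.reference_start = start
        rec.mapping_quality = 60
        rec.query_sequence = stored
        rec.cigartuples = [(0, aln_len)]
        rec.query_qualities = [30] * aln_len
        rec.set_tag("NM", 0)
        if mm:
            rec.set_tag("MM", mm)
            rec.set_tag("ML", ml)
        records.append(rec)

    unsorted = outdir / "unsorted.bam"
    bam_path = outdir / "modified.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in sorted(records, key=lambda r: r.reference_start):
            bam.write(rec)
    pysam.sort("-o", str(bam_path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam_path))

    manifest = {
        "format": "modified_bam",
        "files": {"bam": str(bam_path), "reference": str(ref_path)},
        "threshold": 0.8,
        "total_predictions": total_calls,
        "above_threshold": above,
        "cpg_above_threshold_fwd": sum(pileup_fwd.values()),
        "cpg_above_threshold_rev": sum(pileup_rev.values()),
        "pileup_fwd": {str(k): v for k, v in sorted(pileup_fwd.items())},
        "pileup_rev": {str(k): v for k, v in sorted(pileup_rev.items())},
        "cpg_sites": site_pos,
    }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# RNA-seq BAM + BED12 for TIN

def generate_transcript_bam(outdir, coverage_profile: str = "uniform",
                            depth: int = 20, seed: int = 0) -> dict:
    """Spliced transcript models plus reads realizing a coverage regime.

    Profiles: ``uniform`` (full-length reads, TIN ~ 100),
    ``three_prime_biased`` (reads confined to the 3' third, TIN ~ 33),
    ``spiked`` (all coverage at a single position, TIN = 100/k), and a
    ``sparse`` transcript below any reasonable min_coverage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    ref_length = 12000
    ref_path, ref_seq = _write_reference(outdir, rng, ref_length)

    # two-exon spliced model plus a single-exon control
    models = {
        "tx_main": {"chrom": "chr_syn", "start": 1000,
                    "blocks": [(1000, 1800), (2400, 3600)], "strand": "+"},
        "tx_sparse": {"chrom": "chr_syn", "start": 8000,
                      "blocks": [(8000, 9000)], "strand": "+"},
    }
    bed_path = outdir / "transcripts.bed"
    with open(bed_path, "wt") as fh:
        for name, m in models.items():
            start = m["blocks"][0][0]
            end = m["blocks"][-1][1]
            sizes = ",".join(str(e - s) for s, e in m["blocks"])
            starts = ",".join(str(s - start) for s, e in m["blocks"])
            fh.write(f"{m['chrom']}\t{start}\t{end}\t{name}\t0\t"
                     f"{m['strand']}\t{start}\t{end}\t0\t"
                     f"{len(m['blocks'])}\t{sizes}\t{starts}\n")

    header = {"HD": {"VN": "1.6", "SO": "coordinate"},
              "SQ": [{"SN": "chr_syn", "LN": ref_length}]}
    records = []

    def spliced_read(rid, blocks):
        rec = pysam.AlignedSegment()
        rec.query_name = rid
        rec.flag = 0
        rec.reference_id = 0
        rec.reference_start = blocks[0][0]
        rec.mapping_quality = 60
        seq = "".join(ref_seq[s:e] for s, e in blocks)
        rec.query_sequence = seq
        rec.query_qualities = [40] * len(seq)
        cig = []
        for j, (s, e) in enumerate(blocks):
            cig.append((0, e - s))
            if j + 1 < len(blocks):
                cig.append((3, blocks[j + 1][0] - e))
        rec.cigartuples = cig
        rec.set_tag("NM", 0)
        return rec

    main = models["tx_main"]["blocks"]
    if coverage_profile == "uniform":
        for i in range(depth):
            records.append(spliced_read(f"rna_{i:04d}", main))
        expected = "tin_100"
    elif coverage_profile == "three_prime_biased":
        # 3' third of the mRNA: last 667 of 2000 mRNA bases -> second exon tail
        for i in range(depth):
            records.append(spliced_read(f"rna_{i:04d}", [(2933, 3600)]))
        expected = "tin_one_third"
    elif coverage_profile == "spiked":
        for i in range(depth):
            records.append(spliced_read(f"rna_{i:04d}", [(1000, 1001)]))
        expected = "tin_100_over_k"
    else:
        raise ConfigError(f"unknown coverage profile {coverage_profile!r}")
    # sparse transcript: 3 reads, below any min_coverage of 10
    for i in range(3):
        records.append(spliced_read(f"sparse_{i:02d}", [(8000, 9000)]))

    unsorted = outdir / "unsorted.bam"
    bam_path = outdir / "rnaseq.bam"
    with pysam.AlignmentFile(unsorted, "wb", header=header) as bam:
        for rec in sorted(records, key=lambda r: r.reference_start):
            bam.write(rec)
    pysam.sort("-o", str(bam_path), str(unsorted))
    unsorted.unlink()
    pysam.index(str(bam_path))

    manifest = {
        "format": "transcript_bam",
        "files": {"bam": str(bam_path), "bed12": str(bed_path),
                  "reference": str(ref_path)},
        "profile": coverage_profile, "depth": depth,
        "expected_regime": expected,
        "mrna_length": sum(e - s for s, e in main),
        "sparse_reads": 3,
    }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


# ---------------------------------------------------------------------------
# FAST5 + basecalled BAM with move tables (+ RRMS CSV)

#: Mean DAC level per base; chosen well-separated so per-base means in a
#: periodic motif are visibly periodic.
BASE_LEVELS = {"A": 500, "C": 650, "G": 800, "T": 950}


def generate_signal_files(outdir, n_reads: int = 3, seq_len: int = 60,
                          stride: int = 5, seed: int = 0,
                          motif: str | None = "CAG") -> dict:
    """Multi-read FAST5 + single-read FAST5 + basecalled uBAM + RRMS CSV.

    Sequences repeat ``motif`` (None for random); each base dwells 1-3
    move steps of ``stride`` samples at a base-specific DAC level with
    small integer noise. The move table, trim, and per-base sample
    counts are recorded in the manifest.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = _rng(seed)
    reads = []
    for i in range(n_reads):
        rid = f"sig_{i:04d}"
        if motif:
            seq = (motif * (seq_len // len(motif) + 1))[:seq_len]
        else:
            seq = _random_seq(rng, seq_len)
        trim = int(rng.integers(5, 25))
        moves = []
        samples = []
        per_base_samples = []
        for b in seq:
            dwell_steps = int(rng.integers(1, 4))
            moves.extend([1] + [0] * (dwell_steps - 1))
            n_samp = dwell_steps * stride
            level = BASE_LEVELS[b if b in BASE_LEVELS else "A"]
            samples.extend((level + rng.integers(-5, 6, n_samp)).tolist())
            per_base_samples.append(n_samp)
        raw = rng.integers(400, 420, trim).tolist() + samples
        reads.append({"read_id": rid, "seq": seq, "trim": trim,
                      "moves": moves, "raw": raw,
                      "per_base_samples": per_base_samples})

    channel = {"digitisation": 8192.0, "offset": 12.0, "range": 1402.882,
               "sampling_rate": 4000.0}

    multi = outdir / "reads.fast5"
    with h5py.File(multi, "w") as f5:
        for r in reads:
            grp = f5.create_group(f"read_{r['read_id']}")
            raw = grp.create_group("Raw")
            raw.attrs["read_id"] = r["read_id"]
            raw.create_dataset("Signal", data=np.asarray(r["raw"],
                                                         dtype=np.int16))
            ch = grp.create_group("channel_id")
            for k, v in channel.items():
                ch.attrs[k] = v
            tmpl = grp.create_group("Analyses/Basecall_1D_000/"
                                    "BaseCalled_template")
            qual = "I" * len(r["seq"])
            tmpl.create_dataset(
                "Fastq", data=f"@{r['read_id']}\n{r['seq']}\n+\n{qual}\n")
            tmpl.create_dataset("Move", data=np.asarray(r["moves"],
                                                        dtype=np.uint8))
            tmpl.attrs["block_stride"] = stride
            tmpl.attrs["first_sample_template"] = r["trim"]

    # single-read re-encoding of the first read (legacy layout)
    single = outdir / "read0_single.fast5"
    r0 = reads[0]
    with h5py.File(single, "w") as f5:
        grp = f5.create_group("Raw/Reads/Read_0")
        grp.attrs["read_id"] = r0["read_id"]
        grp.create_dataset("Signal", data=np.asarray(r0["raw"],
                                                     dtype=np.int16))
        ch = f5.create_group("UniqueGlobalKey/channel_id")
        for k, v in channel.items():
            ch.attrs[k] = v
        tmpl = f5.create_group("Analyses/Basecall_1D_000/BaseCalled_template")
        qual = "I" * len(r0["seq"])
        tmpl.create_dataset(
            "Fastq", data=f"@{r0['read_id']}\n{r0['seq']}\n+\n{qual}\n")
        tmpl.create_dataset("Move", data=np.asarray(r0["moves"],
                                                    dtype=np.uint8))
        tmpl.attrs["block_stride"] = stride
        tmpl.attrs["first_sample_template"] = r0["trim"]

    # basecalled uBAM with mv/ts tags, plus one BAM-only orphan read
    bam_path = outdir / "basecalls.bam"
    header = {"HD": {"VN": "1.6"}}
    with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
        for r in reads:
            rec = pysam.AlignedSegment()
            rec.query_name = r["read_id"]
            rec.flag = 4
            rec.query_sequence = r["seq"]
            rec.query_qualities = [20] * len(r["seq"])
            rec.set_tag("mv", [stride] + r["moves"])
            rec.set_tag("ts", r["trim"])
            bam.write(rec)
        orphan = pysam.AlignedSegment()
        orphan.query_name = "bam_only_read"
        orphan.flag = 4
        orphan.query_sequence = "ACGT" * 10
        orphan.query_qualities = [20] * 40
        orphan.set_tag("mv", [stride] + [1] * 40)
        orphan.set_tag("ts", 0)
        bam.write(orphan)

    csv_path = outdir / "rrms_decisions.csv"
    write_rrms_csv([(r["read_id"],
                     "stop_receiving" if i % 2 == 0 else "unblock")
                    for i, r in enumerate(reads)], csv_path)

    manifest = {
        "format": "signal",
        "files": {"fast5_multi": str(multi), "fast5_single": str(single),
                  "bam": str(bam_path), "rrms_csv": str(csv_path)},
        "stride": stride, "motif": motif, "channel": channel,
        "reads": [{"read_id": r["read_id"], "seq": r["seq"],
                   "trim": r["trim"], "n_samples": len(r["raw"]),
                   "per_base_samples": r["per_base_samples"]}
                  for r in reads],
        "bam_only": ["bam_only_read"],
    }
    with open(outdir / "manifest.json", "wt") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
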