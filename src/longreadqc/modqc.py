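"""Decoding and summarizing SAM MM/ML base-modification tags.

MM tags delta-encode modified positions over occurrences of a canonical
base in the read's original (basecall) orientation; ML stores one byte
per implied probability. A byte b maps to the midpoint probability
(b + 0.5)/256, so decoded probabilities lie in [1/512, 511/512].

Calls on aligned reads can be anchored to reference coordinates through
the CIGAR, which also classifies them as CpG or non-CpG using the
reference sequence (not the read), matching how per-site methylation
pileups are defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pysam

from .errors import MalformedTagError
from .bamqc import classify_read

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")

_M, _I, _D, _N, _S, _H, _P, _EQ, _X = range(9)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class ModCall:
    """One base-modification prediction on one read."""

    read_id: str
    read_pos: int          # 0-based, original (basecall) orientation
    mod_code: str          # e.g. "m" for 5mC, or a numeric ChEBI id
    canonical_base: str
    strand: str            # reference strand of the modified base, '+'/'-'
    prob: float            # in [1/512, 511/512]
    read_len: int
    aligned_pos: int = -1  # position in the stored (aligned-orientation) SEQ
    ref_pos: int | None = None
    is_cpg: bool = False


def _parse_mm_entries(mm: str, read_id: str | None):
    """Yield (base, strand, [codes], mode, [deltas]) per MM item."""
    for item in mm.strip().split(";"):
        if not item:
            continue
        base = item[0]
        if len(item) < 2 or item[1] not in "+-":
            raise MalformedTagError(f"malformed MM item {item!r}",
                                    record=read_id)
        strand = item[1]
        rest = item[2:]
        head, _, tail = rest.partition(",")
        mode = "."
        if head.endswith("?") or head.endswith("."):
            mode = head[-1]
            head = head[:-1]
        if head.isdigit():        # numeric ChEBI code: one code
            codes = [head]
        else:
            codes = list(head)
        if not codes:
            raise MalformedTagError(f"MM item {item!r} lists no mod code",
                                    record=read_id)
        deltas = [int(d) for d in tail.split(",")] if tail else []
        yield base, strand, codes, mode, deltas


def decode_mm_ml(seq: str, flag: int, mm: str, ml,
                 read_id: str | None = None) -> list[ModCall]:
    """Expand MM/ML tags into explicit per-position modification calls.

    ``seq`` is the stored SEQ field (aligned orientation). For
    reverse-strand records (flag 0x10) the delta encoding runs over the
    reverse complement, i.e. the read as the basecaller emitted it.
    Implicit '.'-mode positions are not synthesized: only explicitly
    listed predictions are returned. Unknown canonical bases are skipped
    with a warning; an ML byte count that disagrees with MM raises
    :class:`MalformedTagError`.
    """
    if not mm or not mm.strip(";").strip():
        return []
    is_reverse = bool(flag & 0x10)
    work = reverse_complement(seq.upper()) if is_reverse else seq.upper()
    length = len(work)
    ml = list(ml) if ml is not None else []

    # occurrence positions per canonical base, computed lazily
    occ_cache: dict[str, list[int]] = {}

    def occurrences(base: str) -> list[int]:
        if base not in occ_cache:
            if base == "N":
                occ_cache[base] = list(range(length))
            else:
                occ_cache[base] = [i for i, b in enumerate(work) if b == base]
        return occ_cache[base]

    calls: list[ModCall] = []
    ml_idx = 0
    for base, mm_strand, codes, mode, deltas in _parse_mm_entries(mm, read_id):
        n_bytes = len(deltas) * len(codes)
        if base not in "ACGTUN":
            logger.warning("skipping MM entry with unknown canonical base %r "
                           "on read %s", base, read_id)
            ml_idx += n_bytes
            continue
        occ = occurrences(base)
        occ_idx = -1
        for delta in deltas:
            occ_idx += delta + 1
            if occ_idx >= len(occ):
                raise MalformedTagError(
                    f"MM deltas overrun {base!r} occurrences", record=read_id)
            pos = occ[occ_idx]
            for code in codes:
                if ml_idx >= len(ml):
                    raise MalformedTagError(
                        "ML has fewer bytes than MM implies", record=read_id)
                prob = (ml[ml_idx] + 0.5) / 256.0
                ml_idx += 1
                # reference strand of the modified base after mapping
                ref_strand = "+" if (mm_strand == "+") != is_reverse else "-"
                aligned = length - 1 - pos if is_reverse else pos
                calls.append(ModCall(
                    read_id=read_id or "", read_pos=pos, mod_code=code,
                    canonical_base=base, strand=ref_strand, prob=prob,
                    read_len=length, aligned_pos=aligned))
    if ml_idx != len(ml):
        raise MalformedTagError(
            f"ML has {len(ml)} bytes but MM implies {ml_idx}", record=read_id)
    return calls


def query_to_ref_map(cigar: list[tuple[int, int]],
                     ref_start: int) -> dict[int, int]:
    """Map stored-SEQ positions to 0-based reference positions.

    Only aligned columns (M/=/X) appear; insertions and soft clips have
    no reference coordinate, deletions and skips no query coordinate.
    """
    mapping: dict[int, int] = {}
    q = 0
    r = ref_start
    for op, ln in cigar:
        if op in (_M, _EQ, _X):
            for k in range(ln):
                mapping[q + k] = r + k
            q += ln
            r += ln
        elif op in (_I, _S):
            q += ln
        elif op in (_D, _N):
            r += ln
        # H, P consume neither stored SEQ nor reference
    return mapping


def anchor_to_reference(call: ModCall, cigar: list[tuple[int, int]],
                        ref_start: int, ref_seq: str,
                        qpos_map: dict[int, int] | None = None) -> ModCall:
    """Attach a reference coordinate and CpG flag to a call.

    ``ref_seq`` is the reference contig sequence (forward strand). A
    call landing in an insertion or clip keeps ``ref_pos=None`` and is
    never counted as CpG. CpG is defined on the reference: a '+' strand
    call at p needs ref[p:p+2] == CG; a '-' strand call at p needs
    ref[p-1:p+1] == CG.
    """
    mapping = qpos_map if qpos_map is not None else query_to_ref_map(
        cigar, ref_start)
    ref_pos = mapping.get(call.aligned_pos)
    call.ref_pos = ref_pos
    if ref_pos is None:
        call.is_cpg = False
        return call
    if call.strand == "+":
        call.is_cpg = ref_seq[ref_pos:ref_pos + 2].upper() == "CG"
    else:
        call.is_cpg = (ref_pos >= 1
                       and ref_seq[ref_pos - 1:ref_pos + 1].upper() == "CG")
    return call


#: Number of read-length-percentile bins in the positional profile.
PROFILE_BINS = 101


@dataclass
class ModCodeSummary:
    total_predictions: int = 0
    above_threshold: int = 0
    cpg_above_threshold_fwd: int = 0
    cpg_above_threshold_rev: int = 0
    profile_prob_sum: np.ndarray = field(
        default_factory=lambda: np.zeros(PROFILE_BINS))
    profile_count: np.ndarray = field(
        default_factory=lambda: np.zeros(PROFILE_BINS, dtype=np.int64))

    @property
    def position_profile(self) -> list[float | None]:
        """Mean probability per read-length percentile (None where empty)."""
        out: list[float | None] = []
        for s, n in zip(self.profile_prob_sum, self.profile_count):
            out.append(s / n if n else None)
        return out


@dataclass
class ModificationSummary:
    per_code: dict[str, ModCodeSummary] = field(default_factory=dict)
    threshold: float = 0.8
    reads_with_calls: int = 0

    def code(self, mod_code: str) -> ModCodeSummary:
        return self.per_code.setdefault(mod_code, ModCodeSummary())


def _profile_bin(read_pos: int, read_len: int) -> int:
    if read_len <= 1:
        return 0
    return int(round(100.0 * read_pos / (read_len - 1)))


def summarize_modifications(bam_path, ref_path=None,
                            threshold: float = 0.8) -> ModificationSummary:
    """Scan a BAM and summarize every modification code found.

    Primary records only (each molecule once). The threshold comparison
    is >= , so a call exactly at the threshold counts as modified. CpG
    counting requires a reference FASTA; without one, CpG counters stay
    zero. The positional profile averages probability within each
    read-length percentile (0..100).
    """
    summary = ModificationSummary(threshold=threshold)
    ref = pysam.FastaFile(str(ref_path)) if ref_path is not None else None
    contig_cache: dict[str, str] = {}
    try:
        with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
            for rec in bam.fetch(until_eof=True):
                category, _ = classify_read(rec.flag)
                if category in ("secondary", "supplementary"):
                    continue
                mm = None
                for tag in ("MM", "Mm"):
                    if rec.has_tag(tag):
                        mm = rec.get_tag(tag)
                        break
                if mm is None or rec.query_sequence is None:
                    continue
                ml = None
                for tag in ("ML", "Ml"):
                    if rec.has_tag(tag):
                        ml = rec.get_tag(tag)
                        break
                calls = decode_mm_ml(rec.query_sequence, rec.flag, mm, ml,
                                     read_id=rec.query_name)
                if not calls:
                    continue
                summary.reads_with_calls += 1
                qpos_map = None
                ref_seq = None
                if (ref is not None and category == "primary_mapped"
                        and rec.cigartuples):
                    name = rec.reference_name
                    if name in ref.references:
                        if name not in contig_cache:
                            contig_cache[name] = ref.fetch(name)
                        ref_seq = contig_cache[name]
                        qpos_map = query_to_ref_map(rec.cigartuples,
                                                    rec.reference_start)
                for call in calls:
                    cs = summary.code(call.mod_code)
                    cs.total_predictions += 1
                    b = _profile_bin(call.read_pos, call.read_len)
                    cs.profile_prob_sum[b] += call.prob
                    cs.profile_count[b] += 1
                    above = call.prob >= threshold
                    if above:
                        cs.above_threshold += 1
                    if ref_seq is not None:
                        anchor_to_reference(call, rec.cigartuples,
                                            rec.reference_start, ref_seq,
                                            qpos_map)
                        if above and call.is_cpg:
                            if call.strand == "+":
                                cs.cpg_above_threshold_fwd += 1
                            else:
                                cs.cpg_above_threshold_rev += 1
    finally:
        if ref is not None:
            ref.close()
    return summary
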