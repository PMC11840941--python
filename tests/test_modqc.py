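"""MM/ML modification decoding, reference anchoring, CpG counting and
pileup concordance, cross-checked against htslib's own decoder and a
per-site brute-force pileup."""

import pysam
import pytest

from longreadqc import (MalformedTagError, anchor_to_reference, decode_mm_ml,
                        summarize_modifications)
from longreadqc.modqc import query_to_ref_map, reverse_complement


def test_decode_forward_example():
    # deltas count skipped canonical bases: 0 -> first C (pos 1),
    # then 0 -> the very next C (pos 3)
    calls = decode_mm_ml("ACGCG", 0, "C+m,0,0;", [255, 0])
    assert [c.read_pos for c in calls] == [1, 3]
    assert calls[0].prob == pytest.approx(255.5 / 256)
    assert calls[1].prob == pytest.approx(0.5 / 256)
    assert all(c.canonical_base == "C" and c.strand == "+" for c in calls)


def test_decode_empty_mm():
    assert decode_mm_ml("ACGT", 0, "", []) == []
    assert decode_mm_ml("ACGT", 0, "C+m;", []) == []


def test_decode_reverse_equals_forward_of_revcomp():
    """Reverse-strand decoding counts canonical bases from the 3' end —
    the same call set as forward-decoding the reverse complement."""
    seq = "AACGTCCGGA"  # stored (aligned) orientation
    # revcomp = TCCGGACGTT with C's at 1,2,6: deltas 0,1 hit the 1st and 3rd
    mm, ml = "C+m,0,1;", [200, 100]
    rev = decode_mm_ml(seq, 16, mm, ml)
    fwd = decode_mm_ml(reverse_complement(seq), 0, mm, ml)
    assert [(c.read_pos, c.prob) for c in rev] == \
        [(c.read_pos, c.prob) for c in fwd]
    # aligned positions map back through L-1-pos
    assert [c.aligned_pos for c in rev] == \
        [len(seq) - 1 - c.read_pos for c in fwd]


def test_decode_ml_length_mismatch():
    with pytest.raises(MalformedTagError):
        decode_mm_ml("ACGCG", 0, "C+m,0,1;", [255])
    with pytest.raises(MalformedTagError):
        decode_mm_ml("ACGCG", 0, "C+m,0;", [255, 1])


def test_decode_probability_bounds(modified):
    with pysam.AlignmentFile(modified["files"]["bam"]) as bam:
        for rec in bam.fetch(until_eof=True):
            if not rec.has_tag("MM"):
                continue
            for c in decode_mm_ml(rec.query_sequence, rec.flag,
                                  rec.get_tag("MM"), rec.get_tag("ML")):
                assert 1 / 512 <= c.prob <= 511 / 512
                assert 0 <= c.read_pos < c.read_len


def test_decode_agrees_with_htslib(modified):
    """Independent cross-check: positions/bytes from pysam's own
    modified_bases_forward equal ours on every fixture record."""
    checked = 0
    with pysam.AlignmentFile(modified["files"]["bam"]) as bam:
        for rec in bam.fetch(until_eof=True):
            if not rec.has_tag("MM") or not rec.get_tag("MM"):
                continue
            ours = decode_mm_ml(rec.query_sequence, rec.flag,
                                rec.get_tag("MM"), rec.get_tag("ML"))
            theirs = rec.modified_bases_forward[("C", 0, "m")]
            assert sorted((c.read_pos, round(c.prob * 256 - 0.5))
                          for c in ours) == sorted(theirs)
            checked += 1
    assert checked > 0


def test_anchor_simple_10m():
    calls = decode_mm_ml("AACAAAAAAA", 0, "C+m,0;", [230])
    call = anchor_to_reference(calls[0], [(0, 10)], 100, "N" * 300)
    assert call.ref_pos == 102


def test_anchor_inside_insertion_has_no_ref_pos():
    # read: 2M 2I 6M; query positions 2,3 are inserted
    mapping = query_to_ref_map([(0, 2), (1, 2), (0, 6)], 50)
    assert 2 not in mapping and 3 not in mapping
    assert mapping[1] == 51 and mapping[4] == 52


def test_anchor_cpg_context():
    ref = "TTCGTT"
    calls = decode_mm_ml("TTCGTT", 0, "C+m,0;", [230])
    call = anchor_to_reference(calls[0], [(0, 6)], 0, ref)
    assert call.ref_pos == 2 and call.is_cpg
    # a call on the first T is not CpG (use an N-anchored entry)
    tcalls = decode_mm_ml("TTCGTT", 0, "T+x,0;", [230])
    tcall = anchor_to_reference(tcalls[0], [(0, 6)], 0, ref)
    assert tcall.ref_pos == 0 and not tcall.is_cpg


def test_orientation_involution(modified):
    """A record and its flag-flipped, reverse-complemented twin (same
    MM/ML tags — both describe the basecalled read) decode to identical
    basecall-frame call sets, with mirrored aligned positions."""
    with pysam.AlignmentFile(modified["files"]["bam"]) as bam:
        rec = next(r for r in bam.fetch(until_eof=True)
                   if r.has_tag("MM") and not r.is_reverse)
    mm, ml = rec.get_tag("MM"), rec.get_tag("ML")
    fwd = decode_mm_ml(rec.query_sequence, 0, mm, ml)
    twin = decode_mm_ml(reverse_complement(rec.query_sequence), 16, mm, ml)
    assert [(c.read_pos, c.mod_code, c.prob) for c in fwd] == \
        [(c.read_pos, c.mod_code, c.prob) for c in twin]
    L = len(rec.query_sequence)
    assert [c.aligned_pos for c in twin] == \
        [L - 1 - c.aligned_pos for c in fwd]
    assert {c.strand for c in fwd} == {"+"} and {c.strand for c in twin} == \
        {"-"}


def test_threshold_one_counts_nothing(modified):
    s = summarize_modifications(modified["files"]["bam"],
                                modified["files"]["reference"],
                                threshold=1.0)
    assert s.per_code["m"].above_threshold == 0
    assert s.per_code["m"].total_predictions == \
        modified["total_predictions"]


def test_threshold_is_inclusive():
    calls = decode_mm_ml("AC", 0, "C+m,0;", [204])  # (204+.5)/256 = 0.7988
    assert calls[0].prob < 0.8
    calls = decode_mm_ml("AC", 0, "C+m,0;", [205])  # 0.8027 >= 0.8
    assert calls[0].prob >= 0.8


def test_summary_matches_manifest_pileup(modified):
    """Read-level above-threshold CpG counts per strand equal the
    generator's per-site pileup sums."""
    s = summarize_modifications(modified["files"]["bam"],
                                modified["files"]["reference"], 0.8)
    cs = s.per_code["m"]
    assert cs.total_predictions == modified["total_predictions"]
    assert cs.above_threshold == modified["above_threshold"]
    assert cs.cpg_above_threshold_fwd == modified["cpg_above_threshold_fwd"]
    assert cs.cpg_above_threshold_rev == modified["cpg_above_threshold_rev"]
    assert cs.above_threshold <= cs.total_predictions
    assert (cs.cpg_above_threshold_fwd + cs.cpg_above_threshold_rev
            <= cs.above_threshold)


def test_pileup_concordance_brute_force(modified):
    """Per-site pileup built independently (htslib decode + aligned
    pairs) sums to our read-level per-strand CpG counts."""
    ref = pysam.FastaFile(modified["files"]["reference"]).fetch("chr_syn")
    pile_fwd, pile_rev = {}, {}
    with pysam.AlignmentFile(modified["files"]["bam"]) as bam:
        for rec in bam.fetch(until_eof=True):
            if not rec.has_tag("MM") or not rec.get_tag("MM"):
                continue
            qpos2ref = dict(rec.get_aligned_pairs(matches_only=True))
            # modified_bases gives aligned-orientation positions
            for (base, strand_flag, code), items in \
                    (rec.modified_bases or {}).items():
                for qpos, byte in items:
                    if (byte + 0.5) / 256.0 < 0.8:
                        continue
                    rpos = qpos2ref.get(qpos)
                    if rpos is None:
                        continue
                    if not rec.is_reverse:
                        if ref[rpos:rpos + 2] == "CG":
                            pile_fwd[rpos] = pile_fwd.get(rpos, 0) + 1
                    else:
                        if rpos >= 1 and ref[rpos - 1:rpos + 1] == "CG":
                            pile_rev[rpos] = pile_rev.get(rpos, 0) + 1
    s = summarize_modifications(modified["files"]["bam"],
                                modified["files"]["reference"], 0.8)
    cs = s.per_code["m"]
    assert sum(pile_fwd.values()) == cs.cpg_above_threshold_fwd
    assert sum(pile_rev.values()) == cs.cpg_above_threshold_rev
    # and the generator's site map agrees site-by-site
    assert {int(k): v for k, v in modified["pileup_fwd"].items()} == pile_fwd
    assert {int(k): v for k, v in modified["pileup_rev"].items()} == pile_rev


def test_position_profile_bins_probabilities():
    from longreadqc.modqc import _profile_bin
    assert _profile_bin(0, 100) == 0
    assert _profile_bin(99, 100) == 100
    assert _profile_bin(50, 101) == 50
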