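"""TIN: BED12 parsing, position sampling, coverage filters, the entropy
score and its closed-form limits, and regime recovery on simulated
coverage."""

import math

import numpy as np
import pysam
import pytest

from longreadqc import (ParseError, compute_tin, parse_bed12,
                        sample_positions, summarize_tin, transcript_coverage)
from longreadqc.tin import TranscriptModel


def bed_line(chrom="chr1", start=100, end=116, name="tx", strand="+",
             count=2, sizes="4,6", starts="0,10"):
    return "\t".join([chrom, str(start), str(end), name, "0", strand,
                      str(start), str(end), "0", str(count), sizes, starts])


def test_parse_bed12_blocks():
    m = parse_bed12(bed_line())
    assert m.exon_blocks == [(100, 104), (110, 116)]
    assert m.mrna_length == 10
    assert (m.name, m.chrom, m.strand) == ("tx", "chr1", "+")


def test_parse_bed12_single_block():
    m = parse_bed12(bed_line(count=1, sizes="16", starts="0"))
    assert m.exon_blocks == [(100, 116)] and m.mrna_length == 16


def test_parse_bed12_block_count_mismatch():
    with pytest.raises(ParseError):
        parse_bed12(bed_line(count=2, sizes="4,6,2", starts="0,10,14"))


def test_parse_bed12_block_outside_span():
    with pytest.raises(ParseError):
        parse_bed12(bed_line(end=110, sizes="4,6", starts="0,10"))


def test_sample_positions_all_when_short():
    m = TranscriptModel("t", "c", "+", [(0, 10)])
    assert sample_positions(m, 10) == list(range(10))
    assert sample_positions(m, 50) == list(range(10))


def test_sample_positions_closed_form_spacing():
    m = TranscriptModel("t", "c", "+", [(0, 101)])
    assert sample_positions(m, 11) == [0, 10, 20, 30, 40, 50, 60, 70, 80,
                                       90, 100]


def test_sample_positions_spliced_block_walk():
    """mRNA indices past the first block land in the second block's
    reference range; verified against an explicit concatenated map."""
    m = TranscriptModel("t", "c", "+", [(100, 104), (110, 116)])
    # brute-force mRNA->reference map
    flat = [p for lo, hi in m.exon_blocks for p in range(lo, hi)]
    assert sample_positions(m, 50) == flat
    m2 = TranscriptModel("t", "c", "+", [(0, 500), (1000, 1500)])
    flat2 = [p for lo, hi in m2.exon_blocks for p in range(lo, hi)]
    got = sample_positions(m2, 10)
    expect = [flat2[round(i * 999 / 9)] for i in range(10)]
    assert got == expect


def _one_read_bam(tmp_path, quals):
    path = tmp_path / "one.bam"
    with pysam.AlignmentFile(path, "wb", header={
            "HD": {"VN": "1.6"}, "SQ": [{"SN": "c", "LN": 100}]}) as bam:
        rec = pysam.AlignedSegment()
        rec.query_name = "r"
        rec.flag = 0
        rec.reference_id = 0
        rec.reference_start = 0
        rec.mapping_quality = 60
        rec.query_sequence = "A" * 10
        rec.query_qualities = quals
        rec.cigartuples = [(0, 10)]
        bam.write(rec)
    pysam.index(str(path))
    return path


def test_coverage_single_read(tmp_path):
    path = _one_read_bam(tmp_path, [40] * 10)
    model = TranscriptModel("t", "c", "+", [(0, 10)])
    with pysam.AlignmentFile(path) as bam:
        cov, n = transcript_coverage(bam, model)
    assert n == 1 and cov == {p: 1 for p in range(10)}


def test_coverage_low_quality_base_excluded(tmp_path):
    quals = [40] * 10
    quals[5] = 10
    path = _one_read_bam(tmp_path, quals)
    model = TranscriptModel("t", "c", "+", [(0, 10)])
    with pysam.AlignmentFile(path) as bam:
        cov, _ = transcript_coverage(bam, model)
    assert cov.get(5, 0) == 0 and cov[4] == 1


def test_coverage_matches_pileup_oracle(transcripts_uniform):
    """Per-position counts equal samtools' pileup on the fixture (all
    bases Q40, no dedup subtleties)."""
    from longreadqc.tin import read_bed12
    model = next(m for m in read_bed12(transcripts_uniform["files"]["bed12"])
                 if m.name == "tx_main")
    with pysam.AlignmentFile(transcripts_uniform["files"]["bam"]) as bam:
        cov, _ = transcript_coverage(bam, model)
        pile = {}
        for col in bam.pileup(model.chrom, model.start, model.end,
                              truncate=True, min_base_quality=13):
            pile[col.reference_pos] = sum(
                1 for p in col.pileups
                if not p.is_del and not p.is_refskip)
    for lo, hi in model.exon_blocks:
        for p in range(lo, hi):
            assert cov.get(p, 0) == pile.get(p, 0)


@pytest.mark.parametrize("k", [3, 20, 100])
def test_tin_uniform_is_100(k):
    assert compute_tin([7] * k) == pytest.approx(100.0)


@pytest.mark.parametrize("k", [2, 20, 50])
def test_tin_single_spike_is_100_over_k(k):
    cov = [0] * k
    cov[k // 2] = 9
    assert compute_tin(cov) == pytest.approx(100.0 / k)


def test_tin_entropy_oracle():
    # p = (0.25, 0.25, 0.5); H = 1.5 ln 2; TIN = 100 * e^H / 3
    expected = 100.0 * math.exp(1.5 * math.log(2)) / 3
    assert compute_tin([1, 1, 2]) == pytest.approx(expected, abs=1e-9)
    assert compute_tin([1, 1, 2]) == pytest.approx(94.2809, abs=1e-3)


def test_tin_zero_coverage_is_zero():
    assert compute_tin([0, 0, 0]) == 0.0


def test_tin_bounds_and_permutation_invariance():
    rng = np.random.default_rng(3)
    for _ in range(100):
        cov = rng.integers(0, 50, size=rng.integers(1, 60))
        t = compute_tin(cov)
        assert 0.0 <= t <= 100.0 + 1e-9
        assert compute_tin(rng.permutation(cov)) == pytest.approx(t)


def test_tin_monotone_under_mass_concentration():
    """Moving coverage from a low position onto a high one (majorization)
    never increases TIN."""
    rng = np.random.default_rng(4)
    for _ in range(200):
        cov = rng.integers(1, 30, size=20).astype(float)
        lo = int(np.argmin(cov))
        hi = int(np.argmax(cov))
        if lo == hi:
            continue
        before = compute_tin(cov)
        cov2 = cov.copy()
        move = rng.uniform(0, cov2[lo])
        cov2[lo] -= move
        cov2[hi] += move
        assert compute_tin(cov2) <= before + 1e-9


def test_summarize_uniform_fixture(transcripts_uniform):
    res, agg = summarize_tin(transcripts_uniform["files"]["bam"],
                             transcripts_uniform["files"]["bed12"])
    assert [r.transcript for r in res] == ["tx_main"]  # sparse filtered out
    assert res[0].tin == pytest.approx(100.0, abs=1.0)
    assert agg["median"] == pytest.approx(100.0, abs=1.0)


def test_summarize_three_prime_biased(transcripts_biased):
    res, _ = summarize_tin(transcripts_biased["files"]["bam"],
                           transcripts_biased["files"]["bed12"])
    assert res[0].tin == pytest.approx(33.3, abs=3.0)


def test_summarize_spiked_is_100_over_k(transcripts_spiked):
    res, _ = summarize_tin(transcripts_spiked["files"]["bam"],
                           transcripts_spiked["files"]["bed12"],
                           sample_size=100)
    assert res[0].n_positions_sampled == 100
    assert res[0].tin == pytest.approx(100.0 / 100)


def test_min_coverage_excludes_sparse(transcripts_uniform):
    res, agg = summarize_tin(transcripts_uniform["files"]["bam"],
                             transcripts_uniform["files"]["bed12"],
                             min_coverage=10)
    assert all(r.transcript != "tx_sparse" for r in res)
    res2, _ = summarize_tin(transcripts_uniform["files"]["bam"],
                            transcripts_uniform["files"]["bed12"],
                            min_coverage=2)
    assert any(r.transcript == "tx_sparse" for r in res2)


def test_no_scored_transcripts_reports_missing(transcripts_uniform):
    _, agg = summarize_tin(transcripts_uniform["files"]["bam"],
                           transcripts_uniform["files"]["bed12"],
                           min_coverage=10_000)
    assert agg == {"mean": None, "median": None, "stdev": None}


def test_three_prime_bias_scores_below_uniform():
    """Simulated 3'-biased coverage scores below unbiased coverage at
    matched depth in at least 95% of replicates."""
    rng = np.random.default_rng(12)
    L, k, depth, read_len = 2000, 100, 30, 300
    wins = 0
    n_rep = 200
    samples = [round(i * (L - 1) / (k - 1)) for i in range(k)]
    for _ in range(n_rep):
        cov_u = np.zeros(L)
        cov_b = np.zeros(L)
        for _ in range(depth):
            s = rng.integers(0, L - read_len)
            cov_u[s:s + read_len] += 1
            s = rng.integers(2 * L // 3, L - read_len) \
                if L - read_len > 2 * L // 3 else rng.integers(0, L - read_len)
            cov_b[s:s + read_len] += 1
        tu = compute_tin(cov_u[samples])
        tb = compute_tin(cov_b[samples])
        if tb < tu:
            wins += 1
    assert wins >= 0.95 * n_rep
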