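"""FAST5 reading, move-table segmentation, picoampere conversion, and
signal/basecall pairing."""

import numpy as np
import pytest

from longreadqc import (BoundsError, MalformedTagError, SignalTrace,
                        extract_region_signal, pair_signal_bam, read_fast5,
                        segment_signal)
from longreadqc.errors import LongReadQCError
from longreadqc.signalqc import SignalBasecallPair


def make_trace(raw_len=40, trim=10, stride=5, **kw):
    return SignalTrace("t", np.arange(raw_len, dtype=np.int16),
                       trim_start=trim, stride=stride, **kw)


def test_segment_simple_moves():
    trace = make_trace(40, trim=10, stride=5)
    seg = segment_signal(trace, [1, 1, 1], 3)
    assert seg.segments == [(10, 15), (15, 20), (20, 40)]


def test_segment_zero_move_extends_previous_base():
    trace = make_trace(6, trim=0, stride=2)
    seg = segment_signal(trace, [1, 0, 1], 2)
    assert seg.segments == [(0, 4), (4, 6)]


def test_segment_empty_sequence():
    trace = make_trace()
    assert segment_signal(trace, [], 0).segments == []


def test_segment_count_mismatch():
    trace = make_trace()
    with pytest.raises(MalformedTagError):
        segment_signal(trace, [1, 0, 1], 3)


def test_segment_conservation_random_moves():
    """Segments tile [trim_start, len(raw)) exactly for random valid
    move tables."""
    rng = np.random.default_rng(9)
    for _ in range(100):
        stride = int(rng.integers(1, 8))
        trim = int(rng.integers(0, 30))
        n_steps = int(rng.integers(1, 60))
        moves = rng.integers(0, 2, size=n_steps)
        moves[0] = 1
        raw_len = trim + n_steps * stride + int(rng.integers(0, 10))
        trace = SignalTrace("t", np.zeros(raw_len, dtype=np.int16),
                            trim_start=trim, stride=stride)
        seq_len = int(moves.sum())
        seg = segment_signal(trace, moves, seq_len)
        assert seg.segments[0][0] == trim
        assert seg.segments[-1][1] == raw_len
        for (s0, e0), (s1, e1) in zip(seg.segments, seg.segments[1:]):
            assert e0 == s1 and s0 < e0
        assert sum(e - s for s, e in seg.segments) == raw_len - trim


def test_pa_conversion_affine_invertible():
    trace = SignalTrace("t", np.array([0, 100, 2047], dtype=np.int16),
                        offset=12.0, range_pa=1402.882, digitisation=8192.0)
    pa = trace.to_pa()
    back = pa * trace.digitisation / trace.range_pa - trace.offset
    assert np.allclose(back, trace.raw)
    assert pa[0] == pytest.approx(12.0 * 1402.882 / 8192.0)


def test_fast5_multi_read_matches_manifest(signal):
    traces = {t.read_id: t for t in
              read_fast5(signal["files"]["fast5_multi"])}
    assert set(traces) == {r["read_id"] for r in signal["reads"]}
    for r in signal["reads"]:
        t = traces[r["read_id"]]
        assert len(t.raw) == r["n_samples"]
        assert t.trim_start == r["trim"]
        assert t.stride == signal["stride"]
        assert t.sequence == r["seq"]


def test_fast5_single_read_layout_equivalence(signal):
    (single,) = read_fast5(signal["files"]["fast5_single"])
    multi = {t.read_id: t for t in read_fast5(signal["files"]["fast5_multi"])}
    twin = multi[single.read_id]
    assert np.array_equal(single.raw, twin.raw)
    assert single.sequence == twin.sequence
    assert (single.offset, single.range_pa, single.digitisation) == \
        (twin.offset, twin.range_pa, twin.digitisation)
    assert single.trim_start == twin.trim_start


def test_fast5_unsupported_layout(tmp_path):
    import h5py
    p = tmp_path / "odd.fast5"
    with h5py.File(p, "w") as f5:
        f5.create_group("Something")
    with pytest.raises(Exception, match="layout"):
        list(read_fast5(p))


def test_pairing_join_and_orphans(signal):
    traces = list(read_fast5(signal["files"]["fast5_multi"]))
    result = pair_signal_bam(traces, signal["files"]["bam"])
    assert len(result.pairs) == len(signal["reads"])
    assert result.bam_only == signal["bam_only"]
    assert result.signal_only == []


def test_pairing_order_independent(signal):
    traces = list(read_fast5(signal["files"]["fast5_multi"]))
    fwd = pair_signal_bam(traces, signal["files"]["bam"])
    rev = pair_signal_bam(list(reversed(traces)), signal["files"]["bam"])
    assert {p.trace.read_id for p in fwd.pairs} == \
        {p.trace.read_id for p in rev.pairs}


def test_pairing_zero_overlap_is_hard_error(signal):
    stray = [SignalTrace("unrelated", np.zeros(10, dtype=np.int16))]
    with pytest.raises(LongReadQCError, match="mismatched"):
        pair_signal_bam(stray, signal["files"]["bam"])


def test_full_range_extraction_conserves_raw(signal):
    traces = list(read_fast5(signal["files"]["fast5_multi"]))
    result = pair_signal_bam(traces, signal["files"]["bam"])
    for pair in result.pairs:
        series = extract_region_signal(pair, 0,
                                       len(pair.segmentation.segments),
                                       picoamperes=False)
        cat = np.concatenate([s for _, s in series])
        assert np.array_equal(cat, pair.trace.raw[pair.trace.trim_start:])


def test_periodic_motif_levels(signal):
    """A read built from a repeating 3-base motif shows per-base mean
    picoampere levels repeating with period 3."""
    traces = list(read_fast5(signal["files"]["fast5_multi"]))
    result = pair_signal_bam(traces, signal["files"]["bam"])
    pair = result.pairs[0]
    series = extract_region_signal(pair, 0, 12)
    means = [float(np.mean(s)) for _, s in series]
    bases = [b for b, _ in series]
    assert bases[:6] == list(signal["motif"] * 2)
    for i in range(6):
        # same base three positions apart -> same underlying level
        assert means[i] == pytest.approx(means[i + 3], abs=1.5)
    # different bases have well-separated levels
    assert abs(means[0] - means[1]) > 5


def test_extraction_bounds_checked(signal):
    traces = list(read_fast5(signal["files"]["fast5_multi"]))
    result = pair_signal_bam(traces, signal["files"]["bam"])
    pair = result.pairs[0]
    n = len(pair.segmentation.segments)
    with pytest.raises(BoundsError):
        extract_region_signal(pair, 0, n + 1)
    with pytest.raises(BoundsError):
        extract_region_signal(pair, 5, 5)
    (single,) = extract_region_signal(pair, 0, 1)
    assert single[0] == pair.sequence[0]
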