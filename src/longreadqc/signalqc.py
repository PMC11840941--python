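"""Raw nanopore signal extraction and per-base segmentation.

FAST5 files are HDF5 containers holding the raw current trace (integer
DAC samples) plus channel calibration; picoampere conversion is the
affine map pA = (raw + offset) * range / digitisation. Basecallers emit
a move table (mv tag, or an embedded Move dataset): after trimming
``trim_start`` samples, every ``stride`` samples is one step, and a 1
marks the step where a new base begins. Segmenting the trace by these
moves gives the per-base signal intervals used for signal-to-base
correspondence plots (e.g. inspecting repeat motifs).

POD5 stores signal only; its basecalls live in a companion BAM. The
pairing/segmentation logic here is container-agnostic: `pair_signal_bam`
joins any SignalTrace stream with a basecalled BAM, and `pair_pod5_bam`
feeds it from the optional `pod5` reader package when installed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pysam

from .errors import BoundsError, LongReadQCError, MalformedTagError, ParseError


@dataclass
class SignalTrace:
    """One read's raw signal plus calibration and basecall linkage."""

    read_id: str
    raw: np.ndarray                      # integer DAC samples
    offset: float = 0.0
    range_pa: float = 1.0
    digitisation: float = 1.0
    sampling_rate: float = 4000.0
    trim_start: int = 0                  # samples before the basecalled region
    stride: int = 1                      # samples per move-table step
    sequence: str | None = None          # embedded basecall, if any
    moves: np.ndarray | None = None      # embedded move table, if any

    def __post_init__(self):
        self.raw = np.asarray(self.raw)
        if self.digitisation <= 0:
            raise ParseError("digitisation must be positive",
                             record=self.read_id)

    def to_pa(self, raw_samples=None) -> np.ndarray:
        """Convert DAC samples to picoamperes (affine, invertible)."""
        x = self.raw if raw_samples is None else np.asarray(raw_samples)
        return (x + self.offset) * self.range_pa / self.digitisation


@dataclass
class BaseSegmentation:
    """Ordered, contiguous per-base sample intervals into the raw trace."""

    segments: list[tuple[int, int]]      # half-open, tiling the trimmed trace
    bases: str = ""


def _trace_from_groups(read_id: str, signal_ds, channel_attrs,
                       analyses_group=None) -> SignalTrace:
    trace = SignalTrace(
        read_id=read_id,
        raw=signal_ds[...],
        offset=float(channel_attrs.get("offset", 0.0)),
        range_pa=float(channel_attrs.get("range", 1.0)),
        digitisation=float(channel_attrs.get("digitisation", 1.0)),
        sampling_rate=float(channel_attrs.get("sampling_rate", 4000.0)),
    )
    if analyses_group is not None:
        for name in analyses_group:
            if not name.startswith("Basecall_1D"):
                continue
            bc = analyses_group[name]
            tmpl = bc.get("BaseCalled_template")
            if tmpl is None:
                continue
            if "Fastq" in tmpl:
                fastq = tmpl["Fastq"][()]
                if isinstance(fastq, bytes):
                    fastq = fastq.decode()
                lines = fastq.split("\n")
                if len(lines) >= 2:
                    trace.sequence = lines[1]
            if "Move" in tmpl:
                trace.moves = np.asarray(tmpl["Move"][...])
            trace.stride = int(tmpl.attrs.get("block_stride", 1))
            trace.trim_start = int(tmpl.attrs.get("first_sample_template", 0))
            break
    return trace


def read_fast5(path):
    """Stream SignalTrace objects from a single- or multi-read FAST5.

    The two layouts are auto-detected from the group structure:
    multi-read files hold top-level ``read_<id>`` groups each with their
    own Raw/Signal and channel_id; single-read files use the legacy
    /Raw/Reads/Read_N plus /UniqueGlobalKey/channel_id tree. Embedded
    basecalls (Analyses/Basecall_1D_*/BaseCalled_template) are attached
    when present.
    """
    with h5py.File(path, "r") as f5:
        read_groups = [k for k in f5 if k.startswith("read_")]
        if read_groups:  # multi-read layout
            for key in read_groups:
                grp = f5[key]
                if "Raw" not in grp or "Signal" not in grp["Raw"]:
                    raise ParseError(
                        f"FAST5 group {key} lacks Raw/Signal; groups found: "
                        f"{list(grp)}")
                read_id = grp["Raw"].attrs.get("read_id", key[len("read_"):])
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                yield _trace_from_groups(
                    str(read_id), grp["Raw"]["Signal"],
                    dict(grp["channel_id"].attrs) if "channel_id" in grp else {},
                    grp.get("Analyses"))
            return
        if "Raw" in f5 and "Reads" in f5["Raw"]:  # single-read layout
            channel = {}
            if "UniqueGlobalKey" in f5 and "channel_id" in f5["UniqueGlobalKey"]:
                channel = dict(f5["UniqueGlobalKey"]["channel_id"].attrs)
            for key in f5["Raw"]["Reads"]:
                grp = f5["Raw"]["Reads"][key]
                if "Signal" not in grp:
                    raise ParseError(
                        f"FAST5 read group {key} lacks a Signal dataset")
                read_id = grp.attrs.get("read_id", key)
                if isinstance(read_id, bytes):
                    read_id = read_id.decode()
                yield _trace_from_groups(str(read_id), grp["Signal"], channel,
                                         f5.get("Analyses"))
            return
        raise ParseError(
            "unsupported FAST5 layout: no read_* groups and no /Raw/Reads "
            f"tree; top-level groups: {list(f5)}")


def segment_signal(trace: SignalTrace, moves, seq_len: int) -> BaseSegmentation:
    """Assign each basecalled base its half-open raw-sample interval.

    Base i spans from the sample of its move-table 1 (trim_start +
    step * stride) to the sample of the next 1; the final base runs to
    the end of the raw trace. The segments therefore tile
    [trim_start, len(raw)) exactly.
    """
    moves = np.asarray(moves, dtype=np.int64)
    if seq_len == 0:
        return BaseSegmentation(segments=[], bases="")
    n_starts = int((moves == 1).sum())
    if n_starts != seq_len:
        raise MalformedTagError(
            f"move table marks {n_starts} bases but sequence has {seq_len}",
            record=trace.read_id)
    starts = trace.trim_start + np.flatnonzero(moves == 1) * trace.stride
    ends = np.empty_like(starts)
    ends[:-1] = starts[1:]
    ends[-1] = len(trace.raw)
    if starts[-1] >= len(trace.raw):
        raise MalformedTagError(
            "move table extends past the raw trace", record=trace.read_id)
    bases = trace.sequence[:seq_len] if trace.sequence else ""
    return BaseSegmentation(
        segments=list(zip(starts.tolist(), ends.tolist())), bases=bases)


@dataclass
class SignalBasecallPair:
    trace: SignalTrace
    sequence: str
    quals: list[int] | None
    segmentation: BaseSegmentation


@dataclass
class PairingResult:
    pairs: list[SignalBasecallPair] = field(default_factory=list)
    signal_only: list[str] = field(default_factory=list)
    bam_only: list[str] = field(default_factory=list)


def pair_signal_bam(traces, bam_path) -> PairingResult:
    """Join a SignalTrace stream with its basecalled BAM on read id.

    Primary records only; the mv tag supplies stride + move bits and ts
    the number of trimmed samples. Reads present in only one input are
    reported as orphans; zero overlap is a hard error (almost certainly
    mismatched files).
    """
    by_id = {t.read_id: t for t in traces}
    result = PairingResult()
    seen = set()
    with pysam.AlignmentFile(str(bam_path), check_sq=False) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.flag & (0x100 | 0x800):
                continue
            trace = by_id.get(rec.query_name)
            if trace is None:
                result.bam_only.append(rec.query_name)
                continue
            seen.add(rec.query_name)
            seq = rec.query_sequence or ""
            if rec.flag & 0x10:
                # basecall orientation: undo the aligner's reverse complement
                seq = seq.translate(
                    str.maketrans("ACGTN", "TGCAN"))[::-1]
            if rec.has_tag("mv"):
                mv = list(rec.get_tag("mv"))
                if not mv:
                    raise MalformedTagError("empty mv tag",
                                            record=rec.query_name)
                trace.stride = int(mv[0])
                moves = np.asarray(mv[1:], dtype=np.int64)
            elif trace.moves is not None:
                moves = trace.moves
            else:
                raise MalformedTagError(
                    "no move table: BAM lacks mv tag and FAST5 has no "
                    "embedded Move dataset", record=rec.query_name)
            if rec.has_tag("ts"):
                trace.trim_start = int(rec.get_tag("ts"))
            trace.sequence = seq
            seg = segment_signal(trace, moves, len(seq))
            result.pairs.append(SignalBasecallPair(
                trace=trace, sequence=seq,
                quals=list(rec.query_qualities)
                if rec.query_qualities is not None else None,
                segmentation=seg))
    result.signal_only = sorted(set(by_id) - seen)
    if by_id and not result.pairs:
        raise LongReadQCError(
            "no read ids shared between signal file and BAM — "
            "likely mismatched files")
    return result


def pair_pod5_bam(pod5_path, bam_path) -> PairingResult:
    """Join a POD5 file with its basecalled BAM.

    Container decoding is delegated to the official ``pod5`` reader
    package (optional dependency); everything downstream is shared with
    the FAST5 path.
    """
    try:
        import pod5
    except ImportError as exc:
        raise LongReadQCError(
            "POD5 support requires the optional 'pod5' package "
            "(pip install longreadqc[pod5])") from exc
    traces = []
    with pod5.Reader(str(pod5_path)) as reader:
        for read in reader.reads():
            cal = read.calibration
            traces.append(SignalTrace(
                read_id=str(read.read_id),
                raw=np.asarray(read.signal),
                offset=float(cal.offset),
                range_pa=float(cal.scale) * 8192.0,
                digitisation=8192.0,
                sampling_rate=float(read.run_info.sample_rate),
            ))
    return pair_signal_bam(traces, bam_path)


def extract_region_signal(pair: SignalBasecallPair, start_base: int,
                          end_base: int, picoamperes: bool = True,
                          ) -> list[tuple[str, np.ndarray]]:
    """Per-base signal slices for a basecall index range [start, end).

    Returns one (base, samples) tuple per base; samples are picoamperes
    by default, or raw DAC values with ``picoamperes=False`` (full-range
    raw extraction concatenates back to the trimmed trace exactly).
    """
    n = len(pair.segmentation.segments)
    if not (0 <= start_base < end_base <= n):
        raise BoundsError(
            f"base range [{start_base}, {end_base}) outside basecalled "
            f"length {n}")
    out = []
    for i in range(start_base, end_base):
        lo, hi = pair.segmentation.segments[i]
        samples = pair.trace.raw[lo:hi]
        if picoamperes:
            samples = pair.trace.to_pa(samples)
        base = pair.sequence[i] if i < len(pair.sequence) else "N"
        out.append((base, samples))
    return out
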