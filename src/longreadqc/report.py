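"""Report assembly: QC flags, the summary text file, and the HTML report.

One in-memory :class:`ReportBundle` is computed per run; the summary
text file and the HTML report are both serialized from it, never
recomputed, so every scalar shown in an HTML table appears verbatim in
the summary text. The HTML is a single self-contained file: histograms
are rendered as inline SVG and no external resource is referenced.

QC flag thresholds are deliberately configurable defaults (the warning
feature matters more than any particular cutoff); they ship in
``DEFAULT_THRESHOLDS`` and can be overridden per key.
"""

from __future__ import annotations

import html as html_mod
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .bamqc import AlignmentSummary
from .errors import ConfigError
from .modqc import ModificationSummary
from .stats import BasicStats, Histogram, ReadSetAccumulator, build_histogram, \
    gc_histogram
from .tin import TINResult

SCHEMA_VERSION = 1

DEFAULT_THRESHOLDS = {
    # warn when the median per-read quality falls below this Phred score
    "median_read_quality_warn": 10.0,
    # warn when more than this fraction of reads is unmapped
    "unmapped_fraction_warn": 0.20,
    # warn when the median per-read GC deviates from 50% by more than this
    "gc_median_deviation_warn": 15.0,
    # warn when the median transcript TIN falls below this
    "median_tin_warn": 50.0,
}


@dataclass
class QCFlag:
    section: str
    level: str          # pass | warn | fail
    rule: str
    observed: object


@dataclass
class ReportBundle:
    """Everything one QC run computed, ready for serialization."""

    filetype: str
    basic: BasicStats = field(default_factory=BasicStats)
    histograms: dict[str, Histogram] = field(default_factory=dict)
    per_read_gc: list[float] = field(default_factory=list)
    per_read_quality: list[float] = field(default_factory=list)
    alignment: AlignmentSummary | None = None
    modification: ModificationSummary | None = None
    tin_results: list[TINResult] | None = None
    tin_aggregates: dict | None = None
    rrms_accepted: "ReportBundle | None" = None
    rrms_rejected: "ReportBundle | None" = None
    rrms_unclassified: int | None = None
    rrms_conflicts: int | None = None
    signal_reads: list[dict] | None = None
    flags: list[QCFlag] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)

    # ------------------------------------------------------------------
    def scalar_metrics(self) -> dict[str, object]:
        """Flat key -> value mapping of every scalar the reports show."""
        m: dict[str, object] = {
            "schema_version": SCHEMA_VERSION,
            "tool": "longreadqc",
            "version": __version__,
            "filetype": self.filetype,
        }
        for key, value in sorted(self.parameters.items()):
            m[f"parameter.{key}"] = value

        def add_basic(prefix: str, stats: BasicStats):
            m[f"{prefix}.n_reads"] = stats.n_reads
            m[f"{prefix}.n_bases"] = stats.n_bases
            m[f"{prefix}.max_len"] = stats.max_len
            m[f"{prefix}.mean_len"] = stats.mean_len
            m[f"{prefix}.median_len"] = stats.median_len
            m[f"{prefix}.n50"] = stats.n50
            m[f"{prefix}.gc_percent"] = stats.gc_percent
            for base, count in stats.base_counts.items():
                m[f"{prefix}.base_count.{base}"] = count

        add_basic("basic", self.basic)
        if self.per_read_quality:
            m["quality.median_read_quality"] = float(
                np.median(self.per_read_quality))
            m["quality.mean_read_quality"] = float(
                np.mean(self.per_read_quality))
        if self.per_read_gc:
            m["gc.median_read_gc"] = float(np.median(self.per_read_gc))
        if self.alignment is not None:
            for cat, n in self.alignment.read_counts.items():
                m[f"alignment.reads.{cat}"] = n
            for cat, n in self.alignment.base_counts.items():
                m[f"alignment.bases.{cat}"] = n
            m["alignment.duplicate_reads"] = self.alignment.duplicate_reads
            m["alignment.qc_fail_reads"] = self.alignment.qc_fail_reads
            m["alignment.mismatch_unresolved_reads"] = \
                self.alignment.mismatch_unresolved_reads
            add_basic("mapped", self.alignment.mapped_stats)
            add_basic("unmapped", self.alignment.unmapped_stats)
        if self.modification is not None:
            m["modification.threshold"] = self.modification.threshold
            m["modification.reads_with_calls"] = \
                self.modification.reads_with_calls
            for code, cs in sorted(self.modification.per_code.items()):
                p = f"modification.{code}"
                m[f"{p}.total_predictions"] = cs.total_predictions
                m[f"{p}.above_threshold"] = cs.above_threshold
                m[f"{p}.cpg_above_threshold_fwd"] = cs.cpg_above_threshold_fwd
                m[f"{p}.cpg_above_threshold_rev"] = cs.cpg_above_threshold_rev
        if self.tin_aggregates is not None:
            m["tin.n_transcripts_scored"] = len(self.tin_results or [])
            for key in ("mean", "median", "stdev"):
                m[f"tin.{key}"] = self.tin_aggregates[key]
        if self.rrms_accepted is not None:
            m["rrms.unclassified_reads"] = self.rrms_unclassified
            m["rrms.conflict_warnings"] = self.rrms_conflicts
            for side, sub in (("accepted", self.rrms_accepted),
                              ("rejected", self.rrms_rejected)):
                for key, value in sub.scalar_metrics().items():
                    if key in ("schema_version", "tool", "version",
                               "filetype"):
                        continue
                    m[f"rrms.{side}.{key}"] = value
        if self.signal_reads is not None:
            m["signal.n_reads"] = len(self.signal_reads)
            m["signal.total_samples"] = sum(r["n_samples"]
                                            for r in self.signal_reads)
        for flag in self.flags:
            m[f"flag.{flag.section}"] = flag.level
        return m


def evaluate_flags(bundle: ReportBundle,
                   thresholds: dict | None = None) -> list[QCFlag]:
    """Deterministic pass/warn flags per report section."""
    t = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        unknown = set(thresholds) - set(t)
        if unknown:
            raise ConfigError(f"unknown threshold keys: {sorted(unknown)}")
        t.update(thresholds)
    flags: list[QCFlag] = []

    if bundle.per_read_quality:
        med = float(np.median(bundle.per_read_quality))
        level = "warn" if med < t["median_read_quality_warn"] else "pass"
        flags.append(QCFlag("read_quality", level,
                            f"median read quality >= "
                            f"{t['median_read_quality_warn']}", round(med, 4)))
    if bundle.per_read_gc:
        med = float(np.median(bundle.per_read_gc))
        dev = abs(med - 50.0)
        level = "warn" if dev > t["gc_median_deviation_warn"] else "pass"
        flags.append(QCFlag("gc_content", level,
                            f"median GC within "
                            f"{t['gc_median_deviation_warn']} points of 50",
                            round(med, 4)))
    if bundle.alignment is not None:
        rc = bundle.alignment.read_counts
        total = (rc["primary_mapped"] + rc["secondary"]
                 + rc["supplementary"] + rc["unmapped"])
        frac = rc["unmapped"] / total if total else 0.0
        level = "warn" if frac > t["unmapped_fraction_warn"] else "pass"
        flags.append(QCFlag("mapping", level,
                            f"unmapped fraction <= "
                            f"{t['unmapped_fraction_warn']}", round(frac, 4)))
    if bundle.tin_aggregates is not None:
        med = bundle.tin_aggregates["median"]
        if med is None:
            flags.append(QCFlag("tin", "warn", "no transcript passed the "
                                "minimum coverage filter", None))
        else:
            level = "warn" if med < t["median_tin_warn"] else "pass"
            flags.append(QCFlag("tin", level,
                                f"median TIN >= {t['median_tin_warn']}",
                                round(med, 4)))
    if bundle.rrms_unclassified is not None:
        level = "warn" if bundle.rrms_unclassified else "pass"
        flags.append(QCFlag("rrms", level, "all QC-input reads classified "
                            "by the decision CSV", bundle.rrms_unclassified))
    bundle.flags = flags
    return flags


# ---------------------------------------------------------------------------
# serialization

def format_value(value) -> str:
    """Locale-independent formatting: ints plain, floats at 4 decimals."""
    if value is None:
        return "NA"
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, (int, np.integer)):
        return str(int(value))
    if isinstance(value, (float, np.floating)):
        return f"{float(value):.4f}"
    return str(value)


def write_summary_text(bundle: ReportBundle, path) -> None:
    """One metric per line, tab-separated key/value."""
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        for key, value in bundle.scalar_metrics().items():
            fh.write(f"{key}\t{format_value(value)}\n")


def parse_summary_text(path) -> dict[str, str]:
    out = {}
    with open(path, "rt", encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = value
    return out


# ---------------------------------------------------------------------------
# HTML rendering (self-contained, inline SVG)

_FLAG_BADGE = {"pass": "&#10003;", "warn": "&#9888;", "fail": "&#10007;"}


def _svg_histogram(hist: Histogram, title: str, width=640, height=220) -> str:
    counts = hist.counts
    if not counts or sum(counts) == 0:
        return f"<p>{html_mod.escape(title)}: no data</p>"
    peak = max(counts)
    n = len(counts)
    bar_w = max(1.0, (width - 60) / n)
    bars = []
    for i, c in enumerate(counts):
        h = 0 if peak == 0 else (height - 40) * c / peak
        x = 50 + i * bar_w
        y = height - 20 - h
        bars.append(f'<rect x="{x:.1f}" y="{y:.1f}" width="{bar_w:.1f}" '
                    f'height="{h:.1f}" fill="#4878a8"><title>'
                    f'[{hist.edges[i]:.3g}, {hist.edges[i + 1]:.3g}'
                    f'{"]" if i == n - 1 else ")"}: {c}</title></rect>')
    axis = (f'<text x="{width / 2:.0f}" y="14" text-anchor="middle" '
            f'font-size="13">{html_mod.escape(title)}'
            f'{" (log10 x)" if hist.log_scale_hint else ""}</text>'
            f'<line x1="50" y1="{height - 20}" x2="{width - 10}" '
            f'y2="{height - 20}" stroke="#333"/>'
            f'<text x="48" y="{height - 24}" text-anchor="end" '
            f'font-size="10">0</text>'
            f'<text x="48" y="30" text-anchor="end" font-size="10">{peak}'
            f'</text>'
            f'<text x="50" y="{height - 6}" font-size="10">'
            f'{hist.edges[0]:.4g}</text>'
            f'<text x="{width - 10}" y="{height - 6}" text-anchor="end" '
            f'font-size="10">{hist.edges[-1]:.4g}</text>')
    return (f'<svg viewBox="0 0 {width} {height}" width="{width}" '
            f'height="{height}" role="img">{axis}{"".join(bars)}</svg>')


def _table(rows: list[tuple[str, str]], caption: str = "") -> str:
    body = "".join(f"<tr><td>{html_mod.escape(k)}</td>"
                   f"<td>{html_mod.escape(v)}</td></tr>" for k, v in rows)
    cap = f"<caption>{html_mod.escape(caption)}</caption>" if caption else ""
    return f"<table>{cap}{body}</table>"


def _section(bundle: ReportBundle, title: str, prefix: str,
             metrics: dict[str, str]) -> str:
    flag = next((f for f in bundle.flags
                 if f.section == prefix), None)
    badge = ""
    if flag is not None:
        badge = (f' <span class="{flag.level}" title="'
                 f'{html_mod.escape(flag.rule)}">'
                 f'{_FLAG_BADGE[flag.level]} {flag.level}</span>')
    rows = [(k, v) for k, v in metrics.items()]
    return (f"<section><h2>{html_mod.escape(title)}{badge}</h2>"
            f"{_table(rows)}</section>")


def render_html(bundle: ReportBundle, path) -> None:
    """Render the bundle as a single self-contained HTML report.

    Every table value is taken from the same formatted scalar map the
    summary text writes, so the two outputs agree verbatim.
    """
    metrics = {k: format_value(v)
               for k, v in bundle.scalar_metrics().items()}
    groups: dict[str, dict[str, str]] = {}
    for key, value in metrics.items():
        group = key.split(".", 1)[0]
        groups.setdefault(group, {})[key] = value

    parts = [
        "<!DOCTYPE html><html><head><meta charset='utf-8'>",
        f"<title>longreadqc report ({html_mod.escape(bundle.filetype)})"
        "</title>",
        "<style>body{font-family:sans-serif;margin:2em;max-width:60em}"
        "table{border-collapse:collapse;margin:0.6em 0}"
        "td{border:1px solid #bbb;padding:2px 8px;font-size:13px}"
        ".pass{color:#2a7a2a}.warn{color:#b07000}.fail{color:#a02020}"
        "</style></head><body>",
        f"<h1>longreadqc {__version__} &mdash; "
        f"{html_mod.escape(bundle.filetype)} report</h1>",
    ]
    titles = {
        "basic": ("Basic statistics", "basic"),
        "quality": ("Read quality", "read_quality"),
        "gc": ("GC content", "gc_content"),
        "alignment": ("Read and base alignments", "mapping"),
        "mapped": ("Mapped read statistics", "mapping"),
        "unmapped": ("Unmapped read statistics", "mapping"),
        "modification": ("Base modifications", "modification"),
        "tin": ("Transcript integrity (TIN)", "tin"),
        "rrms": ("RRMS accepted/rejected partitions", "rrms"),
        "signal": ("Raw signal", "signal"),
        "parameter": ("Parameters", "parameters"),
    }
    order = ["basic", "quality", "gc", "alignment", "mapped", "unmapped",
             "modification", "tin", "rrms", "signal", "parameter"]
    for group in order:
        if group not in groups:
            continue
        title, flag_section = titles[group]
        parts.append(_section(bundle, title, flag_section, groups[group]))
    for name, hist in bundle.histograms.items():
        parts.append(_svg_histogram(hist, name))
    prov = {k: metrics[k] for k in ("tool", "version", "schema_version",
                                    "filetype")}
    parts.append(_section(bundle, "Provenance", "provenance", prov))
    parts.append("</body></html>")
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write("".join(parts))


# ---------------------------------------------------------------------------
# bundle builders (one per filetype pipeline)

def _bundle_from_accumulator(acc: ReadSetAccumulator, filetype: str,
                             length_log: bool = True) -> ReportBundle:
    bundle = ReportBundle(filetype=filetype, basic=acc.basic_stats())
    bundle.per_read_gc = acc.per_read_gc
    bundle.per_read_quality = acc.per_read_quality
    if acc.lengths:
        bundle.histograms["read length"] = build_histogram(acc.lengths, 100)
        if length_log and min(acc.lengths) > 0:
            bundle.histograms["read length (log10)"] = build_histogram(
                acc.lengths, 100, transform="log10")
    if acc.base_quality_counts.sum() > 0:
        top = int(np.max(np.nonzero(acc.base_quality_counts)[0])) + 1
        bundle.histograms["base quality"] = Histogram(
            edges=[i - 0.5 for i in range(top + 2)],
            counts=acc.base_quality_counts[:top + 1].astype(int).tolist())
    if acc.per_read_quality:
        bundle.histograms["read quality"] = build_histogram(
            acc.per_read_quality, 60)
    if acc.per_read_gc:
        bundle.histograms["per-read GC percent"] = gc_histogram(acc.per_read_gc)
    return bundle


def bundle_from_records(records, filetype: str) -> ReportBundle:
    """QC bundle from any SeqRecord/SummaryRow stream (fasta/fastq/seqtxt)."""
    acc = ReadSetAccumulator()
    for rec in records:
        acc.add(rec)
    return _bundle_from_accumulator(acc, filetype)


def bundle_from_alignment_summary(summary: AlignmentSummary,
                                  filetype: str = "bam") -> ReportBundle:
    combined = ReadSetAccumulator()
    for acc in (summary.mapped_acc, summary.unmapped_acc):
        combined.lengths.extend(acc.lengths)
        for b, n in acc.base_counts.items():
            combined.base_counts[b] += n
        combined.per_read_gc.extend(acc.per_read_gc)
        combined.per_read_quality.extend(acc.per_read_quality)
        combined.base_quality_counts += acc.base_quality_counts
    bundle = _bundle_from_accumulator(combined, filetype)
    bundle.alignment = summary
    return bundle
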