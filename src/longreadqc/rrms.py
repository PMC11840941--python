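"""Accepted/rejected read partitioning for adaptive-sampling (RRMS) runs.

ONT adaptive sampling ejects off-target molecules mid-pore; the run's
decision CSV records, per read, whether the read was kept
("stop_receiving") or unblocked. QC is run separately on each
partition, which makes enrichment effects (long accepted fragments vs
short rejected stubs) directly visible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .bamqc import AlignmentSummary, summarize_bam
from .errors import UnsupportedDialectError
from .readers import _open_text


@dataclass
class RRMSPartition:
    accepted_ids: set[str] = field(default_factory=set)
    rejected_ids: set[str] = field(default_factory=set)
    conflict_warnings: int = 0   # duplicate ids with conflicting decisions
    unclassified: int = 0        # QC-input reads absent from the CSV


DEFAULT_ACCEPTED_VALUES = frozenset({"stop_receiving"})


def parse_rrms_csv(path, id_column: str = "read_id",
                   decision_column: str = "decision",
                   accepted_values=DEFAULT_ACCEPTED_VALUES) -> RRMSPartition:
    """Split read ids by adaptive-sampling decision.

    Rows whose decision is in ``accepted_values`` are accepted; every
    other classified row is rejected. Duplicate ids resolve last-wins,
    with conflicting duplicates counted as warnings.
    """
    part = RRMSPartition()
    with _open_text(path) as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        if id_column not in header or decision_column not in header:
            raise UnsupportedDialectError(
                f"RRMS CSV lacks required columns {id_column!r}/"
                f"{decision_column!r}; found: {header}", line=1)
        for row in reader:
            rid = row[id_column]
            accepted = row[decision_column] in accepted_values
            if accepted:
                if rid in part.rejected_ids:
                    part.rejected_ids.discard(rid)
                    part.conflict_warnings += 1
                part.accepted_ids.add(rid)
            else:
                if rid in part.accepted_ids:
                    part.accepted_ids.discard(rid)
                    part.conflict_warnings += 1
                part.rejected_ids.add(rid)
    return part


def split_and_summarize(bam_path, partition: RRMSPartition,
                        ) -> tuple[AlignmentSummary, AlignmentSummary]:
    """Full alignment QC on each partition of a BAM.

    Reads absent from the CSV are excluded from both summaries and
    counted in ``partition.unclassified`` (surfaced as a QC flag).
    """
    accepted = summarize_bam(
        bam_path, read_filter=lambda rid: rid in partition.accepted_ids)
    rejected = summarize_bam(
        bam_path, read_filter=lambda rid: rid in partition.rejected_ids)
    everything = summarize_bam(bam_path, collect_read_ids=True)
    classified = partition.accepted_ids | partition.rejected_ids
    partition.unclassified = sum(
        1 for rid in everything.read_ids if rid not in classified)
    return accepted, rejected
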