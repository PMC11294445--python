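"""Read hygiene before assembly polishing.

Two operations: removal of duplicated reads (an artifact of the sequencing
software) and a divergence filter on read-to-reference alignments.  The
divergence statistic is the *gap-compressed mismatch ratio*

    r = (mismatches + gap_opens) / (matches + mismatches + gap_opens)

where each insertion or deletion *run* counts as a single event regardless
of its length, mirroring the gap-compressed per-base divergence convention
of modern long/short-read aligners.  Reads with r exceeding the threshold
(default 0.04) are removed; the boundary value itself is retained because
the rule is strictly "exceeding".

When an alignment does not resolve mismatches explicitly (plain ``M`` CIGAR
runs) the mismatch count is inferred from the NM-style edit distance as
``NM - inserted_bases - deleted_bases``.  Records where neither route is
available are *divergence-indeterminate* and are dropped with a warning
rather than assumed perfect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

logger = logging.getLogger(__name__)

#: CIGAR-style operation codes used in event runs.
MATCH, MISMATCH, INS, DEL, ALN_MATCH = "=", "X", "I", "D", "M"
_VALID_OPS = {MATCH, MISMATCH, INS, DEL, ALN_MATCH}


class DivergenceIndeterminate(ValueError):
    """Raised when a record carries no usable mismatch evidence."""


class InconsistentRecordError(ValueError):
    """Edit distance disagrees with the gap structure (negative mismatches)."""


@dataclass
class AlignmentRecord:
    """One read-vs-reference alignment, reduced to its event runs.

    ``event_runs`` is an ordered list of (op, length) with op one of
    ``= X I D M``; ``edit_distance`` follows the NM convention
    (mismatches + inserted bases + deleted bases).
    """

    read_id: str
    target_id: str
    event_runs: list[tuple[str, int]] = field(default_factory=list)
    edit_distance: Optional[int] = None
    mapped: bool = True
    is_primary: bool = True

    def __post_init__(self) -> None:
        for op, length in self.event_runs:
            if op not in _VALID_OPS:
                raise ValueError(f"record {self.read_id!r}: bad op {op!r}")
            if length < 1:
                raise ValueError(f"record {self.read_id!r}: run length {length} < 1")

    def op_total(self, op: str) -> int:
        return sum(n for o, n in self.event_runs if o == op)

    def n_runs(self, op: str) -> int:
        return sum(1 for o, _ in self.event_runs if o == op)

    @property
    def determinate(self) -> bool:
        """True if a gap-compressed divergence can be computed."""
        if not self.mapped or not self.event_runs:
            return False
        if any(o == ALN_MATCH for o, _ in self.event_runs):
            return self.edit_distance is not None
        return True


@dataclass
class FilterReport:
    """Bookkeeping for one filtering pass; counts reconcile to n_input."""

    threshold: float
    n_input: int = 0
    n_duplicates_removed: int = 0
    n_unmapped: int = 0
    n_indeterminate: int = 0
    n_failed_threshold: int = 0
    n_retained: int = 0

    def check(self) -> None:
        total = (
            self.n_duplicates_removed
            + self.n_unmapped
            + self.n_indeterminate
            + self.n_failed_threshold
            + self.n_retained
        )
        if total != self.n_input:
            raise AssertionError(f"filter report does not reconcile: {self}")


def dedup_reads(records: Sequence, key: str = "id"):
    """Drop later records whose key (id or sequence) repeats an earlier one.

    Accepts any records exposing ``.id`` and ``.sequence`` attributes, or
    (id, sequence) tuples.  First occurrence wins; order is preserved.
    """
    if key not in ("id", "sequence"):
        raise ValueError(f"dedup key must be 'id' or 'sequence', got {key!r}")
    seen: set = set()
    retained = []
    removed = 0
    for rec in records:
        if isinstance(rec, tuple):
            rid, seq = rec[0], rec[1]
        else:
            rid, seq = rec.id, getattr(rec, "sequence", None) or str(rec.seq)
        k = rid if key == "id" else seq
        if k in seen:
            removed += 1
        else:
            seen.add(k)
            retained.append(rec)
    return retained, removed


def gap_compressed_divergence(record: AlignmentRecord) -> float:
    """Gap-compressed mismatch ratio of one mapped, determinate record."""
    if not record.mapped:
        raise DivergenceIndeterminate(f"read {record.read_id!r} is unmapped")
    if not record.determinate:
        raise DivergenceIndeterminate(
            f"read {record.read_id!r}: no mismatch evidence (no X runs, no edit distance)"
        )
    gap_opens = record.n_runs(INS) + record.n_runs(DEL)
    ins_bases = record.op_total(INS)
    del_bases = record.op_total(DEL)
    n_m = record.op_total(ALN_MATCH)
    n_eq = record.op_total(MATCH)
    n_x = record.op_total(MISMATCH)
    matches = n_m + n_eq
    mismatches = n_x
    if record.edit_distance is not None:
        # mismatches not resolved in the runs are recovered from NM; match-run
        # columns all stay in the denominator (NM-inference convention)
        inferred = record.edit_distance - ins_bases - del_bases - n_x
        if inferred < 0:
            raise InconsistentRecordError(
                f"read {record.read_id!r}: NM={record.edit_distance} implies "
                f"negative mismatches"
            )
        mismatches += inferred
    denom = matches + mismatches + gap_opens
    if denom == 0:
        raise DivergenceIndeterminate(f"read {record.read_id!r}: empty alignment")
    return (mismatches + gap_opens) / denom


def filter_by_divergence(
    records: Iterable[AlignmentRecord],
    threshold: float = 0.04,
) -> tuple[list[AlignmentRecord], FilterReport]:
    """Retain primary mapped records whose divergence does not exceed threshold.

    Unmapped and indeterminate records are excluded from the retained list
    and counted separately; secondary/supplementary lines are ignored
    entirely (a read is judged by its primary alignment only).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    report = FilterReport(threshold=threshold)
    retained: list[AlignmentRecord] = []
    for rec in records:
        if not rec.is_primary:
            continue
        report.n_input += 1
        if not rec.mapped:
            report.n_unmapped += 1
            continue
        try:
            r = gap_compressed_divergence(rec)
        except DivergenceIndeterminate:
            logger.warning("read %s: divergence indeterminate, dropped", rec.read_id)
            report.n_indeterminate += 1
            continue
        if r > threshold:
            report.n_failed_threshold += 1
        else:
            report.n_retained += 1
            retained.append(rec)
    report.check()
    return retained, report
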