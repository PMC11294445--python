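"""Per-column Shannon entropy of protein alignments and variability summaries.

For a column with residue frequencies p_a over the 20 amino acids,
H = -sum_a p_a log2(p_a), in bits.  Gaps and X are excluded from the
frequencies; a column with fewer than ``min_coverage`` (default 2) scoring
residues has undefined entropy and is never called variable, which keeps
indel-rich columns from being scored off a single residue.

A column is a *variable site* when its entropy exceeds a configurable
threshold, default 0 bits — i.e. at least two distinct residues observed.
Class-wise summaries report per-class orthogroup counts, median variable-
site counts (even-count medians are means of the two central order
statistics, so half-integers like 13.5 are representable), a shared
histogram, and the number of zero-variable orthogroups, which are excluded
from the histogram but counted separately.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = set(AMINO_ACIDS)
MAX_ENTROPY_BITS = math.log2(20)
DEFAULT_MIN_COVERAGE = 2


@dataclass
class EntropyProfile:
    og_id: str
    column_entropies: list[Optional[float]]
    column_coverage: list[int]
    variable_flags: list[bool]
    alignment_length: int

    @property
    def n_variable(self) -> int:
        return sum(self.variable_flags)

    @property
    def fraction_variable(self) -> float:
        return self.n_variable / self.alignment_length


@dataclass
class VariabilitySummary:
    class_counts: dict[str, int]
    class_medians: dict[str, float]
    histogram: list[tuple[int, str, int]]  # (n_variable bin, class, orthogroup count)
    n_zero_variable: int


def _rows(alignment) -> list[str]:
    if isinstance(alignment, Mapping):
        return [alignment[k] for k in alignment]
    return list(alignment)


def column_entropy(column: Iterable[str], min_coverage: int = DEFAULT_MIN_COVERAGE) -> Optional[float]:
    """Shannon entropy (bits) of one alignment column; None when undefined."""
    counts: dict[str, int] = {}
    n = 0
    total = 0
    for aa in column:
        total += 1
        aa = aa.upper()
        if aa in _AA_SET:
            counts[aa] = counts.get(aa, 0) + 1
            n += 1
    if total == 0:
        raise ValueError("empty column")
    if n < min_coverage:
        return None
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h


def entropy_profile(
    alignment,
    og_id: str = "",
    variable_threshold: float = 0.0,
    min_coverage: int = DEFAULT_MIN_COVERAGE,
) -> EntropyProfile:
    """Column entropies and variable-site flags for one rectangular alignment."""
    rows = _rows(alignment)
    if not rows:
        raise ValueError("alignment has no rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged alignment: rows differ in length")
    entropies: list[Optional[float]] = []
    coverage: list[int] = []
    flags: list[bool] = []
    for j in range(width):
        col = [r[j] for r in rows]
        cov = sum(1 for aa in col if aa.upper() in _AA_SET)
        h = column_entropy(col, min_coverage=min_coverage)
        entropies.append(h)
        coverage.append(cov)
        flags.append(h is not None and h > variable_threshold)
    return EntropyProfile(
        og_id=og_id,
        column_entropies=entropies,
        column_coverage=coverage,
        variable_flags=flags,
        alignment_length=width,
    )


def summarize_variability(
    profiles: Sequence[EntropyProfile],
    orthogroup_classes: Mapping[str, str],
) -> VariabilitySummary:
    """Class-wise variable-site summary over many orthogroup profiles.

    ``orthogroup_classes`` maps og_id to its class label; an "all" class
    aggregating every orthogroup is always included.  Zero-variable
    orthogroups are excluded from the histogram but reported in
    ``n_zero_variable``.
    """
    if not profiles:
        raise ValueError("no entropy profiles supplied")
    per_class: dict[str, list[int]] = {"all": []}
    for p in profiles:
        klass = orthogroup_classes.get(p.og_id)
        if klass is None:
            raise KeyError(f"orthogroup {p.og_id!r} has no class label")
        per_class.setdefault(klass, []).append(p.n_variable)
        per_class["all"].append(p.n_variable)
    class_counts = {k: len(v) for k, v in per_class.items()}
    class_medians = {k: float(np.median(v)) for k, v in per_class.items() if v}
    histogram: list[tuple[int, str, int]] = []
    for klass in sorted(per_class):
        nonzero = [n for n in per_class[klass] if n > 0]
        if not nonzero:
            continue
        bins: dict[int, int] = {}
        for n in nonzero:
            bins[n] = bins.get(n, 0) + 1
        for n in sorted(bins):
            histogram.append((n, klass, bins[n]))
    n_zero = sum(1 for p in profiles if p.n_variable == 0)
    return VariabilitySummary(
        class_counts=class_counts,
        class_medians=class_medians,
        histogram=histogram,
        n_zero_variable=n_zero,
    )


def effector_report(
    profiles: Sequence[EntropyProfile],
    name_patterns: Sequence[str],
    names: Optional[Mapping[str, str]] = None,
) -> list[dict]:
    """Variable-site table for orthogroups whose name matches any pattern.

    ``names`` maps og_id to an annotation label; when absent the og_id
    itself is matched.  Percentages are over the full alignment length
    (gap-containing columns included) and rounded to the nearest integer
    percent.
    """
    regexes = [re.compile(p, re.IGNORECASE) for p in name_patterns]
    table = []
    for p in profiles:
        label = names.get(p.og_id, p.og_id) if names is not None else p.og_id
        if any(rx.search(label) for rx in regexes):
            table.append(
                {
                    "og_id": p.og_id,
                    "name": label,
                    "n_variable": p.n_variable,
                    "alignment_length": p.alignment_length,
                    "percent_variable": int(round(100.0 * p.fraction_variable)),
                }
            )
    if not table:
        logger.warning("no orthogroup matched patterns %r", list(name_patterns))
    return sorted(table, key=lambda row: row["og_id"])
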