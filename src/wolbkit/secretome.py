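"""Secretome classification from signal-peptide and transmembrane evidence.

The classification rule itself is simple and total: a protein with a signal
peptide and at least one transmembrane segment (outside the signal region)
is *membrane-bound*; with a signal peptide but no such segment it is
*secreted*; anything without a signal peptide is *other*.

Evidence can come from external predictor tables (the fidelity path, see
:func:`wolbkit.io_formats.read_predictor_tables`) or from built-in
hydropathy heuristics over the Kyte–Doolittle scale.  The heuristics are a
deliberately transparent stand-in for dedicated neural/HMM predictors:

* signal peptide: a positively charged residue within the first five
  positions, followed by a run of at least 7 consecutive positions (within
  the first 25) whose 7-residue mean hydropathy exceeds 1.6; the cleavage
  site is the first small residue (A, G, S) at positions 18–35;
* transmembrane segment: a maximal run of at least 15 consecutive positions
  whose 19-residue mean hydropathy exceeds 1.6; runs separated by fewer
  than 5 residues are merged, and runs overlapping the signal-peptide
  region are discarded (signal peptides are themselves hydrophobic and
  would otherwise promote every secreted protein to membrane-bound).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

logger = logging.getLogger(__name__)

MEMBRANE = "membrane-bound"
SECRETED = "secreted"
OTHER = "other"
CLASSES = (MEMBRANE, SECRETED, OTHER)

#: Kyte–Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}

HYDROPATHY_THRESHOLD = 1.6
SP_SEARCH_END = 25          # hydrophobic core must sit within the first 25 residues
SP_MIN_RUN = 7
SP_CHARGE_WINDOW = 5        # positive charge required within positions 1-5
TM_WINDOW = 19
TM_MIN_RUN = 15
TM_MERGE_GAP = 5
CLEAVAGE_RANGE = (17, 35)   # 0-based half-open bounds for the cleavage search


@dataclass
class ProteinClassification:
    gene_id: str
    has_signal_peptide: bool
    tm_segments: list[tuple[int, int]] = field(default_factory=list)
    cleavage_position: Optional[int] = None
    klass: str = OTHER
    evidence_source: str = "builtin-heuristic"

    def __post_init__(self) -> None:
        if self.klass not in CLASSES:
            raise ValueError(f"unknown class {self.klass!r}")


def hydropathy_profile(protein: str, window: int = TM_WINDOW) -> np.ndarray:
    """Centered moving average of Kyte–Doolittle hydropathy.

    Positions near the ends are averaged over the truncated window that
    fits; unknown residues contribute 0 (with a warning).
    """
    if len(protein) < window:
        raise ValueError(f"sequence length {len(protein)} < window {window}")
    values = np.empty(len(protein))
    for i, aa in enumerate(protein.upper()):
        if aa not in KYTE_DOOLITTLE:
            logger.warning("unknown residue %r treated as hydropathy 0", aa)
        values[i] = KYTE_DOOLITTLE.get(aa, 0.0)
    half = window // 2
    out = np.empty(len(protein))
    cumsum = np.concatenate([[0.0], np.cumsum(values)])
    for i in range(len(protein)):
        lo = max(0, i - half)
        hi = min(len(protein), i + half + 1)
        out[i] = (cumsum[hi] - cumsum[lo]) / (hi - lo)
    return out


def predict_signal_peptide(protein: str) -> tuple[bool, Optional[int]]:
    """Built-in signal-peptide heuristic; returns (flag, cleavage position).

    Sequences shorter than 25 residues are called negative (too short to
    carry the full feature).
    """
    if len(protein) < SP_SEARCH_END:
        logger.info("sequence too short for signal-peptide prediction")
        return False, None
    prot = protein.upper()
    if not any(aa in "KR" for aa in prot[:SP_CHARGE_WINDOW]):
        return False, None
    profile = hydropathy_profile(prot, window=7)
    run_start = None
    best_run: Optional[tuple[int, int]] = None
    for i in range(2, SP_SEARCH_END):
        if profile[i] > HYDROPATHY_THRESHOLD:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= SP_MIN_RUN:
                best_run = (run_start, i)
            run_start = None
    if run_start is not None and SP_SEARCH_END - run_start >= SP_MIN_RUN:
        best_run = (run_start, SP_SEARCH_END)
    if best_run is None:
        return False, None
    lo = max(CLEAVAGE_RANGE[0], best_run[1])
    cleavage = None
    for i in range(lo, min(CLEAVAGE_RANGE[1], len(prot))):
        if prot[i] in "AGS":
            cleavage = i
            break
    if cleavage is None:
        cleavage = min(best_run[1] + 3, len(prot))
    return True, cleavage


def predict_tm_segments(
    protein: str,
    exclude_region: Optional[tuple[int, int]] = None,
) -> list[tuple[int, int]]:
    """Built-in transmembrane-segment heuristic (0-based half-open intervals)."""
    prot = protein.upper()
    if len(prot) < TM_WINDOW:
        return []
    profile = hydropathy_profile(prot, window=TM_WINDOW)
    above = profile > HYDROPATHY_THRESHOLD
    runs: list[tuple[int, int]] = []
    start = None
    for i, flag in enumerate(above):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(prot)))
    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged and run[0] - merged[-1][1] < TM_MERGE_GAP:
            merged[-1] = (merged[-1][0], run[1])
        else:
            merged.append(run)
    segments = [r for r in merged if r[1] - r[0] >= TM_MIN_RUN]
    if exclude_region is not None:
        lo, hi = exclude_region
        segments = [s for s in segments if s[1] <= lo or s[0] >= hi]
    return segments


def classify_protein(sp_flag: bool, tm_segments) -> str:
    """The classification rule: (SP, >=1 TM) -> membrane-bound; (SP, 0) ->
    secreted; no SP -> other.  ``tm_segments`` may be a count or a list."""
    n_tm = tm_segments if isinstance(tm_segments, int) else len(tm_segments)
    if n_tm < 0:
        raise ValueError("negative transmembrane segment count")
    if sp_flag:
        return MEMBRANE if n_tm >= 1 else SECRETED
    return OTHER


def classify_sequence(
    gene_id: str,
    protein: str,
    external: Optional[tuple[bool, int]] = None,
) -> ProteinClassification:
    """Classify one protein, preferring external predictor evidence when given."""
    if external is not None:
        sp_flag, n_tm = external
        return ProteinClassification(
            gene_id=gene_id,
            has_signal_peptide=sp_flag,
            # external tables report counts, not coordinates
            tm_segments=[(-1, -1)] * n_tm,
            klass=classify_protein(sp_flag, n_tm),
            evidence_source="external-table",
        )
    sp_flag, cleavage = predict_signal_peptide(protein)
    exclude = (0, cleavage) if sp_flag and cleavage is not None else None
    segments = predict_tm_segments(protein, exclude_region=exclude)
    return ProteinClassification(
        gene_id=gene_id,
        has_signal_peptide=sp_flag,
        tm_segments=segments,
        cleavage_position=cleavage,
        klass=classify_protein(sp_flag, segments),
        evidence_source="builtin-heuristic",
    )


def classify_orthogroup(member_classes: Iterable[str]) -> tuple[str, dict[str, int]]:
    """Majority vote over member classes; ties broken membrane > secreted > other."""
    tally = {c: 0 for c in CLASSES}
    n = 0
    for c in member_classes:
        if c not in tally:
            raise ValueError(f"unknown class {c!r}")
        tally[c] += 1
        n += 1
    if n == 0:
        raise ValueError("orthogroup has no member classifications")
    best = max(CLASSES, key=lambda c: (tally[c], -CLASSES.index(c)))
    return best, tally
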