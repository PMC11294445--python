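"""Length, GC content and windowed GC / GC-skew profiles of circular genomes.

GC skew per window is (G - C) / (G + C).  Profiles can optionally be
expressed as the deviation from the genome-wide average of the metric, the
form commonly drawn as the inner circle of bacterial genome maps.  All
coordinates are 0-based half-open; circular genomes wrap past the end.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

_NUC_UNAMBIGUOUS = set("ACGT")
_NUC_AMBIGUOUS = set("RYSWKMBDHVN")


class UndefinedValueError(ValueError):
    """A metric has no defined value (e.g. GC of a sequence with no ACGT)."""


@dataclass(frozen=True)
class GenomeRecord:
    """A (possibly circular) nucleotide sequence belonging to one strain."""

    strain_id: str
    sequence: str
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.strain_id!r}: empty sequence")
        bad = set(self.sequence.upper()) - _NUC_UNAMBIGUOUS - _NUC_AMBIGUOUS
        if bad:
            raise ValueError(
                f"genome {self.strain_id!r}: non-IUPAC characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class WindowTrack:
    """Windowed metric values over one sequence.

    ``windows`` holds (start, end, value) with ``end`` possibly exceeding the
    genome length for wrap-around windows on circular genomes; ``value`` is
    ``None`` where the metric is undefined (e.g. a window with no G or C).
    """

    seq_id: str
    metric: str
    window_size: int
    step: int
    seq_length: int = 0
    windows: list[tuple[int, int, Optional[float]]] = field(default_factory=list)
    genome_mean: Optional[float] = None
    deviation: bool = False


def gc_content(sequence: str) -> float:
    """Fraction (G+C)/(A+C+G+T); IUPAC ambiguity codes are excluded entirely."""
    s = sequence.upper()
    g = s.count("G")
    c = s.count("C")
    denom = g + c + s.count("A") + s.count("T")
    if denom == 0:
        raise UndefinedValueError("no unambiguous bases: GC content undefined")
    return (g + c) / denom


def gc_skew(sequence: str) -> float:
    """(G - C) / (G + C) of the sequence."""
    s = sequence.upper()
    g = s.count("G")
    c = s.count("C")
    if g + c == 0:
        raise UndefinedValueError("no G or C: skew undefined")
    return (g - c) / (g + c)


def _window_value(seq: str, metric: str) -> Optional[float]:
    try:
        return gc_content(seq) if metric == "gc_content" else gc_skew(seq)
    except UndefinedValueError:
        return None


def windowed_profile(
    genome: GenomeRecord,
    metric: str = "gc_skew",
    window: int = 10_000,
    step: int = 1_000,
    circular: Optional[bool] = None,
    deviation: bool = False,
) -> WindowTrack:
    """Sliding-window GC or skew profile.

    With ``deviation=True`` the genome-wide value of the metric is subtracted
    from every window and stored in ``genome_mean``.  On circular sequences
    windows wrap past the origin of the coordinate system; on linear ones the
    trailing partial windows are truncated.
    """
    if metric not in ("gc_content", "gc_skew"):
        raise ValueError(f"unknown metric {metric!r}")
    n = len(genome)
    if not 1 <= window <= n:
        raise ValueError(f"window must be in [1, {n}], got {window}")
    if not 1 <= step <= window:
        raise ValueError(f"step must be in [1, window], got {step}")
    circ = genome.circular if circular is None else circular

    seq = genome.sequence.upper()
    mean = _window_value(seq, metric)
    track = WindowTrack(
        seq_id=genome.strain_id,
        metric=metric,
        window_size=window,
        step=step,
        seq_length=n,
        genome_mean=mean if deviation else None,
        deviation=deviation,
    )
    doubled = seq + seq if circ else seq
    for start in range(0, n, step):
        end = start + window
        if not circ and end > n:
            break
        value = _window_value(doubled[start:end], metric)
        if deviation and value is not None and mean is not None:
            value -= mean
        track.windows.append((start, end, value))
    return track


def skew_sign_changes(track: WindowTrack) -> list[int]:
    """Boundaries (bp) where consecutive window values change sign.

    Used to localize the replication-origin flip of a planted or real skew
    profile; undefined windows are skipped.  On deviation tracks the sign is
    taken after mean subtraction.  The reported coordinate is the midpoint
    between the two window centers, modulo genome length for circular wraps.
    """
    vals = [(s, e, v) for s, e, v in track.windows if v is not None and v != 0.0]
    length = track.seq_length
    changes = []
    for (s1, e1, v1), (s2, e2, v2) in zip(vals, vals[1:] + vals[:1]):
        if np.sign(v1) != np.sign(v2):
            c1 = (s1 + e1) / 2
            c2 = (s2 + e2) / 2
            if c2 < c1 and length:  # circular wrap pair
                c2 += length
            mid = int(round((c1 + c2) / 2))
            changes.append(mid % length if length else mid)
    return changes


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (so 35.225 -> 35.23, not banker's 35.22)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


def genome_summary(genome: GenomeRecord) -> dict:
    """Length, GC% (2 decimals, half-up), base counts and circularity flag."""
    s = genome.sequence.upper()
    counts = {b: s.count(b) for b in "ACGT"}
    n_ambiguous = len(s) - sum(counts.values())
    summary = {
        "strain_id": genome.strain_id,
        "length_bp": len(s),
        "gc_percent": round_half_up(100.0 * gc_content(s), 2),
        "n_A": counts["A"],
        "n_C": counts["C"],
        "n_G": counts["G"],
        "n_T": counts["T"],
        "n_ambiguous": n_ambiguous,
        "circular": genome.circular,
    }
    return summary
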