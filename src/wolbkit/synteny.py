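"""k-mer anchor dotplots, collinear-block chaining and breakpoint reports.

A desk-scale stand-in for whole-genome aligners: anchors are maximal runs
of exact shared k-mers (both strands of genome b; repetitive k-mers are
capped), blocks are greedy chains of strand-consistent, monotone anchors,
and breakpoints are the junctions between adjacent blocks where collinear
continuation fails.  Circularity is handled at the junction stage: the
wrap junction between the last and first block of a circular genome is
only a breakpoint if strand or collinearity breaks there, so a block
artificially split at the coordinate origin does not surface as a
rearrangement.

Coordinates are 0-based half-open; anchors on the reverse strand report
forward-strand coordinates of the reverse-complemented interval in b.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import pandas as pd

from .genome_stats import GenomeRecord

DEFAULT_K = 15
DEFAULT_MAX_OCCURRENCE = 4
DEFAULT_MAX_GAP = 5_000
DEFAULT_MIN_ANCHORS = 3
DEFAULT_MIN_SPAN = 200

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Anchor:
    pos_a: int
    pos_b: int
    length: int
    strand: str  # '+' or '-'

    @property
    def end_a(self) -> int:
        return self.pos_a + self.length

    @property
    def end_b(self) -> int:
        return self.pos_b + self.length


@dataclass
class SyntenyBlock:
    interval_a: tuple[int, int]
    interval_b: tuple[int, int]
    strand: str
    n_anchors: int
    anchored_bp: int = 0  # total exact-match bases supporting the block


def _seq(genome: Union[str, GenomeRecord]) -> str:
    return (genome.sequence if isinstance(genome, GenomeRecord) else genome).upper()


def kmer_anchors(
    genome_a: Union[str, GenomeRecord],
    genome_b: Union[str, GenomeRecord],
    k: int = DEFAULT_K,
    max_occurrence: int = DEFAULT_MAX_OCCURRENCE,
    min_anchor_length: Optional[int] = None,
) -> list[Anchor]:
    """Maximal exact shared k-mer runs between two genomes.

    k-mers occurring more than ``max_occurrence`` times on the forward
    strand of either genome are discarded before seeding, which keeps
    repeat families (IS elements and the like) from blowing up the anchor
    set while leaving the unique backbone intact.  Merged runs shorter
    than ``min_anchor_length`` (default k+5) are dropped: an isolated
    k-mer hit between megabase-scale genomes is overwhelmingly a chance
    match, while genuine homology extends well past k.
    """
    if min_anchor_length is None:
        min_anchor_length = k + 5
    a, b = _seq(genome_a), _seq(genome_b)
    if len(a) < k or len(b) < k:
        raise ValueError(f"both genomes must be at least k={k} long")

    counts_a: dict[str, int] = {}
    for i in range(len(a) - k + 1):
        km = a[i:i + k]
        counts_a[km] = counts_a.get(km, 0) + 1
    index_b: dict[str, list[int]] = {}
    for j in range(len(b) - k + 1):
        km = b[j:j + k]
        index_b.setdefault(km, []).append(j)

    # seeds grouped by diagonal so maximal runs merge in one pass
    fwd: dict[int, list[int]] = {}   # diag = pb - pa -> [pa]
    rev: dict[int, list[int]] = {}   # antidiag = pb + pa -> [pa]
    for pa in range(len(a) - k + 1):
        km = a[pa:pa + k]
        if counts_a[km] > max_occurrence:
            continue
        hits = index_b.get(km)
        if hits is not None and len(hits) <= max_occurrence:
            for pb in hits:
                fwd.setdefault(pb - pa, []).append(pa)
        rc = revcomp(km)
        hits = index_b.get(rc)
        if hits is not None and len(hits) <= max_occurrence:
            for pb in hits:
                rev.setdefault(pb + pa, []).append(pa)

    anchors: list[Anchor] = []
    for diag, pas in fwd.items():
        for start, run in _consecutive_runs(pas):
            if run + k - 1 >= min_anchor_length:
                anchors.append(Anchor(pos_a=start, pos_b=start + diag,
                                      length=run + k - 1, strand="+"))
    for antidiag, pas in rev.items():
        for start, run in _consecutive_runs(pas):
            if run + k - 1 < min_anchor_length:
                continue
            # pb decreases as pa increases; the b interval starts at the last seed
            last_pa = start + run - 1
            anchors.append(Anchor(pos_a=start, pos_b=antidiag - last_pa,
                                  length=run + k - 1, strand="-"))
    anchors.sort(key=lambda x: (x.pos_a, x.pos_b, x.strand))
    return anchors


def _consecutive_runs(positions: list[int]):
    positions = sorted(set(positions))
    start = positions[0]
    prev = start
    for p in positions[1:]:
        if p != prev + 1:
            yield start, prev - start + 1
            start = p
        prev = p
    yield start, prev - start + 1


def chain_anchors(
    anchors: Sequence[Anchor],
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    min_span: int = DEFAULT_MIN_SPAN,
) -> list[SyntenyBlock]:
    """Greedy chaining of monotone, strand-consistent anchors into blocks.

    Anchors are processed in genome-a order.  Several chains stay open at
    once, so short spurious anchors (e.g. reverse-palindrome hits inside a
    collinear region) form their own chains instead of interrupting a real
    one.  An anchor joins the open chain whose tail it extends — same
    strand, both coordinates strictly monotone (decreasing in b on the
    minus strand), inter-anchor gaps at most ``max_gap`` in both genomes —
    preferring the chain ending closest to it; otherwise it opens a new
    chain.  Chains with fewer than ``min_anchors`` anchors are dropped
    unless they span at least ``min_span`` bp in genome a: a single long
    exact anchor (the usual outcome between near-identical genomes, where
    maximal-run merging collapses whole collinear regions into one anchor)
    is kept as a block, while isolated short spurious anchors are not.
    Output order and content do not depend on input order.
    """
    ordered = sorted(anchors, key=lambda x: (x.pos_a, x.pos_b, x.strand))
    chains: list[list[Anchor]] = []
    overlap = 50  # exact anchors can overrun a junction by chance matches
    for anc in ordered:
        best: Optional[list[Anchor]] = None
        for chain in chains:
            last = chain[-1]
            ok = anc.strand == last.strand and anc.pos_a > last.pos_a
            ok = ok and -overlap <= anc.pos_a - last.end_a <= max_gap
            if anc.strand == "+":
                ok = ok and anc.pos_b > last.pos_b
                ok = ok and -overlap <= anc.pos_b - last.end_b <= max_gap
            else:
                ok = ok and anc.pos_b < last.pos_b
                ok = ok and -overlap <= last.pos_b - anc.end_b <= max_gap
            if ok and (best is None or last.end_a > best[-1].end_a):
                best = chain
        if best is None:
            chains.append([anc])
        else:
            best.append(anc)

    blocks: list[SyntenyBlock] = []
    for chain in chains:
        anchored = sum(anc.length for anc in chain)
        if len(chain) < min_anchors and anchored < min_span:
            continue
        first, last = chain[0], chain[-1]
        if first.strand == "+":
            interval_b = (first.pos_b, last.end_b)
        else:
            interval_b = (last.pos_b, first.end_b)
        blocks.append(SyntenyBlock(
            interval_a=(first.pos_a, last.end_a),
            interval_b=interval_b,
            strand=first.strand,
            n_anchors=len(chain),
            anchored_bp=anchored,
        ))
    blocks.sort(key=lambda blk: blk.interval_a)
    return blocks


def select_primary_blocks(
    blocks: Sequence[SyntenyBlock],
    overlap_tolerance: int = 50,
) -> list[SyntenyBlock]:
    """Greedy non-overlapping block selection for breakpoint analysis.

    Mosaic genomes yield overlapping blocks where repeated or relocated
    material maps to several places; breakpoints are only meaningful over a
    one-to-one tiling, so blocks are taken in decreasing order of anchored
    bases and any block overlapping an already-selected one in genome a
    (beyond ``overlap_tolerance``) is discarded.
    """
    chosen: list[SyntenyBlock] = []
    for blk in sorted(blocks, key=lambda b: (-b.anchored_bp, b.interval_a)):
        ok = all(
            blk.interval_a[0] >= other.interval_a[1] - overlap_tolerance
            or blk.interval_a[1] <= other.interval_a[0] + overlap_tolerance
            for other in chosen
        )
        if ok:
            chosen.append(blk)
    chosen.sort(key=lambda b: b.interval_a)
    return chosen


def breakpoint_report(
    blocks: Sequence[SyntenyBlock],
    genome_lengths: tuple[int, int],
    collinear_tolerance: int = DEFAULT_MAX_GAP,
    overlap_tolerance: int = 50,
) -> list[dict]:
    """Junctions between adjacent blocks that are not collinear continuations.

    Adjacency is circular (last block pairs with the first across the
    origin).  A junction counts as a breakpoint when the strand changes or
    when the b-coordinates do not continue within ``collinear_tolerance``
    (modulo genome-b length).  Rows report the a-coordinate of the
    junction, the flanking block indices and a strand-change flag, in
    genome-a order.
    """
    ordered = sorted(blocks, key=lambda blk: blk.interval_a)
    for left, right in zip(ordered, ordered[1:]):
        # anchors can overrun a true junction by a few chance matches, so
        # small overlaps are jitter, not misuse
        if right.interval_a[0] < left.interval_a[1] - overlap_tolerance:
            raise ValueError("blocks overlap in genome a")
    if len(ordered) < 2:
        return []
    len_b = genome_lengths[1]
    rows: list[dict] = []
    pairs = list(zip(ordered, ordered[1:])) + [(ordered[-1], ordered[0])]
    for idx, (left, right) in enumerate(pairs):
        strand_change = left.strand != right.strand
        collinear = False
        if not strand_change:
            if left.strand == "+":
                gap = (right.interval_b[0] - left.interval_b[1]) % len_b
            else:
                gap = (left.interval_b[0] - right.interval_b[1]) % len_b
            gap = min(gap, len_b - gap)
            collinear = gap <= collinear_tolerance
        if strand_change or not collinear:
            rows.append({
                "position_a": left.interval_a[1] % genome_lengths[0],
                "left_block": ordered.index(left),
                "right_block": ordered.index(right),
                "strand_change": strand_change,
            })
    rows.sort(key=lambda r: r["position_a"])
    return rows


def anchors_to_table(anchors: Sequence[Anchor], name_a: str, name_b: str,
                     len_a: int, len_b: int) -> pd.DataFrame:
    """PAF-like dotplot table (query, start, end, strand, target, start, end, matches)."""
    rows = [
        {
            "query": name_a, "q_start": anc.pos_a, "q_end": anc.end_a,
            "strand": anc.strand,
            "target": name_b, "t_start": anc.pos_b, "t_end": anc.end_b,
            "matches": anc.length, "q_len": len_a, "t_len": len_b,
        }
        for anc in anchors
    ]
    return pd.DataFrame(rows, columns=["query", "q_start", "q_end", "strand",
                                       "target", "t_start", "t_end", "matches",
                                       "q_len", "t_len"])


def blocks_to_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    rows = [
        {
            "a_start": blk.interval_a[0], "a_end": blk.interval_a[1],
            "b_start": blk.interval_b[0], "b_end": blk.interval_b[1],
            "strand": blk.strand, "n_anchors": blk.n_anchors,
            "anchored_bp": blk.anchored_bp,
        }
        for blk in blocks
    ]
    return pd.DataFrame(rows, columns=["a_start", "a_end", "b_start", "b_end",
                                       "strand", "n_anchors", "anchored_bp"])
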