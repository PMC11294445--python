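"""Orthogroup inference, single-copy orthologs, PAV matrices and alignments.

Inference is a reciprocal-best-hit (RBH) scheme over a k-mer fingerprint
score: the similarity of two proteins is the multiset Jaccard index of
their amino-acid k-mer counts (k=4 by default).  For every ordered strain
pair each protein nominates its best-scoring partner (ties broken by the
lexicographically smallest gene id); reciprocal nominations become edges
and orthogroups are the connected components of that graph, with
unclustered genes kept as singletons.  The scheme deliberately trades the
sensitivity of full graph-clustering orthology tools for determinism and
speed; externally computed orthogroup tables can be ingested through
:mod:`wolbkit.io_formats` when fidelity matters.

Orthogroup alignments use the classic center-star construction: the member
with the greatest summed similarity to the others is the center, every
other member is globally aligned to it (match +1, mismatch -1, gap open
-2, gap extend -1), and the pairwise alignments are merged under
once-a-gap-always-a-gap.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import Align

from .io_formats import OrthogroupTable, SeqRecordSet

DEFAULT_K = 4
DEFAULT_MIN_SCORE = 0.2


class TooShortError(ValueError):
    """Sequence shorter than the k-mer word size."""


@dataclass
class Orthogroup:
    """One orthogroup: strain -> member gene ids, plus an optional alignment."""

    og_id: str
    members: dict[str, list[str]] = field(default_factory=dict)
    alignment: Optional[dict[str, str]] = None  # gene id -> aligned row

    def __post_init__(self) -> None:
        if not any(self.members.values()):
            raise ValueError(f"orthogroup {self.og_id!r} has no members")
        if self.alignment is not None:
            genes = {g for gs in self.members.values() for g in gs}
            if set(self.alignment) != genes:
                raise ValueError(f"orthogroup {self.og_id!r}: alignment rows != members")
            widths = {len(row) for row in self.alignment.values()}
            if len(widths) > 1:
                raise ValueError(f"orthogroup {self.og_id!r}: ragged alignment")

    def gene_ids(self) -> list[str]:
        return sorted(g for gs in self.members.values() for g in gs)

    def copy_counts(self, strains: Sequence[str]) -> tuple[int, ...]:
        return tuple(len(self.members.get(s, [])) for s in strains)


@dataclass
class PAVMatrix:
    """Copy-count matrix (orthogroups x strains); presence means count >= 1."""

    counts: pd.DataFrame

    @property
    def presence(self) -> pd.DataFrame:
        return self.counts >= 1


def _fingerprint(seq: str, k: int) -> Counter:
    if len(seq) < k:
        raise TooShortError(f"sequence of length {len(seq)} shorter than k={k}")
    return Counter(seq[i:i + k] for i in range(len(seq) - k + 1))


def pairwise_similarity(protein_a: str, protein_b: str, k: int = DEFAULT_K) -> float:
    """Multiset Jaccard similarity of k-mer fingerprints, in [0, 1]."""
    fa = _fingerprint(protein_a.upper(), k)
    fb = _fingerprint(protein_b.upper(), k)
    inter = sum((fa & fb).values())
    union = sum(fa.values()) + sum(fb.values()) - inter
    return inter / union if union else 1.0


def _best_hits(
    queries: list[tuple[str, Counter]],
    targets: list[tuple[str, Counter]],
    min_score: float,
) -> dict[str, str]:
    """Best target per query via an inverted k-mer index (exact Jaccard)."""
    index: dict[str, list[tuple[int, int]]] = {}
    sizes = []
    for idx, (_gid, fp) in enumerate(targets):
        sizes.append(sum(fp.values()))
        for kmer, cnt in fp.items():
            index.setdefault(kmer, []).append((idx, cnt))
    hits: dict[str, str] = {}
    for qid, qfp in queries:
        qsize = sum(qfp.values())
        inter: dict[int, int] = {}
        for kmer, qc in qfp.items():
            for tidx, tc in index.get(kmer, ()):
                inter[tidx] = inter.get(tidx, 0) + min(qc, tc)
        best: Optional[tuple[float, str]] = None
        for tidx, shared in inter.items():
            score = shared / (qsize + sizes[tidx] - shared)
            if score < min_score:
                continue
            tid = targets[tidx][0]
            if best is None or score > best[0] or (score == best[0] and tid < best[1]):
                best = (score, tid)
        if best is not None:
            hits[qid] = best[1]
    return hits


def infer_orthogroups(
    proteomes: Mapping[str, SeqRecordSet],
    min_score: float = DEFAULT_MIN_SCORE,
    k: int = DEFAULT_K,
) -> list[Orthogroup]:
    """RBH orthogroup inference over all strain pairs.

    Sequences shorter than k never receive hits and end up as singletons.
    Output is deterministic and invariant to strain enumeration order:
    orthogroups are numbered after sorting by their sorted member gene
    lists.
    """
    strains = sorted(proteomes)
    if len(strains) < 2:
        raise ValueError("need at least two strains")
    fingerprints: dict[str, list[tuple[str, Counter]]] = {}
    gene_strain: dict[str, str] = {}
    for strain in strains:
        recs = proteomes[strain]
        if len(recs) == 0:
            raise ValueError(f"strain {strain!r} has an empty proteome")
        fps = []
        for rec in recs:
            gene_strain[rec.id] = strain
            try:
                fps.append((rec.id, _fingerprint(rec.sequence.upper(), k)))
            except TooShortError:
                continue
        fingerprints[strain] = sorted(fps)

    graph = nx.Graph()
    graph.add_nodes_from(gene_strain)
    for i, sa in enumerate(strains):
        for sb in strains[i + 1:]:
            fwd = _best_hits(fingerprints[sa], fingerprints[sb], min_score)
            rev = _best_hits(fingerprints[sb], fingerprints[sa], min_score)
            for qa, qb in fwd.items():
                if rev.get(qb) == qa:
                    graph.add_edge(qa, qb)

    components = sorted(sorted(c) for c in nx.connected_components(graph))
    orthogroups = []
    for n, genes in enumerate(components):
        members: dict[str, list[str]] = {}
        for g in genes:
            members.setdefault(gene_strain[g], []).append(g)
        orthogroups.append(Orthogroup(og_id=f"OG{n:07d}", members=members))
    return orthogroups


def extract_scos(orthogroups: Sequence[Orthogroup], strains: Sequence[str]) -> list[str]:
    """Ids of orthogroups with exactly one member in every strain."""
    return [og.og_id for og in orthogroups
            if all(c == 1 for c in og.copy_counts(strains))]


def build_pav(orthogroups: Sequence[Orthogroup], strains: Sequence[str]) -> PAVMatrix:
    """Copy-count matrix with one row per orthogroup, rows sorted by og id."""
    declared = set(strains)
    rows = {}
    for og in orthogroups:
        extra = set(og.members) - declared
        if extra:
            raise ValueError(
                f"orthogroup {og.og_id!r} has members in undeclared strains {sorted(extra)}"
            )
        rows[og.og_id] = og.copy_counts(strains)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(strains)).sort_index()
    return PAVMatrix(counts=df.astype(int))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


def _merge_center_star(
    master: str,
    rows: dict[str, str],
    center_gapped: str,
    other_id: str,
    other_gapped: str,
) -> tuple[str, dict[str, str]]:
    """Merge one pairwise (center, other) alignment into the growing MSA."""
    new_master: list[str] = []
    new_rows: dict[str, list[str]] = {g: [] for g in rows}
    new_other: list[str] = []
    i = j = 0
    while i < len(master) or j < len(center_gapped):
        if i < len(master) and master[i] == "-":
            new_master.append("-")
            for g in rows:
                new_rows[g].append(rows[g][i])
            new_other.append("-")
            i += 1
        elif j < len(center_gapped) and center_gapped[j] == "-":
            new_master.append("-")
            for g in rows:
                new_rows[g].append("-")
            new_other.append(other_gapped[j])
            j += 1
        else:
            assert master[i] == center_gapped[j], "center sequences diverged during merge"
            new_master.append(master[i])
            for g in rows:
                new_rows[g].append(rows[g][i])
            new_other.append(other_gapped[j])
            i += 1
            j += 1
    merged = {g: "".join(chars) for g, chars in new_rows.items()}
    merged[other_id] = "".join(new_other)
    return "".join(new_master), merged


def align_orthogroup(members: Sequence[tuple[str, str]], k: int = DEFAULT_K) -> dict[str, str]:
    """Center-star multiple alignment of (gene id, sequence) members.

    A single member is returned unaligned.  Column content is independent
    of input order because the center choice and the merge order follow
    the canonical (sorted) member order.
    """
    members = sorted(members)
    if not members:
        raise ValueError("no members to align")
    if len(members) == 1:
        return {members[0][0]: members[0][1]}

    def safe_sim(a: str, b: str) -> float:
        try:
            return pairwise_similarity(a, b, k)
        except TooShortError:
            return 0.0

    totals = {
        gid: sum(safe_sim(seq, other_seq) for ogid, other_seq in members if ogid != gid)
        for gid, seq in members
    }
    center_id = max(sorted(totals), key=lambda g: totals[g])
    center_seq = dict(members)[center_id]

    aligner = _make_aligner()
    master = center_seq
    rows: dict[str, str] = {center_id: center_seq}
    for gid, seq in members:
        if gid == center_id:
            continue
        aln = aligner.align(center_seq, seq)[0]
        center_gapped, other_gapped = str(aln[0]), str(aln[1])
        master, rows = _merge_center_star(master, rows, center_gapped, gid, other_gapped)
    return rows


def export_supermatrix(
    sco_alignments: Sequence[tuple[str, Mapping[str, str]]],
    strains: Sequence[str],
) -> tuple[dict[str, str], list[tuple[str, int, int]]]:
    """Concatenate per-strain rows of single-copy orthogroup alignments.

    ``sco_alignments`` is a sequence of (og_id, strain -> aligned row).
    Returns (strain -> concatenated sequence, partitions) with partitions
    as (og_id, start, end) half-open column intervals.
    """
    if not sco_alignments:
        raise ValueError("no single-copy orthogroups")
    supermatrix = {s: [] for s in strains}
    partitions: list[tuple[str, int, int]] = []
    offset = 0
    for og_id, rows in sco_alignments:
        missing = [s for s in strains if s not in rows]
        if missing:
            raise ValueError(f"orthogroup {og_id!r} missing strains {missing}")
        widths = {len(rows[s]) for s in strains}
        if len(widths) != 1:
            raise ValueError(f"orthogroup {og_id!r}: ragged alignment")
        width = widths.pop()
        for s in strains:
            supermatrix[s].append(rows[s])
        partitions.append((og_id, offset, offset + width))
        offset += width
    return {s: "".join(parts) for s, parts in supermatrix.items()}, partitions


def orthogroups_to_table(
    orthogroups: Sequence[Orthogroup], strains: Sequence[str]
) -> OrthogroupTable:
    """Convert to the OrthoFinder-style table for serialization."""
    cells = {}
    for og in orthogroups:
        for s in strains:
            cells[(og.og_id, s)] = sorted(og.members.get(s, []))
    return OrthogroupTable(
        og_ids=[og.og_id for og in orthogroups],
        strains=list(strains),
        cells=cells,
    )


def table_to_orthogroups(table: OrthogroupTable) -> list[Orthogroup]:
    """Inverse of :func:`orthogroups_to_table` (empty orthogroups dropped)."""
    out = []
    for og_id in table.og_ids:
        members = {}
        for s in table.strains:
            genes = table.cells.get((og_id, s), [])
            if genes:
                members[s] = list(genes)
        if members:
            out.append(Orthogroup(og_id=og_id, members=members))
    return out
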