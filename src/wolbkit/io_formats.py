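"""Readers and writers for the formats the pipeline touches.

Strict by design: readers reject malformed input instead of repairing it,
and writers are deterministic so identical runs produce identical files.
FASTA goes through Biopython, SAM through pysam, Newick through dendropy;
PAF and the OrthoFinder-style orthogroup table dialect are parsed here.

Coordinates are 0-based half-open everywhere.  Windowed tracks are written
as BED-like TSV; a wrap-around window on a circular sequence is emitted as
two lines sharing a window id.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import dendropy
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome_stats import WindowTrack
from .read_filter import AlignmentRecord

logger = logging.getLogger(__name__)

NUCLEOTIDE_ALPHABET = set("ACGTRYSWKMBDHVN") | {"-"}
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*", "-"}
_ALPHABETS = {"nucleotide": NUCLEOTIDE_ALPHABET, "protein": PROTEIN_ALPHABET}


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str


@dataclass
class SeqRecordSet:
    """Ordered FASTA records of one alphabet with unique ids."""

    records: list[FastaRecord]
    alphabet: str

    def __post_init__(self) -> None:
        if self.alphabet not in _ALPHABETS:
            raise ValueError(f"alphabet must be nucleotide|protein, got {self.alphabet!r}")
        seen: set[str] = set()
        allowed = _ALPHABETS[self.alphabet]
        for rec in self.records:
            if rec.id in seen:
                raise FormatError(f"duplicate record id {rec.id!r}")
            seen.add(rec.id)
            if not rec.sequence:
                raise FormatError(f"record {rec.id!r}: empty sequence")
            bad = set(rec.sequence.upper()) - allowed
            if bad:
                raise FormatError(
                    f"record {rec.id!r}: characters {sorted(bad)!r} not in "
                    f"{self.alphabet} alphabet"
                )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, rec_id: str) -> FastaRecord:
        for rec in self.records:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)


def read_fasta(path, alphabet: str) -> SeqRecordSet:
    """Parse a FASTA file, validating ids, non-emptiness and the alphabet."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(FastaRecord(id=rec.id, description=desc, sequence=str(rec.seq).upper()))
    return SeqRecordSet(records=records, alphabet=alphabet)


def write_fasta(path, recordset: SeqRecordSet, wrap: int = 60) -> None:
    """Write records in input order, sequence lines wrapped to ``wrap``."""
    seqio_records = []
    for rec in recordset:
        r = SeqRecord(Seq(rec.sequence), id=rec.id, description=rec.description)
        seqio_records.append(r)
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=wrap)
        writer.write_file(seqio_records)


# ---------------------------------------------------------------------------
# Orthogroup tables (OrthoFinder-style Orthogroups.tsv dialect)


@dataclass
class OrthogroupTable:
    """Orthogroup x strain table; cells are lists of gene ids."""

    og_ids: list[str]
    strains: list[str]
    cells: dict[tuple[str, str], list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        owner: dict[str, str] = {}
        for (og, _strain), genes in sorted(self.cells.items()):
            for g in genes:
                if g in owner and owner[g] != og:
                    raise FormatError(
                        f"gene {g!r} appears in orthogroups {owner[g]!r} and {og!r}"
                    )
                owner[g] = og

    def counts(self, og_id: str) -> tuple[int, ...]:
        return tuple(len(self.cells.get((og_id, s), [])) for s in self.strains)


def read_orthogroup_table(path) -> OrthogroupTable:
    """Read an ``Orthogroup<TAB>strain...`` TSV with ', '-separated gene lists."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header or "\t" not in header:
            raise FormatError(f"{path}: missing or malformed header row")
        cols = header.split("\t")
        strains = cols[1:]
        og_ids: list[str] = []
        cells: dict[tuple[str, str], list[str]] = {}
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(cols):
                raise FormatError(f"{path}:{lineno}: expected {len(cols)} columns")
            og = parts[0]
            og_ids.append(og)
            for strain, cell in zip(strains, parts[1:]):
                genes = [g for g in cell.split(", ") if g] if cell else []
                cells[(og, strain)] = genes
    return OrthogroupTable(og_ids=og_ids, strains=strains, cells=cells)


def write_orthogroup_table(path, table: OrthogroupTable) -> None:
    with open(path, "w") as fh:
        fh.write("Orthogroup\t" + "\t".join(table.strains) + "\n")
        for og in table.og_ids:
            row = [", ".join(table.cells.get((og, s), [])) for s in table.strains]
            fh.write(og + "\t" + "\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Alignment records (SAM / PAF)

_SAM_OP = {0: "M", 1: "I", 2: "D", 7: "=", 8: "X"}
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")
_QUERY_CONSUMING = set("MIS=X")


def _runs_from_cigartuples(tuples) -> list[tuple[str, int]]:
    runs = []
    for op, length in tuples:
        sym = _SAM_OP.get(op)
        if sym is None:  # N/S/H/P do not enter divergence bookkeeping
            continue
        runs.append((sym, length))
    return runs


def read_alignment_records(path, dialect: str) -> list[AlignmentRecord]:
    """Parse SAM or PAF into :class:`AlignmentRecord` objects.

    Records whose divergence cannot be determined (no mismatch-resolved
    CIGAR and no NM tag) are returned with whatever evidence they carry and
    flagged via ``AlignmentRecord.determinate``.
    """
    if dialect == "sam":
        return _read_sam(path)
    if dialect == "paf":
        return _read_paf(path)
    raise ValueError(f"dialect must be sam|paf, got {dialect!r}")


def _read_sam(path) -> list[AlignmentRecord]:
    try:
        return _read_sam_inner(path)
    except FormatError:
        raise
    except (OSError, ValueError) as exc:  # pysam reports parse errors variously
        raise FormatError(f"{path}: malformed SAM ({exc})") from exc


def _read_sam_inner(path) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as fh:
        for aln in fh:
            mapped = not aln.is_unmapped
            runs = _runs_from_cigartuples(aln.cigartuples or [])
            if mapped and aln.query_sequence is not None and runs:
                qlen = sum(n for op, n in runs if op in ("M", "I", "=", "X"))
                if qlen != len(aln.query_sequence):
                    raise FormatError(
                        f"read {aln.query_name!r}: CIGAR consumes {qlen} query bases "
                        f"but sequence has {len(aln.query_sequence)}"
                    )
            nm = aln.get_tag("NM") if aln.has_tag("NM") else None
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    target_id=aln.reference_name if mapped else "*",
                    event_runs=runs,
                    edit_distance=int(nm) if nm is not None else None,
                    mapped=mapped,
                    is_primary=not (aln.is_secondary or aln.is_supplementary),
                )
            )
    return records


def _read_paf(path) -> list[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: PAF needs >= 12 columns")
            qname, qlen = parts[0], int(parts[1])
            strand, tname = parts[4], parts[5]
            tags = dict(
                (t.split(":", 2)[0], t.split(":", 2)[2]) for t in parts[12:] if t.count(":") >= 2
            )
            runs: list[tuple[str, int]] = []
            if "cg" in tags:
                for m in _CIGAR_RE.finditer(tags["cg"]):
                    n, op = int(m.group(1)), m.group(2)
                    if op in "MIDX=":
                        runs.append((op, n))
                qconsumed = sum(n for op, n in runs if op in _QUERY_CONSUMING)
                span = int(parts[3]) - int(parts[2])
                if qconsumed != span:
                    raise FormatError(
                        f"{path}:{lineno}: CIGAR consumes {qconsumed} query bases, "
                        f"interval spans {span}"
                    )
            nm = int(tags["NM"]) if "NM" in tags else None
            mapped = strand in "+-" and tname != "*"
            is_primary = tags.get("tp", "P") == "P"
            records.append(
                AlignmentRecord(
                    read_id=qname,
                    target_id=tname,
                    event_runs=runs,
                    edit_distance=nm,
                    mapped=mapped,
                    is_primary=is_primary,
                )
            )
    return records


def _cigar_string(runs: list[tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in runs)


def write_sam(path, records: list[AlignmentRecord], sequences: dict[str, str],
              target_lengths: dict[str, int]) -> None:
    """Emit a minimal text SAM with NM tags (query sequences required)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for tid, tlen in sorted(target_lengths.items()):
            fh.write(f"@SQ\tSN:{tid}\tLN:{tlen}\n")
        for rec in records:
            flag = 0 if rec.mapped else 4
            if not rec.is_primary:
                flag |= 256
            cigar = _cigar_string(rec.event_runs) if rec.mapped else "*"
            seq = sequences.get(rec.read_id, "*")
            tname = rec.target_id if rec.mapped else "*"
            pos = 1 if rec.mapped else 0
            fields = [rec.read_id, str(flag), tname, str(pos), "60" if rec.mapped else "0",
                      cigar, "*", "0", "0", seq, "*"]
            if rec.edit_distance is not None:
                fields.append(f"NM:i:{rec.edit_distance}")
            fh.write("\t".join(fields) + "\n")


def write_paf(path, records: list[AlignmentRecord], sequences: dict[str, str],
              target_lengths: dict[str, int]) -> None:
    """Emit PAF lines equivalent to :func:`write_sam` output."""
    with open(path, "w") as fh:
        for rec in records:
            if not rec.mapped:
                continue
            qlen = sum(n for op, n in rec.event_runs if op in ("M", "I", "=", "X"))
            tspan = sum(n for op, n in rec.event_runs if op in ("M", "D", "=", "X"))
            nmatch = sum(n for op, n in rec.event_runs if op == "=")
            alen = sum(n for _, n in rec.event_runs)
            tlen = target_lengths.get(rec.target_id, tspan)
            fields = [rec.read_id, str(qlen), "0", str(qlen), "+", rec.target_id,
                      str(tlen), "0", str(tspan), str(nmatch), str(alen), "60"]
            if rec.edit_distance is not None:
                fields.append(f"NM:i:{rec.edit_distance}")
            fields.append("tp:A:P" if rec.is_primary else "tp:A:S")
            fields.append(f"cg:Z:{_cigar_string(rec.event_runs)}")
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# Predictor tables (signal peptide / transmembrane)

_PREDHEL_RE = re.compile(r"PredHel=(\d+)")


def read_predictor_tables(
    sp_path=None,
    tm_path=None,
    sp_prob_threshold: float = 0.5,
    sp_prob_column: Optional[int] = None,
    tm_count_column: Optional[int] = None,
) -> dict[str, tuple[bool, int]]:
    """Merge external signal-peptide and transmembrane predictor tables.

    Both tables are whitespace/TAB-separated with the gene id in the first
    column.  The signal-peptide call is taken from a probability column
    (threshold ``sp_prob_threshold``) or a YES/NO / ``SP(...)`` label; the
    transmembrane call from a ``PredHel=N`` token or a numeric column.
    Genes present in only one table default to (no signal peptide) or
    (0 segments) with a logged warning.
    """
    sp: dict[str, bool] = {}
    tm: dict[str, int] = {}
    if sp_path is not None:
        for gene, fields in _iter_table(sp_path):
            sp[gene] = _parse_sp_fields(fields, sp_prob_threshold, sp_prob_column)
    if tm_path is not None:
        for gene, fields in _iter_table(tm_path):
            tm[gene] = _parse_tm_fields(fields, tm_count_column)
    merged: dict[str, tuple[bool, int]] = {}
    for gene in sorted(set(sp) | set(tm)):
        if gene not in sp and sp_path is not None:
            logger.warning("gene %s absent from signal-peptide table; defaulting to False", gene)
        if gene not in tm and tm_path is not None:
            logger.warning("gene %s absent from transmembrane table; defaulting to 0", gene)
        merged[gene] = (sp.get(gene, False), tm.get(gene, 0))
    return merged


def _iter_table(path):
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            yield fields[0].strip(), [f.strip() for f in fields[1:]]


def _parse_sp_fields(fields, threshold, prob_column) -> bool:
    if prob_column is not None:
        try:
            return float(fields[prob_column - 1]) >= threshold
        except (IndexError, ValueError) as exc:
            raise FormatError(f"unparseable signal-peptide probability in {fields!r}") from exc
    prob = None
    label = None
    for f in fields:
        try:
            prob = float(f)
            continue
        except ValueError:
            pass
        up = f.upper()
        if up in ("YES", "Y", "NO", "N", "OTHER") or up.startswith("SP"):
            label = up
    if prob is not None:
        return prob >= threshold
    if label is not None:
        return label.startswith(("Y", "SP"))
    raise FormatError(f"no signal-peptide call found in {fields!r}")


def _parse_tm_fields(fields, count_column) -> int:
    if count_column is not None:
        try:
            return int(float(fields[count_column - 1]))
        except (IndexError, ValueError) as exc:
            raise FormatError(f"unparseable transmembrane count in {fields!r}") from exc
    for f in fields:
        m = _PREDHEL_RE.search(f)
        if m:
            return int(m.group(1))
    for f in fields:
        try:
            return int(f)
        except ValueError:
            continue
    raise FormatError(f"no transmembrane helix count found in {fields!r}")


# ---------------------------------------------------------------------------
# BED-like window tracks


def write_track(path, track: WindowTrack) -> None:
    """Serialize a window track as TSV: seqid, start, end, value[, window id].

    Windows must arrive sorted by start.  A window that wraps past the end
    of a circular sequence is split into two lines sharing a window id in
    the fifth column; missing values are written as ``NA``.
    """
    starts = [s for s, _, _ in track.windows]
    if starts != sorted(starts):
        raise ValueError("windows must be sorted by start")
    n = track.seq_length
    with open(path, "w") as fh:
        fh.write(f"# metric={track.metric} window={track.window_size} "
                 f"step={track.step} length={n} deviation={int(track.deviation)}"
                 + (f" genome_mean={track.genome_mean:.6f}" if track.genome_mean is not None else "")
                 + "\n")
        for i, (start, end, value) in enumerate(track.windows):
            sval = "NA" if value is None else f"{value:.6f}"
            if n and end > n:  # circular wrap: split at the origin
                wid = f"w{i}"
                fh.write(f"{track.seq_id}\t{start}\t{n}\t{sval}\t{wid}\n")
                fh.write(f"{track.seq_id}\t0\t{end - n}\t{sval}\t{wid}\n")
            else:
                fh.write(f"{track.seq_id}\t{start}\t{end}\t{sval}\n")


def read_track(path) -> WindowTrack:
    """Inverse of :func:`write_track` (values to 6 decimals)."""
    meta: dict[str, str] = {}
    rows: list[tuple[str, int, int, Optional[float], Optional[str]]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                meta = dict(kv.split("=", 1) for kv in line[1:].split())
                continue
            parts = line.split("\t")
            if len(parts) not in (4, 5):
                raise FormatError(f"{path}: track lines need 4-5 columns")
            value = None if parts[3] == "NA" else float(parts[3])
            rows.append((parts[0], int(parts[1]), int(parts[2]), value,
                         parts[4] if len(parts) == 5 else None))
    n = int(meta.get("length", 0))
    track = WindowTrack(
        seq_id=rows[0][0] if rows else "",
        metric=meta.get("metric", "gc_skew"),
        window_size=int(meta.get("window", 0)),
        step=int(meta.get("step", 0)),
        seq_length=n,
        deviation=bool(int(meta.get("deviation", 0))),
        genome_mean=float(meta["genome_mean"]) if "genome_mean" in meta else None,
    )
    skip_next = False
    for i, row in enumerate(rows):
        if skip_next:
            skip_next = False
            continue
        _, start, end, value, wid = row
        if wid is not None:  # rejoin the two halves of a wrapped window
            nxt = rows[i + 1]
            end = n + nxt[2]
            skip_next = True
        track.windows.append((start, end, value))
    return track


# ---------------------------------------------------------------------------
# Newick trees


def read_newick(path) -> dendropy.Tree:
    """Read a rooted Newick tree; every edge must carry a branch length."""
    tree = dendropy.Tree.get(path=str(path), schema="newick",
                             preserve_underscores=True)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise FormatError("Newick tree is missing branch lengths")
    return tree


def write_newick(path, tree: dendropy.Tree) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)
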