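"""Strain-set simulator with a complete truth manifest.

Generates everything the pipeline consumes — a rooted strain tree with
clade ("supergroup") structure, gene gain/loss producing clade-specific
presence-absence variation, protein families with designated variable
columns, planted signal-peptide / transmembrane features, circular genomes
with an imposed GC-skew origin and planted rearrangements, and alignment
records with known gap-compressed divergences — while recording the ground
truth for every emitted object, so each downstream stage can be tested
against what was actually planted.

Reproducibility: a single integer seed drives one root random stream, and
per-entity sub-streams are derived by stable hashing of entity names
(:mod:`wolbkit._rng`), so outputs are byte-identical for identical
(parameters, seed) regardless of iteration order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from ._rng import child_rng
from .genome_stats import GenomeRecord
from .io_formats import FastaRecord, SeqRecordSet, write_fasta, write_paf, write_sam
from .read_filter import AlignmentRecord
from .secretome import MEMBRANE, OTHER, SECRETED
from .synteny import revcomp

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_POLAR = "STNQDEKRGPH"          # background alphabet: never forms hydrophobic runs
_SIGNAL_CORE = "LIVF"           # hydrophobic signal-peptide core
_TM_CORE = "LIV"                # strongly hydrophobic transmembrane core
_TM_FLANK = "STG"               # mildly polar flanks keep the detection window high
_SIGNAL_LEN = 22
_TM_LEN = 19
_TM_FLANK_LEN = 8


# ---------------------------------------------------------------------------
# Strain tree


@dataclass
class StrainTree:
    """Rooted bifurcating tree over strains plus a clade label per leaf."""

    tree: dendropy.Tree
    clade_labels: dict[str, str]

    def __post_init__(self) -> None:
        leaves = self.leaf_labels()
        if len(leaves) < 2:
            raise ValueError("strain tree needs at least two leaves")
        if set(leaves) != set(self.clade_labels):
            raise ValueError("every leaf needs exactly one clade label")
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")

    def leaf_labels(self) -> list[str]:
        return sorted(lf.taxon.label for lf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True,
                                   unquoted_underscores=True).strip()


def _node_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else node.label


def sample_strain_tree(n_strains: int, n_clades: int, seed: int) -> StrainTree:
    """Random rooted bifurcating tree whose leaves partition into
    ``n_clades`` monophyletic clades.

    Clades are built as independent random-join subtrees and then joined by
    a random-join backbone, so each clade is a subtree by construction.
    Clade stems get longer branches than within-clade edges, giving the
    clade-structured divergence pattern of a supergroup phylogeny.
    """
    if n_strains < 2:
        raise ValueError(f"n_strains must be >= 2, got {n_strains}")
    if not 1 <= n_clades <= n_strains:
        raise ValueError(f"n_clades must be in [1, {n_strains}], got {n_clades}")
    rng = child_rng(seed, "tree")
    labels = [f"S{i + 1:02d}" for i in range(n_strains)]
    base, extra = divmod(n_strains, n_clades)
    partitions: list[list[str]] = []
    start = 0
    for i in range(n_clades):
        size = base + (1 if i < extra else 0)
        partitions.append(labels[start:start + size])
        start += size
    clade_labels = {}
    for i, part in enumerate(partitions):
        for lab in part:
            clade_labels[lab] = chr(65 + i)

    tns = dendropy.TaxonNamespace(labels)

    def random_join(nodes: list[dendropy.Node], scale: float) -> dendropy.Node:
        while len(nodes) > 1:
            i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
            right = nodes.pop(j)
            left = nodes.pop(i)
            parent = dendropy.Node()
            parent.add_child(left)
            parent.add_child(right)
            parent.edge.length = float(rng.exponential(scale))
            nodes.append(parent)
        return nodes[0]

    clade_roots = []
    for part in partitions:
        leaves = []
        for lab in part:
            nd = dendropy.Node(taxon=tns.get_taxon(lab))
            nd.edge.length = float(rng.exponential(0.01))
            leaves.append(nd)
        root = random_join(leaves, scale=0.01)
        root.edge.length = 0.05 + float(rng.exponential(0.05))  # clade stem
        clade_roots.append(root)
    root = random_join(clade_roots, scale=0.05)
    root.edge.length = None
    tree = dendropy.Tree(seed_node=root, taxon_namespace=tns)
    tree.is_rooted = True
    counter = 0
    for node in tree.preorder_node_iter():
        if node.taxon is None:
            node.label = f"N{counter:03d}"
            counter += 1
    return StrainTree(tree=tree, clade_labels=clade_labels)


# ---------------------------------------------------------------------------
# Gene content (gain/loss on the tree)


@dataclass
class GeneContentTruth:
    pav: pd.DataFrame                      # bool, families x strains
    events: dict[str, dict]                # family -> {"gain_node": ..., "losses": [...]}


def simulate_gene_content(
    tree: StrainTree,
    n_core: int,
    n_accessory: int,
    gain_rate: float,
    loss_rate: float,
    seed: int,
) -> tuple[dict[str, list[str]], GeneContentTruth]:
    """Gain/loss simulation of gene-family content along the tree.

    Core families are present in every strain.  Each accessory family is
    gained once, on a branch drawn with probability proportional to
    1 - exp(-gain_rate * branch_length) (all weights zero, i.e.
    ``gain_rate=0``, degenerates to a gain at the root), and can then be
    lost at most once per branch below the gain with probability
    1 - exp(-loss_rate * branch_length); a lost lineage never regains.
    The complete event log is recorded per family.
    """
    if n_core < 0 or n_accessory < 0:
        raise ValueError("family counts must be non-negative")
    if gain_rate < 0 or loss_rate < 0:
        raise ValueError("rates must be non-negative")
    leaves = tree.leaf_labels()
    root_label = _node_label(tree.tree.seed_node)
    nodes = {_node_label(nd): nd for nd in tree.tree.preorder_node_iter()}
    non_root = sorted(lab for lab in nodes if lab != root_label)
    lengths = np.array([nodes[lab].edge.length or 0.0 for lab in non_root])

    families = [f"FAM{i + 1:04d}" for i in range(n_core + n_accessory)]
    pav = pd.DataFrame(False, index=families, columns=leaves)
    events: dict[str, dict] = {}
    for fam in families[:n_core]:
        pav.loc[fam] = True
        events[fam] = {"gain_node": root_label, "losses": []}
    weights = 1.0 - np.exp(-gain_rate * lengths) if len(non_root) else np.array([])
    total_w = float(weights.sum()) if len(non_root) else 0.0
    for fam in families[n_core:]:
        rng = child_rng(seed, "content", fam)
        if total_w == 0.0:
            gain_label = root_label
        else:
            gain_label = non_root[int(rng.choice(len(non_root), p=weights / total_w))]
        losses: list[str] = []
        present_leaves: list[str] = []

        def descend(node: dendropy.Node, present: bool) -> None:
            if node.is_leaf():
                if present:
                    present_leaves.append(node.taxon.label)
                return
            for child in node.child_nodes():
                child_present = present
                if present:
                    p_loss = 1.0 - math.exp(-loss_rate * (child.edge.length or 0.0))
                    if rng.random() < p_loss:
                        child_present = False
                        losses.append(_node_label(child))
                descend(child, child_present)

        gain_node = nodes[gain_label]
        if gain_node.is_leaf():
            present_leaves.append(gain_node.taxon.label)
        else:
            descend(gain_node, True)
        pav.loc[fam, present_leaves] = True
        events[fam] = {"gain_node": gain_label, "losses": losses}

    gene_sets = {
        leaf: sorted(pav.index[pav[leaf]].tolist()) for leaf in leaves
    }
    return gene_sets, GeneContentTruth(pav=pav, events=events)


# ---------------------------------------------------------------------------
# Family alignments with designated variable columns


def simulate_family_alignment(
    family_id: str,
    tree: StrainTree,
    length: int,
    n_variable: int,
    seed: int,
    root_sequence: Optional[str] = None,
    exclude_columns: Optional[set[int]] = None,
    substitution_rate: float = 30.0,
    leaves: Optional[set[str]] = None,
) -> tuple[dict[str, str], set[int]]:
    """Evolve one protein family; substitutions hit only designated columns.

    ``n_variable`` columns are designated as variable (optionally avoiding
    ``exclude_columns``, e.g. planted feature regions); all other columns
    are copied unchanged down the tree.  Each designated column is forced
    to realize at least two residue states among the returned leaves, so
    the realized variable-site count equals ``n_variable`` exactly.

    ``leaves`` restricts the output (and the forcing) to a subset of
    strains, e.g. the strains actually carrying the family; it must
    contain at least two leaves when ``n_variable`` > 0.
    """
    if not 0 <= n_variable <= length:
        raise ValueError(f"n_variable must be in [0, {length}], got {n_variable}")
    rng = child_rng(seed, "aln", family_id)
    if root_sequence is None:
        root_sequence = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    elif len(root_sequence) != length:
        raise ValueError("root_sequence length disagrees with length")
    allowed = [i for i in range(length) if not exclude_columns or i not in exclude_columns]
    if n_variable > len(allowed):
        raise ValueError(
            f"n_variable={n_variable} exceeds {len(allowed)} columns available "
            f"after exclusions"
        )
    var_cols = sorted(int(c) for c in rng.choice(allowed, size=n_variable, replace=False))

    aa = list(AMINO_ACIDS)
    seqs: dict[dendropy.Node, list[str]] = {tree.tree.seed_node: list(root_sequence)}
    for node in tree.tree.preorder_node_iter():
        if node is tree.tree.seed_node:
            continue
        parent_seq = seqs[node.parent_node]
        seq = list(parent_seq)
        p_sub = 1.0 - math.exp(-substitution_rate * (node.edge.length or 0.0))
        for col in var_cols:
            if rng.random() < p_sub:
                current = seq[col]
                choices = [x for x in aa if x != current]
                seq[col] = choices[int(rng.integers(len(choices)))]
        seqs[node] = seq
    alignment = {
        lf.taxon.label: seqs[lf] for lf in tree.tree.leaf_node_iter()
        if leaves is None or lf.taxon.label in leaves
    }
    kept = sorted(alignment)
    if n_variable > 0 and len(kept) < 2:
        raise ValueError("need at least two retained leaves to realize variation")
    for col in var_cols:  # force >= 2 states per designated column
        states = {alignment[s][col] for s in kept}
        if len(states) < 2:
            victim = kept[int(rng.integers(len(kept)))]
            current = alignment[victim][col]
            choices = [x for x in aa if x != current]
            alignment[victim][col] = choices[int(rng.integers(len(choices)))]
    return {s: "".join(alignment[s]) for s in kept}, set(var_cols)


# ---------------------------------------------------------------------------
# Protein feature planting (signal peptides / transmembrane segments)


def _scrub_hydrophobic(seq: list[str], rng, protect: Sequence[tuple[int, int]] = ()) -> None:
    """Remove accidental hydrophobic runs from the background sequence.

    Windows intersecting a protected (planted-feature) interval are left
    alone; the features' own polar buffer zones guarantee those windows
    stay below the detection threshold.
    """
    from .secretome import KYTE_DOOLITTLE

    protected = set()
    for lo, hi in protect:
        protected.update(range(lo, hi))
    for _ in range(100):
        if len(seq) < 19:
            return
        vals = [KYTE_DOOLITTLE.get(a, 0.0) for a in seq]
        dirty = False
        for i in range(len(seq) - 18):
            if any(j in protected for j in range(i, i + 19)):
                continue
            if sum(vals[i:i + 19]) / 19.0 > 1.2:  # margin below the 1.6 threshold
                dirty = True
                for j in range(i, i + 19):
                    if KYTE_DOOLITTLE.get(seq[j], 0.0) > 0:
                        seq[j] = _POLAR[int(rng.integers(len(_POLAR)))]
                break
        if not dirty:
            return
    raise RuntimeError("could not scrub hydrophobic runs from background sequence")


def plant_protein_features(
    sequence: str,
    target_class: str,
    seed: int,
) -> tuple[str, str, list[tuple[int, int]]]:
    """Rewrite a protein so the built-in classifier must assign ``target_class``.

    Returns (modified sequence, class truth, protected intervals).  The
    protected intervals mark the planted features (plus the cleavage
    region) and should be kept invariant by any subsequent evolution so the
    planted class survives.

    * secreted: hydrophobic signal segment at the N terminus (charged
      residue at position 2, core drawn from {L,I,V,F}, small residue at
      the cleavage site), no internal transmembrane-like segment;
    * membrane-bound: the signal segment plus one internal 19-residue
      strongly hydrophobic segment drawn from {L,I,V} with mildly polar
      flanks;
    * other: neither (hydrophobic runs scrubbed).
    """
    if target_class not in (MEMBRANE, SECRETED, OTHER):
        raise ValueError(f"unknown target class {target_class!r}")
    min_len = {OTHER: 25, SECRETED: 45, MEMBRANE: 90}[target_class]
    if len(sequence) < min_len:
        raise ValueError(
            f"sequence of length {len(sequence)} too short for {target_class} features"
        )
    rng = child_rng(seed, "plant", target_class)
    seq = list(sequence.upper())
    protected: list[tuple[int, int]] = []

    if target_class == OTHER:
        _scrub_hydrophobic(seq, rng)
        return "".join(seq), OTHER, protected

    # signal peptide: positions 0..21 hydrophobic, charge at index 1, cleavage
    # S at 22, then a polar buffer so windows straddling the core stay cold
    for i in range(_SIGNAL_LEN):
        seq[i] = _SIGNAL_CORE[int(rng.integers(len(_SIGNAL_CORE)))]
    seq[1] = "KR"[int(rng.integers(2))]
    seq[_SIGNAL_LEN] = "S"
    for i in range(_SIGNAL_LEN + 1, _SIGNAL_LEN + 19):
        seq[i] = "STN"[int(rng.integers(3))]
    protected.append((0, _SIGNAL_LEN + 19))

    if target_class == MEMBRANE:
        tm_start = max(45, len(seq) // 2 - _TM_LEN // 2)
        if tm_start + _TM_LEN + _TM_FLANK_LEN > len(seq):
            raise ValueError("sequence too short to place a transmembrane segment")
        for i in range(tm_start - _TM_FLANK_LEN, tm_start):
            seq[i] = _TM_FLANK[int(rng.integers(len(_TM_FLANK)))]
        for i in range(tm_start, tm_start + _TM_LEN):
            seq[i] = _TM_CORE[int(rng.integers(len(_TM_CORE)))]
        for i in range(tm_start + _TM_LEN, tm_start + _TM_LEN + _TM_FLANK_LEN):
            seq[i] = _TM_FLANK[int(rng.integers(len(_TM_FLANK)))]
        protected.append((tm_start - _TM_FLANK_LEN, tm_start + _TM_LEN + _TM_FLANK_LEN))

    _scrub_hydrophobic(seq, rng, protect=protected)
    return "".join(seq), target_class, protected


# ---------------------------------------------------------------------------
# Genome assembly (GC skew + rearrangements)


@dataclass
class GenomeTruth:
    origin_position: dict[str, int]                 # strain -> skew flip (bp)
    breakpoints: dict[str, list[tuple[int, int]]]   # strain -> rearranged intervals


def _intergenic(rng, n: int, start: int, origin: int, total: int,
                gc: float, amplitude: float) -> str:
    """Intergenic bases with the G/C bias flipping sign halfway round from origin."""
    offsets = (np.arange(start, start + n) - origin) % total
    first_half = offsets < total / 2
    p_at = (1.0 - gc) / 2.0
    bases = np.empty(n, dtype="<U1")
    for mask, sign in ((first_half, 1.0), (~first_half, -1.0)):
        m = int(mask.sum())
        if m == 0:
            continue
        p_g = gc / 2.0 * (1.0 + sign * amplitude)
        p_c = gc / 2.0 * (1.0 - sign * amplitude)
        bases[mask] = rng.choice(list("ACGT"), size=m, p=[p_at, p_c, p_g, p_at])
    return "".join(bases)


def assemble_genomes(
    gene_sets: dict[str, Sequence[str]],
    intergenic_mean: int = 300,
    skew_amplitude: float = 0.6,
    origin_position: float = 0.25,
    rearrangement_spec: Optional[Sequence[dict]] = None,
    seed: int = 0,
    gene_length: int = 600,
    gc: float = 0.35,
) -> tuple[dict[str, GenomeRecord], GenomeTruth]:
    """Assemble one circular genome per strain from its gene-family content.

    Gene sequences are generated once per family (shared across strains)
    with skew-neutral composition; intergenic spacers carry the imposed
    G-vs-C bias, whose sign flips at ``origin_position`` (a fraction of
    the genome) and again at the antipode.  Spacers are keyed by the gene
    they follow, not by strain, so strains with identical content assemble
    byte-identical genomes — which makes planted rearrangements between
    such strains exactly recoverable.

    ``rearrangement_spec`` entries are dicts with keys ``strain``, ``type``
    ("inversion"), ``start`` and ``length``; overlapping intervals on one
    strain are rejected.
    """
    if not 0.0 <= skew_amplitude <= 1.0:
        raise ValueError("skew_amplitude must be in [0, 1]")
    if not 0.0 <= origin_position < 1.0:
        raise ValueError("origin_position must be a fraction in [0, 1)")
    rearrangement_spec = list(rearrangement_spec or [])
    per_strain: dict[str, list[dict]] = {}
    for spec_entry in rearrangement_spec:
        if spec_entry.get("type") != "inversion":
            raise ValueError(f"unsupported rearrangement type {spec_entry.get('type')!r}")
        per_strain.setdefault(spec_entry["strain"], []).append(spec_entry)
    for strain, entries in per_strain.items():
        intervals = sorted((e["start"], e["start"] + e["length"]) for e in entries)
        for (s1, e1), (s2, _e2) in zip(intervals, intervals[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping rearrangements on strain {strain!r}")

    families = sorted({f for fams in gene_sets.values() for f in fams})
    gene_seqs = {}
    ig_lengths = {}
    p_at = (1.0 - gc) / 2.0
    for fam in families:
        g_rng = child_rng(seed, "gene", fam)
        gene_seqs[fam] = "".join(
            g_rng.choice(list("ACGT"), size=gene_length, p=[p_at, gc / 2, gc / 2, p_at])
        )
        ig_lengths[fam] = max(50, int(child_rng(seed, "iglen", fam).poisson(intergenic_mean)))

    genomes: dict[str, GenomeRecord] = {}
    origins: dict[str, int] = {}
    breakpoints: dict[str, list[tuple[int, int]]] = {}
    for strain in sorted(gene_sets):
        fams = sorted(gene_sets[strain])
        if not fams:
            raise ValueError(f"strain {strain!r} has no gene families")
        total = sum(gene_length + ig_lengths[f] for f in fams)
        origin = int(origin_position * total)
        parts: list[str] = []
        pos = 0
        for fam in fams:
            parts.append(gene_seqs[fam])
            pos += gene_length
            n = ig_lengths[fam]
            parts.append(_intergenic(child_rng(seed, "ig", fam), n, pos, origin,
                                     total, gc, skew_amplitude))
            pos += n
        seq = "".join(parts)
        bps: list[tuple[int, int]] = []
        for entry in per_strain.get(strain, []):
            s, ln = entry["start"], entry["length"]
            if not 0 <= s < s + ln <= len(seq):
                raise ValueError(f"rearrangement out of bounds on strain {strain!r}")
            seq = seq[:s] + revcomp(seq[s:s + ln]) + seq[s + ln:]
            bps.append((s, s + ln))
        genomes[strain] = GenomeRecord(strain_id=strain, sequence=seq, circular=True)
        origins[strain] = origin
        breakpoints[strain] = bps
    return genomes, GenomeTruth(origin_position=origins, breakpoints=breakpoints)


# ---------------------------------------------------------------------------
# Alignment records with known gap-compressed divergences


def simulate_alignment_records(
    n_reads: int,
    divergence_values: Sequence[float],
    seed: int,
    n_events: int = 250,
    target_id: str = "ref",
) -> tuple[list[AlignmentRecord], dict[str, str], dict[str, float]]:
    """Reads whose recomputed gap-compressed divergence is known exactly.

    Each read gets ``n_events`` gap-compressed events, of which
    ``round(d * n_events)`` are bad (mismatch runs or indel runs, each
    counting once); the realized divergence k/n_events is recorded as
    truth and differs from the requested value by at most 1/(2*n_events).
    ``divergence_values`` is cycled over the reads.
    """
    if n_reads < 0:
        raise ValueError("n_reads must be non-negative")
    for d in divergence_values:
        if not 0.0 <= d < 0.5:
            raise ValueError(f"divergence {d} outside [0, 0.5)")
    records: list[AlignmentRecord] = []
    sequences: dict[str, str] = {}
    truth: dict[str, float] = {}
    for i in range(n_reads):
        read_id = f"READ{i + 1:05d}"
        rng = child_rng(seed, "read", read_id)
        d = divergence_values[i % len(divergence_values)]
        k_bad = int(round(d * n_events))
        n_match = n_events - k_bad
        if n_match < k_bad + 1:
            raise ValueError(f"divergence {d} too high for {n_events} events")
        seg = np.ones(k_bad + 1, dtype=int)
        seg += rng.multinomial(n_match - (k_bad + 1), np.full(k_bad + 1, 1 / (k_bad + 1)))
        runs: list[tuple[str, int]] = []
        for j in range(k_bad + 1):
            runs.append(("=", int(seg[j])))
            if j < k_bad:
                kind = rng.choice(["X", "I", "D"], p=[0.6, 0.2, 0.2])
                length = 1 if kind == "X" else int(rng.integers(1, 4))
                runs.append((str(kind), length))
        nm = sum(n for op, n in runs if op in ("X", "I", "D"))
        qlen = sum(n for op, n in runs if op in ("=", "X", "I"))
        sequences[read_id] = "".join(rng.choice(list("ACGT"), size=qlen))
        records.append(AlignmentRecord(
            read_id=read_id,
            target_id=target_id,
            event_runs=runs,
            edit_distance=nm,
            mapped=True,
        ))
        truth[read_id] = k_bad / n_events
    return records, sequences, truth


# ---------------------------------------------------------------------------
# Whole-dataset generation


@dataclass
class SimTruth:
    """Complete truth manifest of one simulated dataset."""

    seed: int
    pav_truth: pd.DataFrame
    gene_events: dict[str, dict]
    variable_columns: dict[str, set[int]]
    class_truth: dict[str, str]                      # family -> planted class
    family_names: dict[str, str]
    origin_position: dict[str, int]
    breakpoints: dict[str, list[tuple[int, int]]]
    read_divergences: dict[str, float]


@dataclass
class SimulatedDataset:
    """Everything one pipeline run consumes, plus its truth manifest."""

    tree: StrainTree
    gene_sets: dict[str, list[str]]
    alignments: dict[str, dict[str, str]]            # family -> strain -> row
    proteomes: dict[str, SeqRecordSet]               # strain -> protein records
    genomes: dict[str, GenomeRecord]
    reads: list[AlignmentRecord]
    read_sequences: dict[str, str]
    truth: SimTruth

    def strains(self) -> list[str]:
        return self.tree.leaf_labels()


#: Planted effector-like families get annotation names so the name-pattern
#: report stage has something to find.
EFFECTOR_NAMES = ("TomO_homolog", "WalE1_homolog", "CifA_homolog")


def simulate_dataset(
    seed: int,
    n_strains: int = 8,
    n_clades: int = 2,
    n_core: int = 220,
    n_accessory: int = 80,
    gain_rate: float = 3.0,
    loss_rate: float = 1.0,
    protein_length: int = 180,
    p_secreted: float = 0.10,
    p_membrane: float = 0.10,
    n_reads: int = 300,
    intergenic_mean: int = 300,
    skew_amplitude: float = 0.6,
    origin_position: float = 0.25,
    rearrangement_spec: Optional[Sequence[dict]] = None,
    gene_length: int = 600,
) -> SimulatedDataset:
    """Generate the bundled strain-set simulation with full ground truth.

    Defaults emulate the study conditions at desk scale: 8 strains in two
    clades, 300 gene families (most core, a clade-patterned accessory
    fraction), ~20% of families carrying secretion/membrane features, and
    variable-site counts that are low for ordinary families but high for
    secreted/membrane ones.
    """
    tree = sample_strain_tree(n_strains, n_clades, seed)
    gene_sets, content_truth = simulate_gene_content(
        tree, n_core, n_accessory, gain_rate, loss_rate, seed
    )
    families = list(content_truth.pav.index)

    class_truth: dict[str, str] = {}
    family_names: dict[str, str] = {}
    variable_columns: dict[str, set[int]] = {}
    alignments: dict[str, dict[str, str]] = {}
    secreted_pool: list[str] = []
    for fam in families:
        rng = child_rng(seed, "class", fam)
        u = rng.random()
        if u < p_secreted:
            klass = SECRETED
        elif u < p_secreted + p_membrane:
            klass = MEMBRANE
        else:
            klass = OTHER
        class_truth[fam] = klass
        if klass == SECRETED:
            secreted_pool.append(fam)
    for name, fam in zip(EFFECTOR_NAMES, secreted_pool):
        family_names[fam] = name

    for fam in families:
        rng = child_rng(seed, "sites", fam)
        root_raw = "".join(
            child_rng(seed, "root", fam).choice(list(AMINO_ACIDS), size=protein_length)
        )
        root, _klass, protected = plant_protein_features(root_raw, class_truth[fam], seed=hash_seed(seed, fam))
        exclude = set()
        for lo, hi in protected:
            exclude.update(range(lo, hi))
        if class_truth[fam] == OTHER:
            n_var = int(rng.geometric(0.5)) - 1          # median ~0-1 variable sites
        else:
            n_var = int(rng.poisson(14.0)) + 1           # feature-bearing families vary more
        n_var = min(n_var, protein_length - len(exclude))
        present = content_truth.pav.loc[fam]
        carriers = {s for s in present.index if present[s]}
        if len(carriers) < 2:
            n_var = 0  # variation cannot be realized in a single-copy family
        aln, cols = simulate_family_alignment(
            fam, tree, protein_length, n_var, seed,
            root_sequence=root, exclude_columns=exclude, leaves=carriers,
        )
        alignments[fam] = aln
        variable_columns[fam] = cols

    proteomes: dict[str, SeqRecordSet] = {}
    for strain in tree.leaf_labels():
        recs = []
        for fam in gene_sets[strain]:
            gene_id = f"{strain}|{fam}"
            recs.append(FastaRecord(id=gene_id, description=family_names.get(fam, ""),
                                    sequence=alignments[fam][strain]))
        proteomes[strain] = SeqRecordSet(records=recs, alphabet="protein")

    genomes, genome_truth = assemble_genomes(
        gene_sets,
        intergenic_mean=intergenic_mean,
        skew_amplitude=skew_amplitude,
        origin_position=origin_position,
        rearrangement_spec=rearrangement_spec,
        seed=seed,
        gene_length=gene_length,
    )

    div_rng = child_rng(seed, "divergences")
    divergences = [
        float(div_rng.uniform(0.0, 0.03)) if div_rng.random() < 0.8
        else float(div_rng.uniform(0.05, 0.12))
        for _ in range(n_reads)
    ]
    reads, read_seqs, read_truth = simulate_alignment_records(
        n_reads, divergences, seed
    )

    truth = SimTruth(
        seed=seed,
        pav_truth=content_truth.pav,
        gene_events=content_truth.events,
        variable_columns=variable_columns,
        class_truth=class_truth,
        family_names=family_names,
        origin_position=genome_truth.origin_position,
        breakpoints=genome_truth.breakpoints,
        read_divergences=read_truth,
    )
    return SimulatedDataset(
        tree=tree,
        gene_sets=gene_sets,
        alignments=alignments,
        proteomes=proteomes,
        genomes=genomes,
        reads=reads,
        read_sequences=read_seqs,
        truth=truth,
    )


def hash_seed(seed: int, *names: object) -> int:
    """Stable sub-seed below 2^31 for APIs that take a plain integer."""
    from zlib import crc32

    out = int(seed) * 2654435761
    for name in names:
        out = out * 2654435761 + crc32(str(name).encode())
    return out % (2 ** 31)


def write_dataset(dataset: SimulatedDataset, outdir) -> None:
    """Serialize inputs + truth manifest (FASTA/Newick/SAM/PAF/TSV/JSON)."""
    out = Path(outdir)
    (out / "alignments").mkdir(parents=True, exist_ok=True)
    (out / "proteomes").mkdir(exist_ok=True)
    (out / "truth").mkdir(exist_ok=True)

    with open(out / "tree.nwk", "w") as fh:
        fh.write(dataset.tree.newick() + "\n")
    genome_records = [
        FastaRecord(id=s, description="circular", sequence=g.sequence)
        for s, g in sorted(dataset.genomes.items())
    ]
    write_fasta(out / "genomes.fasta", SeqRecordSet(genome_records, "nucleotide"))
    for strain, recs in sorted(dataset.proteomes.items()):
        write_fasta(out / "proteomes" / f"{strain}.faa", recs)
    for fam, rows in sorted(dataset.alignments.items()):
        recs = [FastaRecord(id=f"{s}|{fam}", description="", sequence=rows[s])
                for s in sorted(rows)]
        write_fasta(out / "alignments" / f"{fam}.afa", SeqRecordSet(recs, "protein"))
    tlen = max(
        (sum(n for op, n in r.event_runs if op in "=XD") for r in dataset.reads),
        default=1000,
    )
    write_sam(out / "reads.sam", dataset.reads, dataset.read_sequences, {"ref": tlen})
    write_paf(out / "reads.paf", dataset.reads, dataset.read_sequences, {"ref": tlen})

    t = dataset.truth
    t.pav_truth.astype(int).to_csv(out / "truth" / "pav.tsv", sep="\t")
    pd.DataFrame(
        [(fam, ",".join(map(str, sorted(cols)))) for fam, cols in sorted(t.variable_columns.items())],
        columns=["family", "variable_columns"],
    ).to_csv(out / "truth" / "variable_columns.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(t.class_truth.items()), columns=["family", "class"]
    ).to_csv(out / "truth" / "classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(t.read_divergences.items()), columns=["read", "divergence"]
    ).to_csv(out / "truth" / "read_divergences.tsv", sep="\t", index=False)
    summary = {
        "seed": t.seed,
        "strains": dataset.strains(),
        "n_families": int(len(t.pav_truth)),
        "clade_labels": dataset.tree.clade_labels,
        "origin_position": t.origin_position,
        "breakpoints": {s: [list(bp) for bp in bps] for s, bps in t.breakpoints.items()},
        "family_names": t.family_names,
        "gene_events": t.gene_events,
    }
    with open(out / "truth" / "truth.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
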