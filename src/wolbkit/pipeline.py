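"""End-to-end orchestration: simulate/ingest -> filter -> genome stats ->
orthogroups -> secretome classes -> entropy -> synteny, from one config.

Every stage parameter defaults to the value documented in its module; a
config file (YAML key/value tree) can override them and unknown keys are
rejected.  Identical config + seed produces byte-identical table outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import entropy as entropy_mod
from . import genome_stats, io_formats, orthology, read_filter, secretome, simulate, synteny

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "genome-stats", "orthogroups", "classify",
          "entropy", "synteny")

_SIM_KEYS = {
    "n_strains", "n_clades", "n_core", "n_accessory", "gain_rate", "loss_rate",
    "protein_length", "p_secreted", "p_membrane", "n_reads", "intergenic_mean",
    "skew_amplitude", "origin_position", "rearrangement_spec", "gene_length",
}


class DependencyError(RuntimeError):
    """A stage is enabled but its upstream inputs are missing."""


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "pipeline_out"
    stages: tuple[str, ...] = STAGES
    inputs: Optional[str] = None            # dataset directory when not simulating
    sim: dict = field(default_factory=dict)
    divergence_threshold: float = 0.04
    dedup_key: str = "id"
    window: int = 10_000
    step: int = 1_000
    min_score: float = orthology.DEFAULT_MIN_SCORE
    k_protein: int = orthology.DEFAULT_K
    k_synteny: int = synteny.DEFAULT_K
    max_occurrence: int = synteny.DEFAULT_MAX_OCCURRENCE
    max_gap: int = synteny.DEFAULT_MAX_GAP
    min_anchors: int = synteny.DEFAULT_MIN_ANCHORS
    entropy_threshold: float = 0.0
    min_coverage: int = entropy_mod.DEFAULT_MIN_COVERAGE
    effector_patterns: tuple[str, ...] = ("TomO", "WalE1", "Cif")
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [s for s in self.stages if s not in STAGES]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {STAGES}")
        bad = set(self.sim) - _SIM_KEYS
        if bad:
            raise ValueError(f"unknown simulate parameters {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys {sorted(bad)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        if "effector_patterns" in data:
            data["effector_patterns"] = tuple(data["effector_patterns"])
        return cls(**data)


def load_dataset(indir) -> simulate.SimulatedDataset:
    """Read a dataset directory in the layout written by
    :func:`wolbkit.simulate.write_dataset` (the truth manifest is optional
    and is not loaded)."""
    indir = Path(indir)
    genomes = {}
    for rec in io_formats.read_fasta(indir / "genomes.fasta", "nucleotide"):
        genomes[rec.id] = genome_stats.GenomeRecord(
            strain_id=rec.id, sequence=rec.sequence, circular=True
        )
    proteomes = {}
    for faa in sorted((indir / "proteomes").glob("*.faa")):
        proteomes[faa.stem] = io_formats.read_fasta(faa, "protein")
    alignments: dict[str, dict[str, str]] = {}
    for afa in sorted((indir / "alignments").glob("*.afa")):
        rows = {}
        for rec in io_formats.read_fasta(afa, "protein"):
            strain = rec.id.split("|", 1)[0]
            rows[strain] = rec.sequence
        alignments[afa.stem] = rows
    reads = io_formats.read_alignment_records(indir / "reads.sam", "sam")
    tree_obj = io_formats.read_newick(indir / "tree.nwk")
    labels = sorted(lf.taxon.label for lf in tree_obj.leaf_node_iter())
    tree = simulate.StrainTree(tree=tree_obj, clade_labels={s: "?" for s in labels})
    gene_sets = {
        s: sorted(rec.id.split("|", 1)[1] for rec in proteomes[s]) for s in proteomes
    }
    return simulate.SimulatedDataset(
        tree=tree, gene_sets=gene_sets, alignments=alignments,
        proteomes=proteomes, genomes=genomes, reads=reads,
        read_sequences={}, truth=None,  # type: ignore[arg-type]
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order; returns the run report."""
    logging.basicConfig(level=config.log_level,
                        format="%(levelname)s %(name)s: %(message)s")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "parameters": dataclasses.asdict(config),
                    "stages": {}}
    dataset: Optional[simulate.SimulatedDataset] = None
    orthogroups: Optional[list[orthology.Orthogroup]] = None
    og_alignments: dict[str, dict[str, str]] = {}
    protein_classes: dict[str, secretome.ProteinClassification] = {}
    og_classes: dict[str, str] = {}

    def need_dataset(stage: str) -> simulate.SimulatedDataset:
        if dataset is None:
            raise DependencyError(
                f"stage {stage!r} needs simulated or ingested inputs; enable "
                f"'simulate' or set config.inputs"
            )
        return dataset

    for stage in STAGES:
        if stage not in config.stages:
            continue
        t0 = time.perf_counter()
        logger.info("[%s] starting", stage)
        info: dict = {}

        if stage == "simulate":
            dataset = simulate.simulate_dataset(seed=config.seed, **config.sim)
            simulate.write_dataset(dataset, out / "sim")
            info = {"n_strains": len(dataset.strains()),
                    "n_families": len(dataset.truth.pav_truth),
                    "n_reads": len(dataset.reads)}
        elif stage == "filter":
            if dataset is None and config.inputs:
                dataset = load_dataset(config.inputs)
            ds = need_dataset(stage)
            deduped, n_dup = read_filter.dedup_reads(
                [(r.read_id, ds.read_sequences.get(r.read_id, r.read_id)) for r in ds.reads],
                key=config.dedup_key,
            )
            kept_ids = {rid for rid, _ in deduped}
            records = [r for r in ds.reads if r.read_id in kept_ids]
            retained, frep = read_filter.filter_by_divergence(
                records, threshold=config.divergence_threshold
            )
            frep.n_duplicates_removed = n_dup
            frep.n_input += n_dup
            frep.check()
            pd.DataFrame(
                [(r.read_id, read_filter.gap_compressed_divergence(r)) for r in retained],
                columns=["read", "divergence"],
            ).to_csv(out / "reads_retained.tsv", sep="\t", index=False, float_format="%.6f")
            pd.DataFrame([dataclasses.asdict(frep)]).to_csv(
                out / "filter_report.tsv", sep="\t", index=False
            )
            info = dataclasses.asdict(frep)
        elif stage == "genome-stats":
            if dataset is None and config.inputs:
                dataset = load_dataset(config.inputs)
            ds = need_dataset(stage)
            summaries = [genome_stats.genome_summary(g)
                         for _, g in sorted(ds.genomes.items())]
            pd.DataFrame(summaries).to_csv(out / "genome_summary.tsv", sep="\t",
                                           index=False)
            (out / "tracks").mkdir(exist_ok=True)
            for strain, g in sorted(ds.genomes.items()):
                track = genome_stats.windowed_profile(
                    g, metric="gc_skew", window=min(config.window, len(g)),
                    step=min(config.step, len(g)), deviation=True,
                )
                io_formats.write_track(out / "tracks" / f"{strain}.gcskew.tsv", track)
            info = {"n_genomes": len(ds.genomes)}
        elif stage == "orthogroups":
            ds = need_dataset(stage)
            strains = sorted(ds.proteomes)
            orthogroups = orthology.infer_orthogroups(
                ds.proteomes, min_score=config.min_score, k=config.k_protein
            )
            io_formats.write_orthogroup_table(
                out / "orthogroups.tsv",
                orthology.orthogroups_to_table(orthogroups, strains),
            )
            pav = orthology.build_pav(orthogroups, strains)
            pav.counts.to_csv(out / "pav_counts.tsv", sep="\t")
            pav.presence.astype(int).to_csv(out / "pav_presence.tsv", sep="\t")
            scos = orthology.extract_scos(orthogroups, strains)
            seq_by_gene = {
                rec.id: rec.sequence for p in ds.proteomes.values() for rec in p
            }
            for og in orthogroups:
                members = [(g, seq_by_gene[g]) for g in og.gene_ids()]
                og_alignments[og.og_id] = orthology.align_orthogroup(members)
            sco_alignments = []
            for og in orthogroups:
                if og.og_id in scos:
                    rows = {g.split("|", 1)[0]: row
                            for g, row in og_alignments[og.og_id].items()}
                    sco_alignments.append((og.og_id, rows))
            if sco_alignments:
                matrix, partitions = orthology.export_supermatrix(sco_alignments, strains)
                recs = [io_formats.FastaRecord(id=s, description="", sequence=matrix[s])
                        for s in strains]
                io_formats.write_fasta(out / "sco_supermatrix.fasta",
                                       io_formats.SeqRecordSet(recs, "protein"))
                pd.DataFrame(partitions, columns=["og_id", "start", "end"]).to_csv(
                    out / "sco_partitions.tsv", sep="\t", index=False
                )
            info = {"n_orthogroups": len(orthogroups), "n_sco": len(scos)}
        elif stage == "classify":
            ds = need_dataset(stage)
            if orthogroups is None:
                raise DependencyError("stage 'classify' needs the 'orthogroups' stage")
            rows = []
            for strain in sorted(ds.proteomes):
                for rec in ds.proteomes[strain]:
                    cls = secretome.classify_sequence(rec.id, rec.sequence)
                    protein_classes[rec.id] = cls
                    rows.append({
                        "gene": rec.id,
                        "signal_peptide": cls.has_signal_peptide,
                        "n_tm_segments": len(cls.tm_segments),
                        "class": cls.klass,
                        "evidence": cls.evidence_source,
                    })
            pd.DataFrame(rows).to_csv(out / "protein_classes.tsv", sep="\t", index=False)
            og_rows = []
            for og in orthogroups:
                klass, tally = secretome.classify_orthogroup(
                    protein_classes[g].klass for g in og.gene_ids()
                )
                og_classes[og.og_id] = klass
                og_rows.append({"og_id": og.og_id, "class": klass, **{
                    f"n_{k.replace('-', '_')}": v for k, v in tally.items()}})
            pd.DataFrame(og_rows).to_csv(out / "orthogroup_classes.tsv", sep="\t",
                                         index=False)
            info = {"n_membrane": sum(1 for c in og_classes.values() if c == secretome.MEMBRANE),
                    "n_secreted": sum(1 for c in og_classes.values() if c == secretome.SECRETED)}
        elif stage == "entropy":
            ds = need_dataset(stage)
            if not og_alignments or not og_classes:
                raise DependencyError("stage 'entropy' needs 'orthogroups' and 'classify'")
            profiles = []
            names = {}
            desc_by_gene = {
                rec.id: rec.description for p in ds.proteomes.values() for rec in p
            }
            for og_id, rows in sorted(og_alignments.items()):
                if len(rows) < 2:
                    continue
                profiles.append(entropy_mod.entropy_profile(
                    rows, og_id=og_id,
                    variable_threshold=config.entropy_threshold,
                    min_coverage=config.min_coverage,
                ))
                labels = sorted({d for g in rows if (d := desc_by_gene.get(g, ""))})
                names[og_id] = labels[0] if labels else og_id
            summary = entropy_mod.summarize_variability(profiles, og_classes)
            pd.DataFrame(
                [(p.og_id, og_classes[p.og_id], p.alignment_length, p.n_variable,
                  p.fraction_variable) for p in profiles],
                columns=["og_id", "class", "length", "n_variable", "fraction_variable"],
            ).to_csv(out / "variability.tsv", sep="\t", index=False, float_format="%.6f")
            pd.DataFrame(
                [(k, summary.class_counts[k], summary.class_medians.get(k, float("nan")))
                 for k in sorted(summary.class_counts)],
                columns=["class", "n_orthogroups", "median_n_variable"],
            ).to_csv(out / "variability_summary.tsv", sep="\t", index=False)
            pd.DataFrame(summary.histogram, columns=["n_variable", "class", "count"]
                         ).to_csv(out / "variability_histogram.tsv", sep="\t", index=False)
            eff = entropy_mod.effector_report(profiles, config.effector_patterns, names)
            pd.DataFrame(eff, columns=["og_id", "name", "n_variable",
                                       "alignment_length", "percent_variable"]
                         ).to_csv(out / "effector_report.tsv", sep="\t", index=False)
            info = {"medians": summary.class_medians,
                    "n_zero_variable": summary.n_zero_variable}
        elif stage == "synteny":
            ds = need_dataset(stage)
            strains = sorted(ds.genomes)
            if len(strains) < 2:
                raise DependencyError("stage 'synteny' needs at least two genomes")
            a, b = strains[0], strains[1]
            ga, gb = ds.genomes[a], ds.genomes[b]
            anchors = synteny.kmer_anchors(ga, gb, k=config.k_synteny,
                                           max_occurrence=config.max_occurrence)
            blocks = synteny.chain_anchors(anchors, max_gap=config.max_gap,
                                           min_anchors=config.min_anchors)
            primary = synteny.select_primary_blocks(blocks)
            bps = synteny.breakpoint_report(primary, (len(ga), len(gb)),
                                            collinear_tolerance=config.max_gap)
            synteny.anchors_to_table(anchors, a, b, len(ga), len(gb)).to_csv(
                out / "synteny_anchors.tsv", sep="\t", index=False)
            synteny.blocks_to_table(blocks).to_csv(
                out / "synteny_blocks.tsv", sep="\t", index=False)
            pd.DataFrame(bps, columns=["position_a", "left_block", "right_block",
                                       "strand_change"]).to_csv(
                out / "synteny_breakpoints.tsv", sep="\t", index=False)
            info = {"pair": [a, b], "n_anchors": len(anchors),
                    "n_blocks": len(blocks), "n_breakpoints": len(bps)}

        info["wall_seconds"] = round(time.perf_counter() - t0, 3)
        report["stages"][stage] = info
        logger.info("[%s] done in %.2fs", stage, info["wall_seconds"])

    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=str)
    return report


# ---------------------------------------------------------------------------
# Optional online replication against deposited assemblies

EFETCH = ("https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
          "?db=nuccore&id={acc}&rettype=fasta&retmode=text")


def replicate_online(accessions: Sequence[str], workdir,
                     expected: Optional[dict] = None, timeout: float = 60.0) -> dict:
    """Fetch deposited assemblies and recompute genome summaries.

    Requires network access; any fetch failure downgrades the report to
    status "skipped" with a warning instead of raising.  ``expected`` maps
    accession -> {"length_bp": ..., "gc_percent": ...} for comparison.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    if not accessions:
        return {"status": "no-op", "genomes": {}}
    results: dict = {"status": "ok", "genomes": {}}
    for acc in accessions:
        dest = workdir / f"{acc}.fasta"
        try:
            if not dest.exists():
                with urllib.request.urlopen(EFETCH.format(acc=acc), timeout=timeout) as resp:
                    data = resp.read()
                if not data.startswith(b">"):
                    raise IOError(f"unexpected response for {acc}")
                dest.write_bytes(data)
            recs = io_formats.read_fasta(dest, "nucleotide")
            genome = genome_stats.GenomeRecord(
                strain_id=acc, sequence=recs.records[0].sequence, circular=True
            )
            summary = genome_stats.genome_summary(genome)
            entry: dict = {"summary": summary}
            if expected and acc in expected:
                exp = expected[acc]
                entry["matches_expected"] = all(
                    summary.get(key) == exp[key] for key in exp
                )
            results["genomes"][acc] = entry
        except Exception as exc:  # noqa: BLE001 - network failures skip, never fail
            logger.warning("replicate-online: %s failed (%s); skipping", acc, exc)
            results["status"] = "skipped"
            results.setdefault("reason", str(exc))
    return results
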