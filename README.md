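# wolbkit

Comparative genomics of small circular endosymbiont genomes — the
*Wolbachia*-style strain comparison, reimplemented as a testable pipeline.

Endosymbionts like *Wolbachia* carry highly mosaic ~1.3 Mb genomes whose
strain-to-strain differences (gene presence–absence, rapidly evolving
secreted effectors, genome rearrangements) underlie host manipulation
phenotypes. Comparing a newly assembled strain against its relatives
involves a standard sequence of analyses, each usually delegated to a
different external tool. `wolbkit` implements that sequence as one
library + CLI, with a simulator that generates strain sets with fully
known ground truth so every stage is verifiable without downloads:

1. **Read hygiene** (`read_filter`) — duplicate removal and a divergence
   filter on read-to-reference alignments using the *gap-compressed
   mismatch ratio* r = (mismatches + gap opens) / (matches + mismatches +
   gap opens), each indel run counting once; reads with r > 0.04 are
   removed (the boundary itself is retained — the rule is strictly
   "exceeding").
2. **Genome statistics** (`genome_stats`) — length, GC%, and windowed
   GC-skew (G−C)/(G+C) profiles of circular genomes, optionally as the
   deviation from the genome-wide average; the skew sign flip localizes
   the replication origin.
3. **Orthology** (`orthology`) — reciprocal-best-hit orthogroups over a
   k-mer multiset-Jaccard similarity, presence–absence (PAV) matrices
   with copy counts, single-copy ortholog (SCO) extraction, center-star
   orthogroup alignment, and SCO supermatrix export with a partition
   table. OrthoFinder-style tables can be ingested instead.
4. **Secretome** (`secretome`) — the classification rule: signal peptide
   + transmembrane segment ⇒ *membrane-bound*; signal peptide only ⇒
   *secreted*; otherwise *other*. Evidence comes from external predictor
   tables (SignalP/TMHMM-style) or built-in Kyte–Doolittle hydropathy
   heuristics.
5. **Entropy** (`entropy`) — per-column Shannon entropy
   H = −Σ p_a log₂ p_a of orthogroup alignments (gaps excluded), variable
   sites (H > 0 by default), class-wise medians and histograms, and a
   name-matched effector report (TomO / WalE1 / Cif-style).
6. **Synteny** (`synteny`) — exact k-mer anchors (dotplot), greedy
   collinear-block chaining, and breakpoint reporting with circular
   wrap handling.
7. **Simulator** (`simulate`) — strain trees with clade ("supergroup")
   structure, gene gain/loss, planted variable columns, planted
   signal/transmembrane features, circular genomes with an imposed skew
   origin and rearrangements, and alignment records with known
   divergences — all recorded in a truth manifest.

## Worked example

Run the bundled analyses (each regenerates the same seeded dataset and
writes tables under `results/`):

```sh
python analysis/01_simulate_strains.py
python analysis/06_entropy_variability.py
```

The entropy step prints, for 8 simulated strains × 300 gene families:

```
families profiled          : 287
variable-count mismatches  : 0 (vs planted truth)
zero-variable families     : 115 (excluded from the histogram)
median variable sites      :
  all             1 (n=287)
  membrane-bound  14.5 (n=22)
  other           1 (n=234)
  secreted        15 (n=31)
effector-like families     :
  TomO_homolog    16 of 180 sites (~9%)
  WalE1_homolog   15 of 180 sites (~8%)
  CifA_homolog    16 of 180 sites (~9%)
```

Reading this: every planted variable-site count was recovered exactly;
ordinary families have a median of 1 variable site while
secreted/membrane families are an order of magnitude more variable —
the signature the analysis is designed to expose — and the named
effector-like families report their variable fraction as a percentage
of the full alignment length.

The same stages run from the shell via the `wolbkit` CLI
(`wolbkit simulate`, `filter-reads`, `genome-stats`, `orthogroups`,
`classify-proteins`, `entropy`, `synteny`, `run`), and `wolbkit run
--config cfg.yaml` executes the whole pipeline from one config file.
`wolbkit replicate-online` optionally fetches deposited assemblies
(e.g. CP157591.1) to recompute their summaries; it requires network
access and degrades to a reported skip without it.

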