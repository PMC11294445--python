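# Methods

This note documents the models and procedures `wolbkit` implements, the
parameters that matter, what the simulator does and does not emulate, and
the numerical choices made where the design was genuinely open. No
empirical claim is made here beyond what the test suite and
`scripts/acceptance.py` compute.

## Gap-compressed divergence filter

Reads aligned to a reference are scored by the gap-compressed mismatch
ratio

    r = (n_mismatch + n_gap_opens) / (n_match + n_mismatch + n_gap_opens)

where every insertion or deletion *run* contributes one event regardless
of length — the "gap-compressed per-base divergence" convention of
modern aligners, which keeps long indels (common in nanopore data and in
repeat regions) from dominating the score. Reads with r strictly greater
than the threshold (default 0.04) are removed; the boundary value is
retained, reading the removal rule literally as "exceeding". The
threshold is configurable.

When the CIGAR resolves mismatches (`=`/`X` operations) the counts are
taken directly. When it does not (plain `M` runs), mismatches are
inferred from the NM edit distance as `NM − inserted − deleted bases`;
under this inference path all match-run columns remain in the
denominator (so 100 aligned columns + NM-implied 2 mismatches + 1
deletion run give r = 3/103). Records offering neither route are
*divergence-indeterminate* and are dropped with a warning rather than
assumed perfect — failing safe, since such reads cannot be vouched for.
A read is judged by its primary alignment only; secondary and
supplementary lines are ignored.

## GC statistics

GC content is (G+C)/(A+C+G+T) with IUPAC ambiguity codes excluded from
numerator and denominator (excluding them is unbiased; counting N as
half-GC is not). GC skew per window is (G−C)/(G+C); windows with no G or
C record a missing value rather than zero. Windowed profiles default to
window 10,000 bp / step 1,000 bp — smooth at the ~1.3 Mb scale of these
genomes — and both are plain configuration, not claims about any
upstream tool's settings. With `deviation=true` the genome-wide value is
subtracted per window (the "deviation from average" track of circular
genome maps), which makes the count-weighted track sum to zero. Windows
wrap on circular sequences; a wrapped window serializes as two BED-like
lines sharing a window id. Reported GC% is rounded half-up to two
decimals. The skew sign flip is localized as the midpoint between
adjacent windows of opposite sign; on a genome with a replication-origin
skew structure two flips appear (origin and terminus).

## Orthology

The similarity score between two proteins is the multiset Jaccard index
of their amino-acid k-mer counts (k = 4). Per ordered strain pair, each
protein nominates its best-scoring partner with score ≥ `min_score`
(default 0.2 — permissive at congeneric-strain divergence; ties broken
by lexicographically smallest gene id); reciprocal nominations become
edges and orthogroups are connected components, with unclustered genes
kept as singletons. This replaces MCL-style graph clustering because the
downstream statistics need only a strain→gene partition, and externally
computed orthogroup tables can be ingested for fidelity. Inference is
order-invariant: batch best-hit search uses an inverted k-mer index that
computes exactly the pairwise score, and orthogroup ids are assigned
after canonical sorting.

Orthogroup alignments use the center-star construction: the member with
the greatest summed similarity to the rest is the center; every other
member is aligned to it globally (match +1, mismatch −1, gap open −2,
gap extend −1, via Biopython's PairwiseAligner) and merged under
once-a-gap-always-a-gap. Center-star has bounded error relative to an
optimal sum-of-pairs alignment and is trivially testable on small cases;
precomputed alignments are accepted wherever alignments are consumed.
Single-copy orthologs (exactly one gene in every strain) concatenate
into a per-strain supermatrix with a partition table of column
intervals; tree inference itself is out of scope.

## Secretome classification

The rule is total and evidence-driven: signal peptide and ≥1
transmembrane segment ⇒ membrane-bound; signal peptide and none ⇒
secreted; no signal peptide ⇒ other. Segments overlapping the predicted
signal region do not count — signal peptides are themselves hydrophobic
and would otherwise promote every secreted protein to membrane-bound.

External predictor tables always override the built-in heuristics, and
the evidence source is recorded per protein so mixing is never silent.
The built-in heuristics operate on centered moving averages of
Kyte–Doolittle hydropathy:

* **Signal peptide** — a positively charged residue in the first five
  positions, then ≥7 consecutive positions within the first 25 whose
  7-residue mean exceeds 1.6; cleavage at the first small residue
  (A/G/S) in positions 18–35.
* **Transmembrane segment** — a maximal run of ≥15 consecutive positions
  whose 19-residue mean exceeds 1.6; runs closer than 5 residues merge.

The 1.6 threshold is the classic hydropathy cutoff for membrane-spanning
character at window 19. These heuristics are deliberately transparent
stand-ins for neural/HMM predictors: adequate for planted features and
desk-scale testing, not competitive on real proteomes — which is what
the external-table path is for.

Orthogroup-level labels aggregate member classes by majority vote with
ties broken membrane-bound > secreted > other (the aggregation rule for
orthogroup-level presence–absence displays is not standardized anywhere;
this one is explicit, deterministic and configurable, and vote tallies
are retained). Both per-strain-protein and per-orthogroup classification
paths are supported.

## Entropy and variable sites

Column entropy is H = −Σ_a p_a log₂ p_a over the 20 amino acids, in bits
(base 2 is the sequence-conservation convention; the base only matters
if the variable-site threshold is nonzero). Gaps and X are excluded from
frequencies, and a column with fewer than 2 scoring residues is
undefined and never variable — preventing indel-rich columns from being
called variable off a single residue. A *variable site* is a column with
entropy strictly above the threshold, default 0 (i.e. ≥2 observed
states); the threshold is first-class configuration so stricter
definitions can be re-run. Summaries report per-class orthogroup counts
and medians (even-count medians are means of the central order
statistics, so half-integer medians are representable), a histogram
excluding zero-variable orthogroups (counted separately), and a
name-pattern report for effector-like families whose variable fraction
is shown as a whole percent of the full alignment length, gap columns
included.

## Synteny

Anchors are maximal runs of exact shared k-mers (k = 15) between two
genomes, both strands of the target; k-mers occurring more than 4 times
on the forward strand of either genome are discarded (IS-element-rich
genomes otherwise blow up the anchor set), and merged runs shorter than
k+5 are dropped as chance matches — an isolated k-mer hit between
megabase-scale sequences is overwhelmingly noise, while genuine homology
extends past k. Minus-strand anchors report forward-strand coordinates
of the reverse-complemented interval; all coordinates are 0-based
half-open.

Chaining is greedy over anchors in genome-a order with several chains
open at once (so short spurious anchors cannot interrupt a real
collinear run): an anchor extends a chain when strand matches, both
coordinates are strictly monotone (decreasing in b on the minus strand),
and inter-anchor gaps lie within [−50, max_gap] bp in both genomes —
the small negative bound permits junction overrun by chance matches
while forbidding the large interval overlaps that characterize false
joins. Chains with fewer than `min_anchors` (3) anchors are kept only if
they carry ≥200 anchored bases, since near-identical genomes legitimately
collapse whole collinear regions into a single long anchor.

Breakpoints are junctions between adjacent non-overlapping blocks
(circular adjacency included) where the strand changes or the
b-coordinates fail to continue within tolerance modulo the genome
length; a collinear block split across the circular origin therefore
does not surface as a rearrangement, which is how circularity is
handled throughout (in place of internally doubling one genome). Where
mosaic genomes produce overlapping candidate blocks, a greedy
maximum-anchored-bases selection yields the one-to-one tiling that
breakpoint analysis requires. An inversion of length above `max_gap`
yields exactly two strand-change breakpoints, each within k−1 bp of the
true coordinate (the resolution limit of exact anchors).

## The simulator and what passing tests mean

The simulator generates the study conditions at desk scale with complete
ground truth, seeded so identical parameters and seed give byte-identical
outputs (sub-streams are derived by stable hashing of entity names, never
iteration order).

* **Tree** — random-join bifurcating clades (within-clade branch scale
  0.01 expected substitutions/site) joined by a random-join backbone with
  clade stems of 0.05 + Exp(0.05), emulating supergroup-structured
  divergence. Defaults: 8 strains, 2 clades.
* **Gene content** — 220 core + 80 accessory families. Each accessory
  family is gained once on a branch drawn ∝ 1 − exp(−gain_rate·length)
  (gain_rate 3; gain_rate 0 degenerates to a root gain) and lost at most
  once per branch below it with probability 1 − exp(−loss_rate·length)
  (loss_rate 1), no regain. The event log is recorded, making PAV
  recomputable by traversal.
* **Family alignments** — proteins of 180 residues; substitutions
  (uniform over the other 19 amino acids) are placed only in designated
  variable columns, each forced to realize ≥2 states among the strains
  carrying the family, so recovered variable-site counts can be compared
  to truth exactly. Ordinary families draw Geometric(0.5)−1 variable
  sites (median ≈ 1); secreted/membrane families draw 1 + Poisson(14) —
  reproducing the low-background / variable-effector contrast the
  analysis is meant to expose. Three secreted families receive effector
  annotation names for the name-pattern report.
* **Protein features** — signal peptide: residues 1–22 hydrophobic
  ({L,I,V,F}, excluding A so the cleavage site stays unambiguous) with a
  charged residue at position 2 and serine at the cleavage site;
  transmembrane: 19 residues from {L,I,V} with mildly polar {S,T,G}
  flanks. The strongly hydrophobic core plus flanks guarantees — by a
  worst-case window calculation — a detection run of ≥15 positions for
  every random draw, which a broader alphabet does not. Polar buffer
  zones follow each feature and accidental hydrophobic runs in the
  background are scrubbed below the detection threshold, so planted
  class labels are recoverable by construction.
* **Genomes** — shared per-family gene sequences (600 bp, GC 0.35,
  skew-neutral) in fixed family order with intergenic spacers
  (Poisson mean 300 bp) whose G/C probabilities are gc/2·(1 ±
  skew_amplitude), the sign flipping at the planted origin fraction and
  its antipode. Spacers are keyed by the preceding family rather than by
  strain, so strains with identical content assemble byte-identical
  genomes and planted inversions between such twins have exactly
  recoverable breakpoints. Default amplitude 0.6 gives a windowed skew
  signal roughly six times its sampling noise at window 4 kb.
* **Reads** — each read is a run-length event list with
  round(d·n_events) bad events (60% mismatch runs, 40% indel runs of
  1–3 bp) out of n_events = 250, so the true gap-compressed divergence
  is known to within 1/(2·n_events); reads serialize to both SAM and
  PAF with NM tags.

What the simulator does **not** emulate: realistic nanopore error
profiles, codon structure, recombination, paralogous gene families,
rate heterogeneity among lineages, repeat-driven rearrangement hotspots,
or genuinely hard secretome cases (marginal hydrophobicity, lipoprotein
signals). Passing the closed-loop tests therefore demonstrates that each
stage computes its statistic correctly and recovers what was planted
under controlled conditions — not that the heuristics match dedicated
predictors, or the anchor-chaining matches full aligners, on real data.
The external-table and table-ingestion paths exist precisely for real
inputs.

## Pipeline

`run_pipeline` executes simulate/ingest → filter → genome-stats →
orthogroups → classify → entropy → synteny from one config whose
defaults equal the values documented above; unknown config keys are
rejected. All table outputs are deterministically ordered, and two runs
with the same config and seed are byte-identical (the JSON run report,
which carries wall-clock times, is the only exception). The optional
online replication subcommand fetches deposited assemblies and
recomputes their length/GC summaries; any fetch failure downgrades to a
reported skip, never an error, so offline environments are unaffected.

## Problem sizes

Bundled analyses and the acceptance script use 6–8 strains, 300 gene
families, 180-residue proteins, ~0.22 Mb genomes, and 300–1,000 reads —
sizes chosen so the full suite and all analyses re-run from scratch in
about a minute while every statistic of interest remains measurable at
its native scale (medians over hundreds of families, breakpoints at
single-bp resolution, ARI over ~2,000 genes).
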