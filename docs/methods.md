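# Methods

## The network model

Nodes are genes (official symbols, upper-cased).  A directed edge
*A* ⊣ *B* states that gene *A* hosts an intragenic pre-miRNA whose mature
form has *B* among its validated targets.  Validation is the intersection
of two independent interaction tables: a (mature miRNA, target) pair is
kept only if both sources report it.  Mature miRNA identifiers are matched
case-insensitively and otherwise exactly — no -3p/-5p collapsing — because
distinct mature forms of one precursor are biologically distinct
regulators.  A mature miRNA deriving from precursors in several host genes
contributes an edge from every such host; the attribution is recorded in
the network's provenance table and is the package's resolution of a
genuinely ambiguous situation (a mature form cannot be traced back to the
transcript it was actually excised from without expression data).

Simplification order is: self-loops removed (but recorded in a side table,
since a gene targeted by its own intragenic miRNA is a meaningful
self-regulatory motif), parallel edges merged with miRNA labels unioned,
isolated nodes dropped.  This order makes the degenerate case of a host
targeted only by its own miRNA well defined: the loop is removed first,
then the node is dropped as isolated.  All summary counts (node roles,
miRNA/precursor/host counts) refer to the simplified graph and to miRNAs
that induce at least one retained edge.

Networks can be built for all intragenic miRNAs or for intronic-sense
miRNAs only.  Since the class filter only removes annotations, the
restricted network's edges — and, by the monotonicity of strong
connectivity under edge addition, its core — are contained in the full
network's.

## Core extraction

The core is the union of all strongly connected components with at least
two nodes; the two-node threshold is a fixed definition, not a parameter.
Components are reported largest-first, ties broken by the
lexicographically smallest member, so reports are reproducible.  SCCs come
from networkx's standard decomposition; the test suite checks it against a
brute-force pairwise-reachability oracle on hundreds of random graphs.

## Triad census

Motif statistics use the *induced* classification: every unordered node
triple is assigned to one of the 16 isomorphism classes of three-node
digraphs (standard 003…300 nomenclature, where the digits count mutual,
asymmetric and null dyads).  The production counter is networkx's
implementation of the edge-based Batagelj–Mrvar algorithm, which completes
on graphs of ~10⁴ nodes without enumerating all ~10¹¹ triples; the sparse
classes (003, 012, 102) are completed arithmetically so the census
identity Σ counts = C(n, 3) always holds.  An independent brute-force
counter — full triple enumeration against a 64-entry canonical code table
built in-package by permutation canonicalisation of hand-written class
representatives — serves as the oracle and is guarded at 300 nodes.
A secondary counter reports not-necessarily-induced embeddings for
sensitivity checks of the induced convention.

The three figure-bound motif shapes are registered as configurable
constants rather than hard-wired, because their adjacency patterns are
defined by drawings, not prose.  Defaults: `FIG2C = "102"` (mutual dyad
plus disconnected spectator — the only class whose count scales as
(#mutual dyads) × (#non-adjacent third nodes), matching a count in the
tens of thousands on a sparse ~8,500-node graph with a handful of
reciprocal pairs); `FIG2A = "111U"` (mutual dyad with an out-edge, a rare
reciprocity-driven shape whose excess survives out-degree conditioning);
`FIG2B = "030T"` (the feed-forward triple, the classic
Erdős–Rényi-overrepresented motif).  `configure_figure_motifs` re-points
any of them.

## Null models and Monte Carlo testing

Two null models are matched to an observed network:

* **directed G(n, m)**: exactly m loop-free directed edges uniform over
  ordered pairs.  Sampling draws distinct pair indices (directly for small
  capacity, by rejection at large capacity and low density; both uniform).
* **fixed out-degree**: node k keeps its observed out-degree N_k, and its
  target set is uniform over all C(n−1, N_k) subsets of the other nodes.
  Sampling takes the first N_k entries of a Fisher–Yates shuffle of
  {0,…,n−2} and shifts indices ≥ k by one so the source never targets
  itself.  This model is the network equivalent of shuffling each hosted
  miRNA's target list while preserving its length.

Significance uses the add-one estimator p = (r + 1)/(N + 1) with an
explicit tail per test: upper for motif over-representation, lower for a
core smaller than random expectation.  The estimator can never return less
than 1/(N + 1) (≈ 9.999 × 10⁻⁵ at the customary N = 10,000 replicates).
Replicate j draws its generator from a counter-based seed stream
(`SeedSequence(seed, spawn_key=(j,))`), so results are bit-reproducible
and independent of generation order.  Replicate statistics are streamed,
not retained.

## Expression ranking and enrichment

Quartiles use linear interpolation between order statistics (the numpy
default); the convention matters little for stratum membership of
well-separated genes and is recorded here.  Expression variance is the
Q3/Q1 ratio, defined only for Q1 > 0; for positive transcripts its ranking
coincides with the log-scale IQR ranking (exactly so when the quartiles
fall on order statistics, where the monotone log transform commutes with
the quantile).  Before variance ranking, the transcriptome is reduced to
the upper half by Q1 (cutoff ⌊total/2⌋, "first"-method ranks for
determinism), which also guarantees Q1 > 0 for retained transcripts.

Stratum membership ranks transcripts by the chosen statistic (descending
for "top"), assigns average ranks to ties, and counts gene-set members
with rank ≤ ⌊fraction × total⌋ — the floor makes the count conservative.
Genes absent from the matrix are excluded from n and reported, mirroring
how cohort platforms measure only a subset of core genes.  The enrichment
p-value is the exact binomial upper tail Σⱼ₌ₖⁿ C(n,j) qʲ(1−q)ⁿ⁻ʲ, computed
in full precision and rounded only for display.

## Cohort dichotomization and signatures

A dichotomization scheme has three time parameters (months): event horizon
h, control minimum follow-up c ≥ h, and an early-event exclusion e.  The
event class is recurrence with time in (e, h]; the control class is
recurrence-free with follow-up ≥ c; unknown status and early events are
excluded, and everything else is the grey zone.  Presets:
colorectal (h = 36, c = 48, e = 1) and breast (h = 60, c = 84, e = 0).

Classifiers are linear-kernel SVMs (C = 1 by default; the cost is exposed
because no principled value is singled out, and the analysis is assessed
by planted-signal recovery, not by exact weight reproduction) with class
weights inversely proportional to class sizes.  Expressions are scaled to
zero mean and unit standard deviation (sample SD, ddof = 1) using
*training-cohort statistics only*; filtration and validation cohorts are
transformed with the same scaler, so no information leaks out of training.
The risk score is R = w·e − ρ; R ≥ 0 assigns high risk (the boundary is
deliberately in the high-risk group).  Sensitivity is the detected
fraction of the event class, specificity the low-risk fraction of
controls, and the AUC is the tie-corrected rank statistic of R (constant
scores give exactly 0.5).

The exhaustive search enumerates gene subsets lexicographically (the
result is order-invariant), discards candidates with training sensitivity
or specificity below 0.60, then discards survivors whose sensitivity or
specificity drops below 0.50 on *any* filtration cohort — the thresholds
are conjunctive per cohort and per metric.  Survivors are sorted by the
arithmetic mean of the per-cohort AUCs over training plus filtration
cohorts, ties broken by gene tuple.  Validation metrics are computed on
the dichotomized (non-grey) part of the validation cohort; Kaplan–Meier
curves and the two-tailed log-rank test use all validation patients with
follow-up, since survival curves extend beyond the dichotomization
horizon.  Cross-validation is stratified, seeded, and refits both the
scaler and the SVM inside every fold; when folds equal the patient count
it degrades to leave-one-out.

## Synthetic data: what it emulates and what it does not

* `simulate_annotations` wires each planted cycle [g₁…g_k] as gᵢ hosting an
  intronic-sense miRNA targeting g_{i+1}, and adds background host→target
  records that respect a random topological order among non-core genes, so
  the planted cycles are provably the *only* nontrivial SCCs and
  core-recovery tests are exact rather than probabilistic.  Both target
  tables carry every real interaction plus a few source-unique decoys that
  the two-database intersection must discard.  One background miRNA in
  five is exonic/antisense so the class filter has work to do.
* `simulate_expression` is log-normal: background transcript locations
  μᵢ ~ N(1, 0.75) (log units) with scales sᵢ ~ U(0.5, 1.5); planted genes
  get μᵢ + shift and sᵢ × dispersion factor.  The default shift of 2 log
  units against the 0.75 location spread makes a planted gene land in the
  top median-expression quartile with probability ≈ 0.98, so a 12-gene
  planted set reaches ≥ 10/12 members in the top quarter in ≥ 95% of
  replicates — the regime the recovery suite asserts.  A log-normal, not a
  count model, suffices because every downstream quantity is a quantile
  rank, insensitive to count-level noise.
* `simulate_cohorts` draws uninformative N(0, 1) expression for all genes,
  shifts the planted signature genes between classes by stated per-gene
  amounts (signs may differ, emulating oppositely directed expression
  changes), and draws event times inside the scheme's event window,
  control follow-up beyond the control minimum with exponential spread
  (scale 24 months), and grey-zone times between the two rules for a
  stated fraction of patients.

These generators reproduce the *statistical structure* each stage assumes,
not the biology: no sequence features, no seed-match logic, no genomic
coordinates, no correlated co-expression between background genes, no
platform effects.  Passing recovery tests therefore demonstrates that the
algorithms detect the structure they are specified to detect at the stated
effect sizes — not that real databases or cohorts contain such structure.

## Problem sizes in the test and acceptance suites

Oracle-equivalence suites use 200 random graphs (≤ 60 nodes for the
census, ≤ 50 for the core).  Planted-recovery suites use 100 expression
replicates (5,000 transcripts × 100 samples), 300 null-calibration
replicates at 2,000 × 20, and 50 signature replicates (cohorts of
200/150/150/150 patients, a 10-gene universe).  Monte Carlo demonstrations
use 200 replicates on 300-node graphs, plus a single 10,000-replicate run
on a toy graph to exhibit the estimator floor.  These sizes were chosen to
give the recovery assertions comfortable statistical margins while keeping
a full run in the minutes range on one CPU; the full-scale defaults
(10,000 replicates) remain the package defaults.

## Known limitations

* The figure-bound motif constants are plausibility-based defaults; an
  analysis against a concrete published network should set them explicitly
  from the source figures via `configure_figure_motifs`.
* Gene-symbol namespaces drift between database releases; the readers
  upper-case symbols and accept a user-supplied synonym map but do not
  resolve symbol history across genome builds.
* The fixed-out-degree model conditions on out-degrees only; in-degree-
  preserving or degree-pair-preserving (edge-swap) randomisations are out
  of scope.
* Exact reproduction of published database-derived counts requires the
  original frozen snapshots and cohort series, which the package does not
  download; the synthetic generators stand in for them.
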