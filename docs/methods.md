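# Methods

## Model and assumptions

The screen assumes that anti-CRISPR genes are recognizable not by sequence
but by context: short proteins, in short and sparsely annotated directons,
adjacent (upstream, in transcription order) to an HTH-domain gene, inside
virus-derived sequence of genomes under pressure to silence their own
CRISPR-Cas (self-targeting). None of these signals is individually
decisive, so they are combined by an ensemble of extremely randomized
trees over a 12-feature vector per protein. The ensemble is the standard
extra-trees algorithm (random thresholds over random feature subsets,
splits chosen by weighted Gini impurity, 1 − Σ pᵢ²); the backend is
scikit-learn's `ExtraTreesClassifier` with its default split
randomization, wrapped in the `AcrForest` estimator. A candidate's score
is the mean over trees of the positive-class *weight* fraction in its
leaf, so scores live in [0, 1] and inherit the example weighting.

Directon segmentation treats a gap of exactly 100 bp as still
co-directional (the bound is inclusive) and clamps overlapping same-strand
genes to gap 0 — overlap is stronger, not weaker, evidence of
co-transcription. Coordinates are 1-based inclusive throughout; BED export
converts to 0-based half-open. Directons never span contigs, and circular
contigs are not wrapped.

## Weighting

Known Acr families are few and wildly unequal in membership, and negative
sets are built by random sampling, so three weighting schemes matter:

- positives: weight 1 per family, split evenly over subfamilies
  (sequence-similarity clusters), then over members — Σ per family = 1;
- negatives: one representative per cluster at weight 1, then the whole
  class scaled so Σw(neg) = Σw(pos) (rebalancing is idempotent);
- candidate summaries: each predicted Acr weighs 1/n of its cluster.
  The per-cluster variant (1/n_c split over members) differs only by a
  global constant, so weighted means are identical under both; both are
  implemented and the identity is tested.

All evaluation metrics (ROC-AUC, balanced accuracy, precision/recall) are
weighted with the same weights. The weighted AUC equals weighted pairwise
concordance with ties counted half, which the tests verify against an
O(n²) enumeration oracle.

## Evaluation protocol

Cross-validation folds partition Acr *families*, not proteins (3 folds,
5 repetitions, 15 AUCs), because the question is whether unseen families
are detectable, not unseen members of seen families. Negatives are
re-randomized across folds in every repetition (the protocol for them is
genuinely open; re-randomizing gives slightly more conservative variance
estimates and is seeded). Significance uses a permutation test on scores:
p = (1 + n_p)/(N + 1) with N = 1000, so the attainable floor is
1/1001 ≈ 0.001. Binary thresholds maximize weighted balanced accuracy by
default — under class rebalancing plain accuracy is nearly equivalent,
and it remains available as an option. Candidate thresholds are the
midpoints between consecutive distinct scores (plus the extremes), ties
resolved toward the lowest threshold.

## Search space and cascade

Provirus detection is deliberately loose: any directon with a pVOG hit at
e ≤ 1e−4, plus its immediate neighbor directons, merged into blocks when
≤ 500 bp apart (inclusive, mirroring the 100 bp convention); a block with
two viral hits whose gene midpoints are within 3 kb is a predicted
prophage. Midpoint distance is the default because block membership, not
exact provirus boundaries, is what the pipeline consumes; edge-to-edge is
a parameter. Prokaryotic assemblies without a CRISPR-Cas system are
excluded from the search space entirely.

Cascade stage order is hallmarks → mean directon size → prokaryotic
homolog count → virus enrichment → HHblits count, with per-stage survivor
counts recorded. The numeric cutoffs default to 5 / 374 / 3 / 52 but are
learnable from any positive set by the ten-threshold search: exactly ten
evenly spaced thresholds spanning [min, max] of the positive values (both
endpoints included, linspace convention), scored by the cascade's
balanced accuracy (mean of the fraction of positives kept and the
fraction of candidates removed), ties resolved toward the most stringent
threshold. A family with zero provirus homologs fails the ratio test
unless the virus-hit override applies. Known-Acr removal uses strict
e < 1e−3.

E-value thresholds follow the `1e−4` / `5e−3` / `1e−6` / `1e−3` readings
of the conventional shorthand; all are keyword arguments so stricter
literal readings can be tested.

## Sequence statistics

Hydropathy is the mean Kyte–Doolittle value over standard residues
(non-standard letters skipped with a warning). The isoelectric point is
found by bisection of the Henderson–Hasselbalch net-charge curve under
EMBOSS pKa values (N-term 8.6, C-term 3.6; K 10.8, R 12.5, H 6.5, D 3.9,
E 4.1, C 8.5, Y 10.1) to |charge| < 1e−4; sequences whose charge curve
never crosses zero return 7.0 with a warning. Consensus sequences pick,
per alignment column, the residue maximizing the summed BLOSUM62 score
against the column (gaps ignored, ties alphabetical).

## Feature selection

The genetic algorithm is generational with population 50, tournament
size 3, uniform crossover at rate 0.5, bit-flip mutation at rate 0.1,
elitism 2, run for 10 generations; fitness is mean family-grouped CV
weighted AUC of a small forest on the masked features. These internals
are package choices (only the generation count is externally fixed) and
all are parameters. The selected 8-feature subset is also available as
the constant `FINAL_MODEL_FEATURES` so pipelines can skip the GA.

## Synthetic data

The generator targets *feature-space* statistics, not sequence realism.
Class-conditional means are the published ones (Acr vs background:
length 104.11/245.54 aa, directon mean length 119.27/251.71, directon
size 3.49/3.5, hydropathy −0.48/−0.15, annotated 0.064/0.673,
HTH-downstream 0.401/0.118, self-targeting 0.334/0.192, membrane
0.026/0.278, spacing 18.37/13.7). Where only means are published, the
spreads are package choices, fixed once: log-normal lengths with
log-SD 0.6 (matching the reported SD ≈ 0.66 × mean of predicted Acr
lengths), hydropathy SD 0.5 (the reported weighted SD), Beta(μ·4, (1−μ)·4)
for directon annotated fraction, shifted Poisson for directon size, and
mild family-level random effects (log-length SD 0.15, hydropathy SD 0.1,
mean-corrected) so family-grouped CV is non-trivial. Protein sequences
are random residues: uniform draws give a mean Kyte–Doolittle value of
≈ −0.49 (the Acr mean), and background sequences draw from the
hydrophobic subset with probability 0.0955 to shift the mean to −0.15.

Genome-level fixtures plant Acr directons (1–3 short genes plus an
Aca-like HTH gene) directly beside a pVOG-hit directon, so the
search-space stage recovers them; self-targeting assemblies carry one
spacer copied verbatim from their own contig among random decoys. The
planted-family cascade fixture mirrors the magnitudes of the real
filtering funnel: background clusters are mostly small (mean ≈ 3.8
members) with background hallmark rates, so roughly 95% of them fail the
hallmark stage, while planted families are larger (mean ≈ 6) with
known-Acr hallmark rates and homolog profiles (few prokaryotic homologs,
prokaryote/provirus ratio mostly ≤ 3, few HHblits annotations).

Passing tests on these fixtures show that the implementation recovers
structure it was designed to detect when that structure is present at the
published effect sizes. They do not show performance on real genomes:
real features are correlated in ways the generator does not model
(length and annotation status, directon statistics shared among
neighbors), real negatives are not i.i.d., and real Acr families are far
from feature-space Gaussians. Published headline numbers (CV AUC 0.93,
test AUC 0.83, precision 78% / recall 57%, score threshold 0.09, the
232,616 → 2,500 filtering funnel) depend on a curated positive set and a
182M-protein database and are not reproducible at desk scale; the test
suite instead checks the analytically forced values and the qualitative
recovery behaviour.

## Problem sizes and numerics

Default experiment sizes are chosen for single-CPU runs: 500/500 training
matrices, 100–1000 trees, 1000 permutations, 50/500 planted cascade
fixtures, 1000-contig property sweeps. Every stochastic operation takes a
mandatory seed and records it in its manifest; pipeline reruns with the
same seed are byte-identical. Gini impurity validates that fractions sum
to 1 within 1e−9; weighted SD uses the frequency-weight (population)
convention; degenerate inputs (single-class nodes, empty directons,
all-gap columns, no predicted positives) either return documented
conventions or raise.

## Known limitations

- No gene calling, CRISPR array detection, or HMM/profile searching:
  external tool output is ingested as tables. `greedy_cluster` is a
  deterministic k-mer stand-in for real sequence clustering, adequate for
  fixtures only.
- Self-targeting uses exact spacer matches with no PAM/adjacency logic.
- The presence–absence matrix orders columns by Jaccard similarity with
  average-linkage leaf ordering; other orderings are defensible.
- Membrane association is ingestion-only (the feature is outside the
  final model).
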