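# Methods

`tcellgrn` re-implements, as one reusable pipeline, a multi-stage discovery
procedure for condition-specific transcriptional regulators in CD4+ T-cell-like
expression compendia. The chain is: preprocessing → sample-structure analysis →
differential expression → co-expression modules → consensus network inference →
hub extraction and candidate prioritization → regulon/target filtering. A
synthetic generator plants a fully known regulatory and condition structure so
every stage is verifiable by recovery.

## The synthetic data model

The generator emulates log2-scale microarray intensities. Genes come in three
kinds: transcription factors (TFs), their targets, and a background population
below detection. Defaults: 10 TFs, 90 targets, 50 background genes, three
labelled conditions ("resting", "activated", "lineage") with 20 samples each.

* **TF profiles.** Each TF has a condition-dependent baseline plus N(0, σ)
  sample noise (σ = 0.3 log2 units). Non-lineage TFs sit at the signal
  baseline (9.0) everywhere and receive a mild boost (`modulation_offset`,
  1.0) in one preferred condition — expressed everywhere, modulated somewhere,
  like most real TFs. The *lineage TF* is on/off: at the background floor
  (6.0) except in the lineage condition, where it reaches baseline + 2.0. This
  asymmetry makes exactly one module strongly condition-private, which is the
  structure the discovery procedure targets (a FOXP3-like regulator and its
  hidden MEOX1-like target).
* **Targets.** Each target draws 1–3 regulators and responds linearly:
  x_target = baseline + Σ_tf effect · (x_tf − baseline) + N(0, σ), with
  effects uniform in ±[0.8, 1.6] (negative with probability 0.25). The hidden
  target has exactly one incoming edge, from the lineage TF, with a positive
  effect, so its regulator is unambiguous.
* **Nuisance structure.** Each gene is measured by duplicated probes
  (gene profile + N(0, 0.05), ids `GENE_p1…`), samples belong to batches with
  per-gene batch offsets N(0, 0.5), and background genes fluctuate around the
  floor. The floor (6.0) and baseline (9.0) mirror typical log2 microarray
  intensity scales.

What the generator does **not** emulate: count noise of sequencing data,
single-cell dropout, probe cross-hybridization, nonlinear or combinatorial
regulation, feedback loops (the planted graph is a two-layer DAG), and
correlated batch-by-condition confounding. Passing recovery tests therefore
demonstrates the pipeline's correctness under a linear-Gaussian regime that
satisfies the assumptions of all five inference engines; they do not guarantee
performance on data violating those assumptions.

All randomness flows through one seeded generator per call; the seed fully
determines every output file byte for byte.

## Preprocessing

Quantile normalization forces every sample onto the per-rank mean
distribution; within-column ties receive the mean reference value of the ranks
they occupy, which makes the operation idempotent and deterministic. The
background threshold τ is estimated by fitting a two-component Gaussian
mixture to per-gene mean expression and taking the point between the component
means where the posterior responsibility flips; when Ashman's D < 2 the modes
are not separable and the 10th percentile of gene means is used instead (the
original study reports only a dataset-wide scalar, 7.183, from an unspecified
coefficient-of-variation procedure, so the estimator here is a documented
replacement that reproduces the observable — a single threshold between floor
and signal — rather than a guess at the formula). A gene is kept when it
exceeds τ in at least one sample; duplicated probes collapse to the probe with
the highest mean (ties: lexicographically smallest probe id); batch centering
shifts each batch's per-gene mean onto the gene's grand mean. Missing values
are rejected at load rather than imputed.

## Sample structure

PCA is the mean-centered SVD with signs fixed by the largest-magnitude loading
entry. The condition correlation matrix (CCM) is the pairwise Pearson
correlation of per-condition mean profiles; it is standardized matrix-wide and
its rows clustered with Euclidean distance. The linkage method is average
(UPGMA) by default — the tree is cut at a user-chosen cluster count rather
than by an automatic stopping rule. K-means model selection minimizes the
Davies–Bouldin index over a k range with seeded restarts. The fold-change
convention is signed linear: FC = 2^Δ for Δ ≥ 0, −2^(−Δ) otherwise, so the
classical gate |FC| > 2 is exactly |Δ| > 1 in log2 units.

## Differential expression

Two-group contrasts use the pooled-variance Student t (not Welch); multi-group
designs use fixed-effects two-way ANOVA with condition and batch, no
interaction, and type-II sums of squares by least squares on the dummy-coded
design (condition and batch are the only two annotations available per sample,
and batch is the nuisance preprocessing worries about). Multiplicity is
handled by Benjamini–Hochberg; the DE gate is strict on both sides
(|FC| > 2 and q < 0.05). UpSet accounting bins every gene of the union into
exactly one exclusive membership pattern.

## Co-expression modules

Modules follow the weighted co-expression recipe: unsigned soft-thresholded
adjacency a_ij = |cor|^β with β = 15, topological overlap
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 − a_ij), average-linkage
clustering of 1 − TOM, a static cut at height 0.99, and iterative merging of
clusters smaller than `minModuleSize` (10) into the best-correlated large
module by eigengene correlation; irreducible leftovers go to module 0. The
static cut replaces dynamic tree-cut heuristics — a documented
simplification. The module eigengene is the unit-norm first right-singular
vector of the gene-standardized submatrix, oriented to correlate non-negatively
with the module's mean standardized profile. β = 15 presumes the strong
correlations of array compendia; small noisy datasets need a lower power
(the pipeline raises a clear error when no module survives).

The self-organizing map uses online training with a Gaussian neighborhood
whose radius decays linearly from max(grid)/2 to 0.5 and a learning rate
decaying 0.05 → 0.01, prototypes initialized deterministically on the grid
spanned by the first two principal loadings, and seed-controlled sample order.
The per-node "eigenvalue" summary is the mean profile of member genes.

GSEA uses the weighted Kolmogorov–Smirnov statistic with weight exponent 1;
a set containing every ranked gene has an empty miss pool and scores 0 by
definition. NES divides ES by the mean |ES*| of same-sign permutations;
p = (1 + #{same sign, |ES*| ≥ |ES|})/(n_same + 1). The null is built by
sample-label permutation when the expression matrix and labels are provided
(the statistic is recomputed per permutation) and by gene-label permutation
otherwise — the function operates on a precomputed ranking, so gene
permutation is the default that needs no extra inputs. The ranking metric is
the pooled t of a cluster-vs-rest contrast. Permutations default to 1,000
(configurable; pipeline stages use smaller counts, see problem sizes below).

## Network inference

Mutual information uses a plug-in estimator on rank-transformed, equal-width
binned data (B = clamp(round(n^{1/3}), 3, 16) bins), in bits. Rank binning
makes MI exactly invariant under strictly monotone per-gene transforms and
keeps the estimator oracle-checkable; absolute MI values will differ from
kernel or adaptive estimators, so rank-level agreement is the contract.
Significance comes from the G-statistic 2n·ln2·MI ~ χ²((B−1)²) or a
margin-permutation null.

* **ARACNe-style**: significance gate p < 0.05 (no Bonferroni), then the data
  processing inequality removes edge (i,j) when some third gene k has both
  (i,k) and (j,k) surviving and MI_ij < min(MI_ik, MI_jk)·(1 − 0.01); removals
  are decided against the gated graph and applied simultaneously, so the
  result does not depend on scan order.
* **TINGe-style**: every pair ranked by MI, no filtering.
* **CLR**: z = max(0, (MI_ij − μ_i)/σ_i) against the row background,
  score = sqrt(z_i(j)² + z_j(i)²).
* **GENIE3-style**: per target, a bagged random forest (√|regulators|
  candidate splits per node) predicts the target from the other regulators;
  the edge weight is the regulator's share of total impurity reduction
  (per-target weights sum to 1). This is the only directed method.
* **Pearson**: |r| ≥ 0.7.

## Consensus, hubs, MCL

Each method's edges carry fractional ranks (1 = strongest, ties averaged);
candidate pairs a method did not list receive the mid-rank of the unoccupied
positions, (L + 1 + E)/2 — the unbiased convention for unlisted edges.
Directed lists are symmetrized by max weight before ranking. The consensus
score is the mean rank across methods; the top K edges (ties at the boundary
broken lexicographically) form the network. Degree is unweighted; the top 20%
of nodes by degree are the hubs. MCL uses the canonical defaults (inflation
2.0, expansion 2), self-loops at the node's maximum incident weight, and reads
clusters off the weakly connected components of the converged matrix support.

## Prioritization and regulons

Hub genes intersected with a TF catalogue are ranked by (a) mean |Pearson r|
with a small training set of known regulators and (b) mean Jaccard similarity
of annotation-term sets, then combined by the Borda rule
(score = Σ_lists (N − position), averaged positions for ties, final ties by
gene id). The two similarity rankings are self-contained replacements for
external web prioritization services whose feature sets cannot be shipped;
the Borda combination step itself is preserved exactly. Among the prioritized
head (default 15) the most highly expressed candidates (default 6) are kept.
Regulon analysis scores each TF's promoter motif-hit genes against a gene set
by the one-sided hypergeometric tail with BH correction across TFs — a
self-contained analog of motif-collection enrichment scanners, taking the
boolean gene × TF hit table as its interface. Target filtering keeps module
genes that carry the TF's hit and pass |FC| > 1 strictly.

## Pipeline defaults and problem sizes

The orchestrated run writes every intermediate as TSV with a `# generated-by`
metadata line (stage, seed, parameter hash — no timestamps, so repeated seeded
runs are byte-identical). Stage defaults are sized for the default synthetic
compendium (300 probes × 60 samples): GENIE3 forests use 100 trees, GSEA 200
permutations, consensus keeps the top 500 edges. On larger compendia these
should be raised toward the classical settings (1,000 trees, 1,000–10,000
permutations, top 10,000 edges); all are flags. The acceptance script measures
recovery over 10 generator seeds (50 seeds for the chain-pruning check, 100
simulations for the null-FDR check, 5 full pipeline runs) — sizes chosen so a
complete desk-scale verification runs in minutes on one CPU.

## Numerical choices and degenerate inputs

Zero pooled variance in a t contrast yields t = 0, p = 1 for identical groups
and a floored variance (1e-12, with a warning) otherwise. Constant genes are
dropped from module detection and have zero MI against everything. A
zero-variance MI row contributes 0 to CLR. Probe-collapse and hub ties break
by id; consensus boundary ties break lexicographically. Quantile normalization
of a single-column matrix returns it unchanged with a warning. MCL
non-convergence within `max_iter` returns the current clustering with a
warning flag.

## Known limitations

* The background-threshold estimator is a replacement for an unrecoverable
  published procedure; only its observable (a dataset-wide scalar) matches.
* The static TOM tree cut finds well-separated modules; nested or overlapping
  module structure needs the dynamic cut this package deliberately omits.
* MI values are estimator-specific; cross-tool comparisons should use ranks.
* Outlier removal is an explicit id-list flag, never automated — the original
  study removed outliers by joint visual inspection with no numeric rule.
* t-SNE embeddings are visualization and are delegated to standard
  implementations rather than re-implemented.
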