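# Methods

This note documents the models, defaults and numerical choices behind
`cnpath`, and what the synthetic benchmarks do and do not demonstrate.

## Statistical preprocessing

Compound abundances are natural-log transformed (all observed values must
be positive; the offending cell is named otherwise). Missing values are
completed by **iterative rank-k SVD imputation**: missing cells start at
column means, and the matrix is alternately reconstructed at rank k
(default 3) and re-filled at the missing cells until the largest imputed
change falls below `tol` (1e-6) or 200 iterations. Observed cells are never
altered. This is a deterministic low-rank completion; it recovers exactly
low-rank matrices (a unit test plants a rank-1 matrix with holes) but, like
any low-rank method, it smears compound-specific effects that are not
shared across the matrix — the imputation error it leaves on strongly
treatment-shifted compounds is visible as inflated within-group variance.
Columns that are entirely missing, or ≥ 50% missing, are rejected.

Per-compound screening is a **one-factor ANOVA** over the genotype ×
treatment design cells (six cells in the default 2 × 3 design), with
Bonferroni adjustment over all compounds tested and significance at
adjusted p ≤ 0.05. Degenerate compounds (all cell means equal, zero
within-cell variance) get F = 0, p = 1. Post-hoc contrasts use **Tukey's
HSD** with a compact letter display computed by the insert-and-absorb
algorithm; groups are sorted by mean (ascending) before lettering, so "a"
always marks the lowest-mean clique, and ties are broken by group order.
The letters satisfy, and the tests assert, the defining invariant: two
groups share a letter exactly when their pairwise Tukey test is
non-significant.

**PCA** is centred and unscaled, computed by SVD, with a deterministic sign
convention (each loading column's largest-magnitude entry is positive).
The same conventions apply everywhere a first principal component is used,
including the genetic-algorithm objective — results would otherwise depend
on the SVD backend's arbitrary sign choices.

## Correlation networks

All compound pairs are Pearson-correlated; p-values use the exact
t-transform t = r·√((n−2)/(1−r²)) with n−2 degrees of freedom, two-sided,
and the full set of p(p−1)/2 tests is Benjamini–Hochberg adjusted (the
classical step-up; the pipeline delegates to statsmodels and the tests
re-derive the step-up by hand). Edges require **|r| ≥ r_min (0.8) and
q ≤ q_max (0.05)**. The threshold applies to the absolute correlation:
negative edges are biologically meaningful and are kept, with the sign
stored as an edge attribute. Perfectly collinear pairs get p = 0 and always
pass. Zero-variance compounds cannot be tested; their pairs are excluded
with a warning, but every compound remains a node of the network.

Network summaries: positive/negative edge counts, their ratio (reported as
`inf` when there are no negative edges, and excluded from numeric
comparisons in that case), edge density 2|E|/(|V|(|V|−1)), and average
weighted degree defined as the mean over *all* nodes (isolated included) of
the summed incident |r| — the unweighted mean degree is a different
quantity and is not used.

**Walktrap** community detection runs on |r| edge weights (the algorithm
requires nonnegative weights) with walk length 4, its canonical default;
the dendrogram is cut at maximum modularity and isolated nodes become
singleton communities. The procedure is seedless and deterministic given
the node order, and invariant to a global rescaling of the weights.

Cross-genotype comparison uses edge-set algebra with the unordered node
pair as edge identity: intersection, both differences and the symmetric
difference, each carrying its source network's edge attributes. The
counting identities |E_a| = |E_a∩E_b| + |E_a∖E_b| and
|E_a△E_b| = |E_a∖E_b| + |E_b∖E_a| are asserted on every pipeline run.

## Pathway-activity classification

A pathway is **mapped** as the intersection of its compound set with the
network's nodes, and is unmappable below 3 mapped members (a 2-node
subgraph has degenerate statistics). Each mappable pathway becomes an
11-dimensional descriptor of its footprint: mapped fraction and count;
induced-subgraph density, mean |r| and positive-edge fraction (0 when the
subgraph has no edges); largest-component fraction and normalised component
count; the fraction of member pairs sharing a walktrap community; mean
member degree and local clustering coefficient in the full network; and
mean pairwise shortest-path distance, with unreachable pairs set to the
network diameter + 1 (diameter = largest finite shortest path). Features
are permutation-invariant in member order and node labels. The published
analysis this follows does not print its feature list; this set was chosen
to capture density, cohesion, sign structure and community co-membership —
the quantities the downstream interpretation relies on.

Training instances are the known-active pathways (label 1) against
foreign/random pathways (label 2); random negative subsets are size-matched
to the positive size distribution so the classifier cannot key on size.
Feature selection keeps the top 6 features by total split gain of a
preliminary boosted model (constant features dropped first). The classifier
is xgboost with shallow trees (depth 3), learning rate 0.1, at most 200
rounds with early stopping (20 rounds) on the held-out fold's log-loss,
under stratified 10-fold CV; AUC, the 2 × 2 confusion matrix at threshold
0.5 (rows = predicted, columns = actual, label order 1, 2) and accuracy are
computed from out-of-fold probabilities, and the final model is refit on
all instances at the median per-fold best round count. All randomness runs
through one seed.

The **sensitivity analysis** retrains the final model's settings on
`reps` (default 100; the benchmarks use 25) stratified 80% subsamples of
the training instances and averages the predictions per test pathway. A
pathway is **validated** only when the original prediction and the
subsample mean both reach 0.5. Validated sets from two networks are
partitioned into shared / a-specific / b-specific.

## Genetic algorithm

The objective is |cor(PC1(Expr[·,C]), PC1(Pr[·,M]))| for a gene subset C
and pathway compound set M, with the PCA conventions above; the absolute
value makes it invariant to PC sign flips and to negating the expression
submatrix. The search is a canonical binary GA — the published source
states only the objective — fully parameterized in `GAConfig`: population
100, up to 200 generations, initialization probability 0.05 per bit (at
least one bit forced on), tournament selection (size 3), uniform crossover
(rate 0.8), per-bit mutation (default 1/n), elitism 2, stop after 30
stagnant generations. An optional per-gene fitness penalty (default 5e-4)
presses toward small gene sets; setting it to 0 reproduces the pure ARGMAX
and is what the correctness benchmarks use, so the GA and the exhaustive
oracle maximize the same quantity. Restricting the search to a candidate
gene set (e.g. one co-expression module) is supported and is how the
per-module analyses run; the pipeline's default prescreen keeps the genes
most correlated with the target pathway's PC1 when the universe is large.
Objective evaluations cache by chromosome and compute PC1 scores through
the n × n Gram matrix (n samples ≪ genes); the returned objective is
always re-evaluated through the reference implementation.

**Known limitation — subset recovery at small n.** With 18 samples the
sample Pearson correlation has substantial variance, and subsets of
roughly half a planted 75-gene module reach higher *in-sample* objectives
(≈ 0.99) than the full module (calibrated to 0.95) by fitting that
sampling noise. The argmax of the stated objective therefore genuinely
excludes part of the module: measured Jaccard overlap with the planted
module is ≈ 0.45–0.53, and strengthening the search (larger populations,
more generations) lowers it further while raising the objective. Gene
*lists* selected at this sample size should be read as signal-carrying but
not exhaustive; the objective value itself is recovered reliably (≥ 0.9 in
every benchmark run).

## Synthetic study generator

The generator emulates a 2-genotype × 3-treatment × 3-replicate design (18
samples), 139 metabolites + 195 lipids (334 compounds) and 4.4% missing
values — inserted completely at random as an exact floor(rate × cells)
count — plus a 2000-gene expression matrix. Compounds follow a
latent-factor model: one standard-normal factor per community per sample,
member value = loading × factor + noise (defaults: loading 0.9, noise sd
0.15, population within-block r ≈ 0.97), exponentiated to natural scale so
the log transform recovers it exactly. By default all metabolites form one
community and lipids split evenly over the remaining communities (five in
total), mirroring one-metabolite-plus-four-lipid-community structure.
Latent factors over a positive-definite covariance were chosen because the
block structure stays valid at any size.

Ten percent of compounds get planted treatment responses in two regimes:
two thirds are *mild* (one genotype × treatment cell shifted by
U(2, 3.9) × noise sd — real but below the Bonferroni detection floor, so
their community correlations survive), one third are *strong* (a whole
treatment shifted by U(60, 80) × noise sd in both genotypes — noncentrality
far beyond the Bonferroni critical value, so the ANOVA stage has guaranteed
true positives even after imputation smearing). The split is deliberate:
within-group variance is dominated by the community factor
(sd ≈ √(loading² + noise²) ≈ 0.91), so a shift must be huge on the noise
scale to be detectable, and compounds carrying such shifts necessarily
decorrelate from their community; keeping them to ~3% of compounds
preserves the planted correlation structure (> 90% of within-community
pairs at |r| ≥ 0.8 at defaults).

Pathway databases contain 38 positives (compound sets drawn within single
communities — "active" pathways) and 38 negatives (19 uniform random sets,
19 deliberately cross-community round-robin sets), sizes 4–12. The planted
gene module's genes are scaled copies of the target pathway's compound PC1
plus per-gene Gaussian noise whose scale is calibrated *by bisection
against the actually drawn noise* so the realised |cor(PC1(module),
PC1(pathway))| matches the requested value; a closed-form calibration fails
because with n ≪ module size the sample PC1 drops a weak factor entirely
(the spiked-covariance detection threshold). Background genes are
independent log-normal noise; a global shift keeps everything nonnegative
without touching correlations.

What the generator does **not** emulate: chromatography artifacts, batch
effects, isotope interference, heteroscedastic measurement error,
non-random missingness, or realistic pathway overlap/shared-compound
structure. Passing benchmarks therefore demonstrate correctness of the
algorithms under the stated statistical structure, not performance on real
instrument data.

## Benchmark problem sizes

The shipped benchmarks run at the full 334-compound, 18-sample scale. The
classifier benchmark averages over 5 generator seeds with 25 sensitivity
subsample repetitions; community recovery and the GA module benchmark use
3 seeds; brute-force network equivalence uses 20 random matrices up to 30
compounds × 12 samples; the GA-versus-enumeration check uses 20 instances
of 8 candidate genes (255 subsets each). These sizes keep the whole suite
to well under a minute of compute while leaving every assertion at full
statistical strength.
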