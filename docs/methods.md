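# Methods

`drynet` implements a desk-scale, fully testable version of a drought
multi-omics analysis workflow: differential screening of transcripts and
metabolites over a stress time course, temporal clustering of metabolite
profiles, and — at its core — bottom-up construction of a multi-layer
hierarchical gene regulatory network (ML-hGRN) above a metabolic-pathway
gene layer.  Because studies of this kind rarely deposit raw data, every
stage is exercised against seeded simulators that plant known structure,
so recovery can be scored exactly.

## The hierarchical GRN construction (BWERF)

The construction takes a base layer of pathway genes (e.g. flavonoid or
lipid biosynthesis structural genes) and a pool of candidate TFs, and
stacks regulatory layers bottom-up.

**Recursive random-forest elimination.**  For each target gene, a random
forest regresses the target's expression profile on all surviving
candidate TF profiles (impurity-decrease importances, normalized to sum
to one, `sqrt(m)` features per split).  After each fit the
`floor(drop_fraction * survivors)` (at least one) least important TFs
are eliminated and the forest is re-fit, down to a single survivor; with
`drop_fraction = 0.5` this is `ceil(log2 m)` rounds.  A TF's aggregated
importance for a target is the mean of its importances over the
iterations it survived; this avoids biasing against TFs eliminated early,
which still carry one recorded value.  The per-TF *pathway score* sums
aggregated importances over all targets.

Defaults: `drop_fraction = 0.1` (small steps trade runtime for ranking
stability), `n_trees = 1000`.  The planted-recovery experiments shipped
with the package run at `n_trees = 100` and `drop_fraction = 0.3`,
which keep a full two-layer build under a minute on one core with no
measurable loss of ranking quality at the simulated problem size
(50 TFs, 40 targets, 18 samples).  Layer-1 recovery at those settings
averages recall ~0.75 and precision ~0.55-0.65 over ten simulated
datasets; per-dataset selection size varies with the mixture fit, so
individual runs spread around those means.

**Gaussian-mixture layer selection.**  Pathway scores are fitted with a
two-component 1-D Gaussian mixture (EM, best of `n_init = 10` random
starts, variance floor 1e-10).  TFs whose posterior responsibility for
the higher-mean component is at least 0.5 form the layer immediately
above the targets.  If the two component means are numerically equal the
mixture carries no separation and the top half of TFs by score is
retained, with a warning.  The selected layer becomes the new target set
and the procedure repeats on the still-unplaced TFs; layers are disjoint
by construction.  Edges between adjacent layers keep, per target, the
`edges_per_target = 3` retained TFs of highest aggregated importance
(the edge weight).  An optional `max_layer_size` caps a layer at the
top scorers; it is off by default.

**Gene-metabolite links.**  Pearson correlation between gene and
metabolite profiles — by default on per-timepoint replicate means, since
transcriptome and metabolome samples come from parallel material rather
than shared extractions — retaining `|r| >= 0.8` with BH-adjusted
p < 0.05.  Networks export to SIF, GraphML and a node-attribute CSV for
Cytoscape.

**Null-control guard.**  Selecting the top mixture component and then
testing retained-vs-dropped separation on the *same* scores is
circular — and re-running the forest with a fresh seed on the same data
does not break the circle, because a TF that chance-correlates with the
targets in that dataset scores high in every pass.  The packaged null
control therefore rescores the candidates on an independent replicate
dataset and permutation-tests the original selection's separation on
those scores: with no planted regulation, TF identity carries nothing
across replicates and the permutation p-value is uniform.

## Differential expression screen

The screening criteria are |log2 fold change| >= 1 (boundary included)
with BH FDR < 0.05 (boundary excluded), per stress timepoint against the
day-0 control.  The underlying test is intentionally simple — the
package's subject is the screening logic and downstream inference, not
the DE engine, and externally computed (log2fc, p) tables can be fed
straight into `screen_degs`:

* median-of-ratios size factors (geometric-mean reference over genes
  positive in all samples, factors rescaled to geometric mean 1);
* a single NB dispersion shared across genes, pooled as the mean of
  per-gene method-of-moments estimates from within-group residuals and
  floored at 1e-8.  With n = 3 per group a per-gene moment estimate has
  ~4 degrees of freedom and a normal-reference Wald test built on it is
  badly anticalibrated (empirical type-I error ~0.11 at nominal 0.05);
  pooling across thousands of genes restores calibration (~0.05) and
  matches the shared-dispersion NB simulator;
* Wald z = log2FC / SE with delta-method SE from NB variance
  `mu + alpha mu^2` at the group means, pseudo-count 0.5 on normalized
  means, two-sided normal p-values.  All-zero genes report p = 1,
  log2FC = 0.

FPKM (`counts * 1e9 / (length * library size)`) and the 2^-ddCt relative
expression transform are provided for unit conversion and qPCR
comparison.

## Metabolite screen

Missing peak areas are imputed by k-nearest-neighbour averaging over
metabolite rows (k = 10): candidate neighbours are rows observed in the
target column, nearness is plain Euclidean distance over mutually
observed columns, and the imputed value is the 1/distance-weighted mean
of the k nearest neighbours' values in that column (zero-distance
neighbours share equal weight and take precedence).  Compounds with
pooled-QC coefficient of variation (sample sd / mean) not strictly below
0.5 are dropped.

OPLS-DA is a NIPALS O-PLS: X is unit-variance scaled (the dominant
metabolomics convention; the choice is configurable), `n_orthogonal = 1`
components orthogonal to the centered class vector are deflated from X,
then a single predictive component is extracted.  With unit-norm
predictive weights, VIP over the predictive component reduces to
`sqrt(p) * |w_j|`, so mean squared VIP is exactly 1.  A metabolite is
differentially accumulated when VIP > 1 (strict) and the ratio of
arithmetic group means of imputed intensities is >= 2 or <= 0.5 (both
inclusive).  A Welch t-test on log2 intensities with BH FDR is reported
alongside but does not gate the screen, which names only VIP and fold
change.

## Temporal clustering

Metabolite levels are collapsed to replicate means per timepoint and
z-scored per metabolite (constant profiles are dropped with a warning);
K-means with k-means++ initialization and Lloyd iterations (convergence
at centroid shift < 1e-8 or 300 iterations, best of 50 restarts by
inertia) groups accumulation patterns, defaulting to k = 8 as is typical
for drought time-course metabolomes.  Lloyd is run in-house so the
within-run inertia trace is available as an invariant check; results
match scikit-learn's KMeans inertia on the same data.

## Synthetic data: what it emulates, and what it does not

`simulate_hierarchy_expression` plants a two-layer TF hierarchy.
Layer-2 TFs follow independent random cubic-spline temporal trends (a
knot per timepoint) plus per-sample biological fluctuation; each
layer-1 TF is a standardized linear combination of the realized
per-sample profiles of 1-3 layer-2 parents plus its own per-tier noise;
each pathway gene likewise combines 1-3 layer-1 parents.  Decoy TFs are
pure iid noise with no planted edge, variance-matched to the signal
TFs.  A per-gene positive baseline keeps values non-negative while
leaving the linear structure exact (baselines and standardization
shifts are recorded in the truth object, so the zero-noise limit can be
checked as an identity).

Two aspects of this design carry the identifiability and are worth
stating explicitly:

* **Regulation acts within samples.**  The child responds to its
  parent's realized level in the same replicate plant, not only to the
  shared timepoint trend.  Were signals confined to the timepoint level,
  any two signal-carrying TFs would chance-correlate at |r| ~ 1/sqrt(T)
  ~ 0.33 for T = 6 timepoints — the same magnitude as true transmission
  — and no inference method could tell planted structure from
  coincidence.  Per-sample propagation opens an 18-dof channel that only
  true regulator-target pairs share (measured: true parents |r| ~ 0.5
  vs ~0.2 for grandparents and decoys at default noise).
* **Per-tier noise attenuates grandparent association**, which is what
  makes the *layers* (not just the edges) statistically tellable: a
  pathway gene reflects its layer-2 grandparents only through the
  ~`1/(1+noise_sd^2)` variance fraction its layer-1 parents inherit.

With all profiles standardized, the attainable per-gene R^2 of a child
regressed on its parents is `1/(1+noise_sd^2)`; the default
`noise_sd = 1` gives R^2 = 0.5.

Features of real data deliberately not emulated: regulatory nonlinearity
and saturation, autocorrelated (AR) noise across the time course,
TF-TF feedback, unequal per-gene noise, batch effects.  Passing recovery
tests therefore show the inference machinery works in a favourable
linear regime at realistic sample sizes — not that it would achieve the
same operating point on field transcriptomes.

`simulate_counts` draws gamma-Poisson (NB) counts with mean
`expr * length/1e3 * libsize/1e6` (the FPKM inverse) and one shared
dispersion, matching the DE test's assumption.  `simulate_metabolome`
draws log-normal peak areas (base level uniform on log2 [10, 20],
replicate sd 0.25 on log2 — typical of targeted LC-MS), shifts a random
differential subset by `log2fc` in treated groups, draws pooled-QC
injections at a controlled raw-scale CV, and masks biological cells
completely at random (QC injections stay complete so the CV filter sees
every compound).  All simulators draw every stream from one
`SeedSequence`, so a seed fixes the dataset bit-for-bit.

## Numerical choices and degenerate inputs

* BH FDR delegates to `statsmodels` `multipletests`; tests verify it
  against a literal step-up recursion.
* GMM EM: log-likelihood computed with log-sum-exp; convergence when the
  improvement drops below 1e-10; trace monotonicity is asserted in tests.
* K-means ties/empty clusters: an emptied cluster is re-seeded at the
  point farthest from its centroid.
* Elimination ties in BWERF break by TF id (stable, deterministic).
* `rf_importance` sorts TF rows canonically by id before fitting, making
  importances exactly invariant to caller row order at a fixed seed; a
  constant target yields uniform importances with a warning.
* Correlation p-values use the t transform with n-2 df; |r| = 1 maps to
  p = 0.
* All long-running stages derive per-task seeds by `SeedSequence`
  spawning, so results are independent of execution order.

## Known limitations

* The layer assignment is identifiable only statistically: a pathway
  gene's profile is an exact linear function of its layer-2 grandparents
  too, so layer-2 TFs are the dominant contaminant of layer 1 and
  precision is bounded well below 1 at these sample sizes.
* The NB Wald test is calibrated for shared-dispersion data; strongly
  gene-specific dispersions would need a shrinkage estimator and are out
  of scope.
* OPLS-DA is fit with a single predictive component (two-class designs);
  multi-class designs are not supported.
* The KNN imputer is quadratic in matrix size for heavily missing data;
  it is intended for desk-scale (thousands of metabolites) matrices.
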