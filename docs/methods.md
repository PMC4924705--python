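# Methods

This note records the models, numerical choices and simulation design
behind `coexsurv`, and what the synthetic experiments do and do not
demonstrate about real data.

## Co-expression network model

The network core is the unsigned weighted-correlation construction. For
genes i, j with profiles x_i, x_j over the ordered time points,

    a_ij = |cor(x_i, x_j)|^β,      β = 10 (default),

with the diagonal fixed at 1. The soft power sharpens the contrast between
strong and weak correlations while keeping the network weighted; β = 10 is
the conventional unsigned choice for small-sample time series and is the
package default. The topological overlap measure augments direct adjacency
with shared-neighbour structure:

    TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,    k_i = Σ_{u≠i} a_iu,

diagonal 1, and 1 − TOM is the clustering dissimilarity. The matrix
formulation is verified against a literal triple-loop evaluation to 1e-12
in the tests.

Average-linkage (UPGMA) agglomeration of 1 − TOM is delegated to
`scipy.cluster.hierarchy.linkage`; tie handling is scipy's deterministic
distance-update order.

**Dynamic tree cut.** Modules are dendrogram branches below a cut height.
The default cut is placed at the midpoint of the *largest gap* in the
sorted merge heights: with block-structured data the many within-branch
merges crowd at low heights and the few between-branch joins sit far above
them, so the widest gap separates the two regimes regardless of where TOM
dissimilarities saturate. Fixed-quantile or fraction-of-maximum rules were
considered and rejected: both place the cut relative to the extreme top of
the dendrogram and mis-handle instances where between-module joins spread
downwards. If all merge heights are equal (no structure) the whole tree is
one module. Branches smaller than `min_module_size` (default 5, the
smallest module size the screen should admit) are merged into the module
with the smallest average dissimilarity when that average is below the cut,
otherwise left unassigned (label 0); unassigned genes are excluded
downstream. Labels are renumbered by decreasing module size. The whole
pipeline has no internal randomness: identical input gives an identical
partition.

**PPI membership filter.** Within each module only genes with at least one
interaction partner inside the same module are kept; modules with no
internally interacting member are dropped entirely, and labels re-compacted.

## Interaction-constrained co-expression comparison

Per retained interaction edge, the Pearson correlation of the two partners'
profiles is computed in the protein and mRNA matrices. Edges with an
endpoint missing from a matrix, fewer than 3 pairwise-complete samples, or
a zero-variance profile have no defined correlation; they are excluded
pairwise (the paired t-test needs complete pairs) and counted, never
silently dropped. The comparison is a two-sided paired Student t-test on
the per-edge differences; all-zero differences return t = 0, p = 1 by
convention. The Q-Q table pairs the two correlation sets by rank,
interpolating the longer set's empirical quantiles when lengths differ.

## Stage grouping

Module activity is the unweighted arithmetic mean of member expression per
time point. Activity rows are z-scored before clustering because modules
differ in absolute abundance and only the temporal shape should drive the
grouping; this also makes stage labels invariant to positive rescaling of
the input matrix. Modules are clustered with average linkage on Euclidean
distance, cut into 3 groups, and each group is named by the stage block
(default: first/middle/last thirds of the time axis, configurable as
explicit column blocks) that maximizes its mean standardized activity. If
two groups claim one stage, the group with the larger block mean wins and
the other takes its next-best block (logged). Constant activity across all
modules is rejected rather than grouped arbitrarily.

## Survival screen

The Cox proportional-hazards fit maximizes the Breslow partial likelihood
by Newton–Raphson with step-halving, on standardized covariates
(back-transformed afterwards), declaring convergence when the score norm
falls below 1e-8 (at most 50 iterations). Breslow tie handling was chosen
because event times driven by continuous expression rarely tie, and
Breslow is the simplest estimator that remains correct with few ties.
Reported statistics are Wald (z = β̂/SE from the observed information).
Degenerate inputs have defined behaviour: constant expression gives
β = 0, p = 1 with a `degenerate` flag; fits wandering beyond |β| > 20
(separation) are flagged non-converged and carry no p-value; zero events
raise. The implementation is checked three ways: against a grid-search
maximization of the same likelihood (1e-4 grid), against `lifelines`, and
by parameter recovery on simulated proportional-hazards cohorts.

The median-split log-rank test assigns x > median(x) to the high group
(values equal to the median go low, for determinism on discrete data) and
computes the standard 1-df chi-square from observed-vs-expected events
with the hypergeometric variance at each distinct event time.

Two-cohort validation keeps genes with p < α in discovery, p < α in
validation, and the same sign of β̂ in both — the strictest natural reading
of "consistent"; a sign-only mode is available. The permutation enrichment
test redraws |group| genes from the screened universe (default: all genes
entering the screen) without replacement, compares overlaps with the
significant set, and uses the (b+1)/(B+1) estimator so p is never zero.
The sampler is vectorized (argpartition of uniform draws), exact against
the hypergeometric tail within Monte-Carlo error, and reproducible under a
fixed generator.

Categorical covariates (gender, race) are encoded as reference-level
indicators; age enters untransformed. Progression-free survival reuses the
identical machinery on a second (time, event) pair; 0.05 ≤ p < 0.1 is
reported as "weak" association.

## Chemoresponse

Per compound, log10(IC50) is z-scored across cell lines (zero-variance
compounds are excluded with a warning; missing values stay missing).
Classification uses the sample (n−1) SD with strict inequalities — values
exactly at μ ± SD are intermediate. Because z-scoring sets μ = 0, SD = 1,
classification commutes with normalization; both steps are implemented and
the redundancy is intentional, mirroring the procedure as described.
Compounds need ≥ 10 sensitive and ≥ 10 resistant lines (inclusive). The
group test is Welch's t-test (group sizes and variances differ by
construction); no multiple-testing correction is applied by default, with
BH-FDR available as an optional extra. Pairs where either group has fewer
than two expression values are reported with NaN statistics, not dropped.

## Synthetic-data design

The generators define the study conditions for all tests.

**Developmental time series.** Nine time points split into three blocks of
three (early / middle / late). A module's template is high (+1) in its
block and low (−0.5) elsewhere, centered and scaled to unit variance. Each
module additionally receives a deterministic "identity wiggle": a unit-
variance direction from the orthonormal nullspace of the three stage
templates, scaled by `template_jitter` (default 1.0) and renormalized.
Every nullspace direction has exactly zero mean within each stage block,
so the wiggle leaves block means — and hence the stage peak and the
stage-grouping problem — untouched, while giving two modules that peak in
the same stage a template correlation of only 1/(1 + jitter²) = 0.5, which
makes them separable by clustering. Without the wiggle, two same-stage
modules are statistically identical and no method could recover them.
A gene's profile is amplitude × template + N(0, noise_sd²) per time point,
with amplitude = noise_sd·sqrt(ρ/(1−ρ)) so the expected within-module
Pearson correlation is the declared ρ (ρ = 1 is the noiseless limit). The
mRNA matrix adds independent per-gene noise scaled so
cor(protein, mRNA) ≈ `mrna_agreement`; agreement 1 duplicates the protein
matrix exactly.

**Interactions.** A stochastic block model on the planted partition:
within-module pairs become edges with probability p_within, between-module
pairs with p_between < p_within; scores are drawn strictly above the
STRING-style thresholds so simulated edges always survive the read filter.

**Survival cohorts.** Event times are exponential with rate
baseline_rate·exp(Σ β_g x_g + covariate terms) given standard-normal
expression; censoring is an independent exponential (rate 0 = none), so
the proportional-hazards assumption holds by construction and the Cox
estimator is consistent for the planted β. Defaults: baseline rate 0.01,
censoring rate 0.005 per time unit.

**Drug panel.** 60 cell lines (the NCI-60 convention); per drug,
log10(IC50) is standard-normal noise. For each planted (gene, drug) pair
the gene's expression is shifted by −δ in lines below μ − SD of that
drug's vector and +δ in lines above μ + SD, so the planted effect aligns
exactly with the downstream classification rule.

**Bundled end-to-end configuration.** 260 genes in six modules (two per
stage, sizes 29–45 after PPI filtering), ρ = 0.9, mRNA agreement 0.6,
p_within = 0.35 / p_between = 0.01, discovery n = 120 and validation
n = 300 patients, 12 early-module genes carrying log-hazard 1.0, a
25-drug × 60-line panel with three planted δ = 3 pairs, and 2,000
permutations. These sizes run the whole pipeline in a few seconds while
leaving every effect detectable but not trivial.

**What passing does and does not show.** The generators produce Gaussian
noise, exchangeable samples, exponential event times and block-constant
templates. Real developmental proteomes have heteroscedastic abundance-
dependent noise, unevenly spaced time points, batch structure and
non-proportional hazards; recovery and calibration on these simulations
demonstrate correctness of the implementations under their stated models,
not robustness to those violations. External-data idiosyncrasies
(identifier mapping, missingness patterns, platform effects) are
explicitly out of scope.

## Experiment sizes

The recovery and calibration experiments use: 100 random adjacencies
(≤ 30 nodes) for the TOM oracle; 50 small cohorts (n ≤ 12) for the Cox
grid oracle; 200 cohorts of n = 1000 per planted β ∈ {0, 0.35, 0.7} for
recovery and coverage; 2,000 null genes at n = 100 for screen calibration;
1,000 replicates at 499 permutations for enrichment-test calibration
(10,000 permutations for the exactness check); 100 seeds for chemoresponse
power and 2,000 gene–drug pairs for its null rate. These are the package's
chosen desk-scale study conditions; all complete in seconds to a few
minutes on one CPU.

## Known limitations

- The dynamic tree cut is the simple gap-based flavor, not the hybrid
  variant with PAM-like reassignment; deeply nested or strongly unbalanced
  module structures may need an explicit `cut_height`.
- The unsigned network maps strong negative correlation to high adjacency;
  anti-correlated gene groups can merge, which is inherent to the unsigned
  choice.
- Cox fits assume independent samples and proportional hazards; no frailty
  or time-varying effects.
- The permutation universe defaults to the screened genes; enrichment
  p-values change under a different universe convention (configurable).
- Module numbering encodes size rank, not dendrogram order.
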