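# coexsurv

Developmental co-expression network modules and their prognostic value in
glioblastoma — a reusable, fully tested implementation of the analysis
pipeline, exercisable end to end on synthetic data with planted ground
truth.

## The scientific problem

Brain development is driven by coordinated waves of protein expression.
Proteins that physically interact tend to be co-expressed, and groups of
proteins that rise and fall together across developmental time form
**co-expression modules** whose activity peaks early, midway or late in
development. Because glioblastoma (GBM) partly recapitulates developmental
programs, genes from early-development modules are candidate prognostic
markers. This package implements that chain of reasoning as five
computational stages:

1. **Interaction-constrained co-expression.** For every protein–protein
   interaction (STRING-style edge list filtered at experimental score > 200
   and combined score > 400), compute the Pearson correlation r of the two
   partners' profiles over the developmental time points, once on the
   protein matrix and once on the mRNA matrix, and compare the two sets of
   per-edge correlations with a paired Student t-test. A higher mean r on
   the protein side means protein profiles track the interactome more
   faithfully than transcripts do.
2. **Weighted co-expression modules.** Unsigned WGCNA-style network:
   adjacency a_ij = |cor(x_i, x_j)|^β with β = 10, topological overlap

       TOM_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
       ℓ_ij = Σ_u a_iu a_uj,  k_i = Σ_u a_iu,

   average-linkage clustering of 1 − TOM, and module extraction by a
   dynamic tree cut with a minimum module size of 5. Modules are then
   filtered against the interaction network: a member is kept only if it
   interacts with another member of its own module, and modules left with
   no internally interacting member are dropped.
3. **Stage grouping.** Each module's activity per time point is the mean
   expression of its members; modules are clustered on z-scored activity
   and labeled early / middle / late by the block of the time axis that
   maximizes their standardized activity.
4. **Survival screen.** Per gene, a univariate (optionally age/gender/race-
   adjusted) Cox proportional-hazards fit (own Newton–Raphson maximization
   of the Breslow partial likelihood) in a discovery cohort; discovery hits
   (Wald p < 0.05) are validated in a second cohort requiring significance
   plus a concordant hazard-ratio sign. Median-split log-rank tests
   stratify patients per gene. Whether a stage group concentrates the
   survival-associated genes is tested by permutation: redraw the group
   from the screened universe 10,000 times and compare overlaps, with
   p = (1 + #{overlap ≥ observed}) / (1 + N).
5. **Chemoresponse.** In an NCI-60-style panel, per-compound log10(IC50)
   values are z-scored; cell lines below μ − SD are sensitive, above μ + SD
   resistant, otherwise intermediate; compounds with ≥ 10 sensitive and
   ≥ 10 resistant lines are kept; each gene is tested between sensitive
   and resistant lines with a Welch t-test at p < 0.05.

A synthetic-data module generates all four input kinds — a time series
with planted stage-peaked modules, an interaction set enriched within
modules, proportional-hazards survival cohorts with planted log-hazard
effects, and a drug panel with planted gene–drug effects — so every stage
is testable against known truth without downloading anything.

## Worked example

Run the bundled synthetic configuration (six planted modules, two per
developmental stage; twelve early-module genes carry a log-hazard of 1.0):

```bash
coexsurv run --seed 1 --outdir out
```

Output (abridged):

```yaml
coexpression:
  mean_r_mrna: 0.318665
  mean_r_protein: 0.800508
  n_edges: 1662
  t_statistic: 54.316106
modules:
  n_modules: 6
  sizes: {1: 45, 2: 40, 3: 40, 4: 40, 5: 35, 6: 29}
stages:
  {1: early, 2: middle, 3: late, 4: early, 5: middle, 6: late}
survival:
  early:
    enrichment_p: 0.031984007996002
    n_discovery_significant: 9
    n_validated: 8
chemo:
  n_compounds_retained: 10
  n_significant: 20
```

Reading this: over 1,662 interacting pairs the protein-level correlations
(mean 0.80) clearly exceed the mRNA-level ones (mean 0.32) because the
synthetic mRNA layer tracks proteins with agreement 0.6 — the same
qualitative gap the protein-vs-transcript comparison is designed to
detect. All six planted modules are recovered and correctly staged. The
early group concentrates the survival-associated genes (permutation
p ≈ 0.03; 8 genes validated in the second cohort with concordant hazard
direction), while middle/late groups are at chance. Ten of 25 simulated
compounds pass the ≥10/≥10 sensitivity filter.

Each stage is also available as its own subcommand (`simulate`,
`coexpress`, `modules`, `stages`, `survival`, `chemo`) operating on plain
TSV files, and as importable library functions
(`coexsurv.network.detect_modules`, `coexsurv.survival.fit_cox`, ...).

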