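# Methods notes

This note records the modelling conventions, parameter choices, and known
limitations of `stemscore`, in the spirit of a statistical methods
appendix. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The enrichment statistic

The per-sample score of a gene set is the single-sample GSEA running-sum
statistic computed on within-sample expression **ranks**:

* Midranks for ties (so rank sums are invariant), 1 = lowest.
* Genes are walked in decreasing rank order. `P_hit` accumulates in-set
  weights `rank^α` normalized by the in-set total; `P_miss` accumulates
  the uniform out-of-set mass. The score is the **sum** of
  `P_hit − P_miss` over positions, not the extremum: the sum variant is
  the single-sample convention and is less noise-peaked than the maximum
  deviation.
* **α = 0.25** by default. The exponent controls how strongly highly
  ranked genes dominate; 0.25 is the widely used single-sample default
  and is recorded in every `ScoreMatrix` (and sidecar JSON) rather than
  hard-coded, since published analyses frequently leave it unstated.
* **Weights are ranks, not expression.** This makes scores invariant
  under any strictly increasing per-sample transform (log, quantile,
  unit changes), which is the property that lets one scoring rule serve
  microarray and RNA-seq inputs alike. The property is asserted exactly
  in the test suite.
* **Ties are handled blockwise.** Genes sharing a midrank form a block,
  and each gene in the block contributes the end-of-block value of
  `P_hit − P_miss`. With no ties this is exactly the positional walk.
  The motivation is well-definedness: a positional walk through tied
  genes depends on the arbitrary order chosen within the tie, whereas
  the blockwise statistic depends only on the rank values. In
  particular, a constant sample — where every gene ties — scores exactly
  0 for every set, which is the only defensible answer. Iteration order
  within blocks is lexicographic in the gene id purely so outputs are
  bit-reproducible.
* At α = 0, `ES(G) = −ES(Gᶜ)` exactly (both cumulative distributions
  swap roles); this identity is used as an exact regression test.
* **Normalization** (optional, default on for collections) divides the
  whole set × sample matrix once by its global max − min, giving a
  matrix of range exactly 1. It is a display/comparability convention
  only; all filters downstream are either rank-based (AUC) or applied
  after their own rescaling (CV). A constant raw matrix skips
  normalization with a warning.
* Sets overlapping the expression universe in fewer than
  `min_overlap = 2` genes are dropped and reported, not scored.

## The distillation funnel

* **AUC filter (default 0.95, inclusive).** The exclusion rule is
  "discard sets with AUC < 95%", so a set at exactly 0.95 survives. AUC
  is computed by the Mann–Whitney midrank formula with ties counted
  half. No orientation flipping: candidate stemness sets are expected a
  priori to score *higher* in stem-like samples, and a set that scores
  the wrong way should fail, not be rescued.
* **CV filter (default 0.1, inclusive).** Enrichment scores can be
  negative, making sd/mean meaningless on the raw scale. The package
  therefore min–max rescales the whole panel score matrix to [0, 1]
  before computing per-set CV; this is one defensible reading of a CV
  criterion on signed enrichment scores, and it is recorded in the
  report (including a flag for sets whose rescaled mean is 0, where CV
  is undefined and the set is excluded). The standard deviation uses
  n − 1, treating the panel as a sample of lines.
* **Consensus (default membership ≥ 4).** Genes are counted across the
  surviving sets only; output is sorted by descending count, then gene
  id, for determinism. An empty consensus is a warning, not an error.
* **Pearson screen.** r is computed vectorized; p by the t transform
  `t = r√((n−2)/(1−r²))` with n − 2 df, two-sided. Both thresholds are
  strict (`r > 0.4`, `p < 0.05`) as the convention states them. No
  multiple-testing correction enters the decision — matching the
  published practice this implements — but Benjamini–Hochberg q-values
  are reported alongside so the cost of that choice is visible.

## Cohort analytics

* **Median split, ties to low.** Published analyses typically state only
  "high and low groups"; the median is the conventional unsupervised
  choice, avoids optimal-cutoff optimism, and is recorded (split value +
  method) in every output.
* **Welch t.** For two-group contrasts the unequal-variance t is used
  even where a pooled test might be implied: it is the safer default and
  identical in the balanced equal-variance case.
* **Survival.** KM estimates, the log-rank test (hypergeometric
  variance, df = 1), and Cox PH fits are delegated to lifelines; Cox
  uses Efron tie handling by default (Breslow by flag). Non-convergent
  or separated fits are flagged (`converged = False`) with no estimates
  reported. The score test at β = 0 for a single covariate is
  implemented directly (`cox_score_test`) and equals the log-rank
  statistic for a binary covariate without ties — verified numerically
  to 1e−8 against the independent log-rank route.
* **Chi-square.** Uncorrected Pearson, no Yates, no Fisher fallback,
  even at small expected counts: the bundled LUAD marker tables
  (ALDH1A1 IHC and E2F1 IHC, n = 95; serum E2F1 ELISA, n = 100)
  reproduce all 18 of their printed P-values at 3-decimal half-up
  rounding only under this convention (one of the age rows has an
  expected count below 5, which pins the choice). The test suite
  additionally checks the asymptotic p against a seeded Monte-Carlo
  permutation null; because the permutation statistic is discrete, the
  comparison uses the mid-p (P(T > t) + ½P(T = t)), the standard
  continuity-consistent convention.

## The synthetic design

The generator's defaults define the reference study conditions; they are
chosen once for realism and fixed.

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | gene universe (enough for disjoint set pools) |
| `sigma` | 1.0 | log-scale expression noise sd |
| `delta` | 2.0 | planted shift in stem samples, σ units |
| `n_stem`, `n_somatic` | 20, 20 | discrimination panel arms |
| `n_planted` / `n_unstable` / `n_null` | 6 / 3 / 6 | set truth classes |
| `core_signature_size` | 120 | true signature genes |
| `core_membership_range` | 4–6 | planted sets per core gene |
| `n_lines` | 200 | cell-line panel size |
| `stable_shift` | 2.0σ | fixed panel shift of stable sets |
| `unstable_shift_sd` | 3.0σ | per-line shift sd of unstable sets |
| `n_tumor`, `n_normal` | 500, 100 | cohort arms |
| `separation` | 2.5 | latent stemness shift of tumors (design AUC Φ(2.5/√2) ≈ 0.96) |
| `beta` | 0.7 | log-hazard per unit standardized score |
| `baseline_hazard` | 0.1 | exponential baseline rate |
| `censoring_rate` | 0.3 | target uniform-censoring fraction |
| `clinical_odds_mult` | 2.0 | advanced-stage odds × per score quartile |

Notes on construction:

* Expression is log-normal: Gaussian on the log scale plus additive
  shifts, then exponentiated. Because scoring is rank-based, the
  marginal shape is nearly irrelevant; log-normal is kept for realism of
  skew.
* Each core gene is assigned to 4–6 of the 6 planted sets, so the
  membership ≥ 4 consensus recovers exactly the core pool when all
  planted sets survive; planted sets also carry 20 private filler genes
  each, and decoy sets draw from genes outside the core, all pools
  disjoint. This makes recovery metrics exact rather than approximate.
* The uniform censoring horizon is solved (bisection) so the expected
  censored fraction matches `censoring_rate` under the marginal
  effective hazard `λ·exp(β²/2)`; with `censoring_rate = 0` every event
  flag is 1.
* The survival table carries the generator's standardized latent trait
  (`stemness_z`) and an independent noise covariate (`age_z`); Cox on
  `stemness_z` is a clean parameter-recovery check of β, and `age_z`
  checks null retention. Regressing instead on the ssGSEA-estimated
  score measures the pipeline path but is attenuated by score noise, so
  the recovery checks use the design covariate.
* One global seed expands into fixed per-component substreams
  (`SeedSequence(seed, spawn_key=(k,))`), so identical design + seed are
  bitwise-reproducible and generating one component never perturbs
  another. The integer-state PCG64 generator is platform-stable.

What the generator deliberately does **not** emulate: real cohort sample
sizes, microarray/RNA-seq batch effects, probe-level structure,
correlated gene-gene noise, non-proportional hazards, or competing
risks. Passing the recovery tests therefore demonstrates correctness of
the pipeline's statistics under its stated model, not robustness to
those real-data pathologies.

A consequence of the rank-based score worth knowing: in the synthetic
discrimination panel the *null* decoy sets score systematically **below**
0.5 AUC, not at it, because up-shifting several hundred planted genes in
stem samples pushes all unshifted genes down in relative rank. This
compositionality is a genuine property of rank-based scoring on globally
shifted profiles, and it is why the discrimination filter's null
calibration is checked under a δ = 0 design (where null AUCs do hover
around 0.5).

## Numerical conventions

* Degenerate inputs fail loudly: empty set/matrix intersections,
  all-identical scores at dichotomization, zero-margin contingency
  tables, single-sample panels, and one-class label vectors all raise
  typed errors.
* Invalid rows in survival/clinical TSVs are dropped and counted in a
  read report (strict mode raises instead).
* Display rounding of association P-values is 3-decimal half-up, the
  printed-table convention; machine outputs keep full precision.
* Problem sizes in the tests and the acceptance script (2000-gene
  universe, 200-line panel, 500-tumor cohort, a few hundred brute-force
  oracle instances) are the package's reference design — small enough to
  run in seconds, large enough that every recovery criterion is met with
  wide margin.

## Known limitations

* The ssGSEA exponent, normalization, and the CV-on-signed-scores
  convention vary across published analyses; all are surfaced as
  recorded configuration, but cross-study numeric agreement is not
  guaranteed.
* The AUC filter evaluates one labeled panel at a time; pooling
  strategies across multiple chips are the caller's composition.
* No time-dependent ROC, no optimal-cutpoint split, no multivariable
  logistic models for the clinical tables, and no gene identifier
  mapping (inputs are taken at gene level, case-sensitively).
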