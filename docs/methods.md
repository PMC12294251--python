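# Methods

## Model

`sparsegblup` fits a multi-environment genomic BLUP with
genotype-by-environment (G×E) interaction to environment-level adjusted
line means (BLUEs):

    Y_ij = μ + E_i + g_j + gE_ij + ε_ij

- `E_i` — environment main effects, iid `N(0, σ²_E)`. Environments are
  treated as random draws from a population of site–season combinations;
  no environmental covariates enter the model.
- `g_j` — genomic line effects, `MVN(0, σ²_g G)` with `G` the VanRaden
  (method 1) relationship matrix: `W = M − 2p` column-centred at observed
  allele frequencies, `G = WWᵀ / (2 Σ p_k(1−p_k))`. The variant is the
  canonical default of the BGLR-style workflows this model family is run
  with.
- `gE_ij` — interaction deviations with covariance
  `σ²_gE (Z_g G Z_gᵀ ∘ Z_E I Z_Eᵀ)`; because the environment kernel is the
  identity, this is an independent `MVN(0, σ²_gE G)` per environment.
  Environments are exchangeable a priori: the model borrows strength
  across lines (through `G`) but not across environments (beyond `E` and
  `g`).
- `ε_ij` — iid residuals, `N(0, σ²_ε)`. One record per line × environment;
  within-trial design structure (incomplete blocks, replicates) is assumed
  to have been absorbed into the BLUEs upstream and is out of scope.

The model is fit on raw BLUE values by default; an optional
`center_by_env` flag removes each environment's observed mean first (and
restores it at prediction) for traits with strong level differences.

## Posterior computation

All effects and variance components are sampled by Gibbs. Priors follow
the BGLR convention: scaled-inverse-chi-square on each variance with
`prior_df = 5`, scales set so that a share `prior_r2 = 0.5` of the
observed phenotypic variance is attributed a priori to the random terms
jointly (split equally among them; `1 − prior_r2` to the residual), each
term's scale divided by the mean diagonal of its kernel. The grand mean
has a flat prior. Defaults `n_iter = 10,000`, `burn_in = 2,000`,
`thin = 5`; the demonstration scenarios use shorter chains (stated below)
after verifying agreement with the closed-form solution.

Numerics:

- Each random term `u ~ N(0, σ² G)` observed through per-line record
  counts is reparameterised as `u = A c` with `c ~ N(0, σ² I)`, where `A`
  is built once per fit from the eigendecomposition of `G`
  (eigenvalues below `1e−8 × λ_max` dropped) followed by a simultaneous
  diagonalisation of the prior covariance and the count matrix. Every
  full conditional is then diagonal, one Gibbs sweep costs a few
  matrix–vector products, and the quadratic form in the variance update is
  simply `cᵀc`. This is algebraically the same posterior as the standard
  RKHS/eigen formulation, not an approximation.
- Masked records are excluded from all likelihood updates; predictions for
  any cell are the sums of posterior-mean effects (`μ + E_i + g_j +
  gE_ij`), so cells never observed — including lines with no record at all,
  predicted purely through `G` — need no data augmentation. An environment
  with zero observed records has no estimable main effect and is rejected
  at prediction.
- Prior scales are floored at `1e−8` so a constant response (zero sample
  variance) degrades gracefully: μ converges to the constant and all
  variances collapse toward zero.
- A non-finite variance draw aborts the chain with the iteration and
  component named.
- `blup_oracle` solves the mixed-model prediction equations directly
  (`ŷ = μ̂_GLS + V_cross (V_obs + σ²_ε I)⁻¹ (y_obs − μ̂_GLS)`) and adds a
  `1e−8` ridge only if the covariance is numerically singular (logged).
  At fixed variance components the Gibbs posterior means agree with it to
  well under 1% of sd(y) (tested).

A caveat on identifiability: with a handful of environments (2–6 per
dataset, as in the emulated study), `σ²_E` is informed by only that many
realised effects, so its posterior is prior-dominated and its point
estimate carries chi-square-few-df sampling noise no estimator can remove.
The genetic components (`σ²_g`, `σ²_gE`) and the residual are estimated
from hundreds of lines and recover well (tested); posterior credible
intervals are calibrated for all four components (tested).

## Synthetic trial generator

The generator emulates a two-country wheat MET program: per dataset
(a target population of environments, TPE, in one season) a cohort of
lines is phenotyped in a few *target* environments (the selection country)
and a few *auxiliary* environments (an off-season nursery), with partially
overlapping cohorts between consecutive seasons. `make_study_designs`
reproduces the emulated study's six dataset shapes (112–166 lines, 2–6
target and 3–6 auxiliary environments per TPE × season, 18,238 markers at
full scale) and scales them down by a factor.

Phenotypes are drawn exactly from the model above. Markers are biallelic
dosages in Hardy–Weinberg proportions with per-marker allele frequency
uniform on `maf_range` and missing calls placed completely at random (the
real missingness mechanism is unknown; MCAR is the neutral choice). Two
features are deliberate additions beyond the fitted model:

- **Auxiliary-merit correlation.** In auxiliary environments the line
  effect is a correlated copy `g_aux` with `cor(g, g_aux) =
  aux_genetic_correlation` (default 0.5) and equal variance. This is the
  knob that makes enrichment data informative (near 1) or misleading
  (near 0) about target-environment merit — the mechanism the sparse-
  testing comparison probes. The fitted model assumes a single `g`, so a
  low correlation is a controlled model violation, as in reality.
- **Season overlap.** Within a TPE, consecutive seasons share
  `round(line_overlap_fraction × min(n₁, n₂))` lines (default fraction
  0.2; the real overlap is not published) and a single realisation of
  `g`/`g_aux` over the union cohort — a line's merit is a property of the
  line — while environment effects, G×E deviations and residuals are
  season-specific.

Defaults: `mu = 6.0` (t/ha scale typical of wheat grain-yield BLUEs),
`σ²_E = 0.5`, `σ²_g = σ²_gE = σ²_ε = 1.0`, `missing_rate = 0.1`,
`maf_range = (0.05, 0.5)`, 150 lines × 1,000 markers at desk scale (the
full 18,238 markers are available by parameter). The generator emits
BLUE-level values directly; it does not simulate plot-level alpha-lattice
data, spatial trends, weather/soil covariates, or informative missingness,
so passing tests demonstrate correctness of the machinery and the
qualitative enrichment behaviour, not absolute accuracy levels on real
trials.

## Marker QC

Markers are kept when minor-allele frequency (computed on non-missing
calls; ties at the threshold retained) is at least `maf_min = 0.05` and
the missing fraction is at most `pmv_max = 0.50`; monomorphic markers are
always dropped. Missing calls are then mean-imputed per marker. Filtering
is applied per analysis dataset. The filter is idempotent and `G` is
invariant to marker order, marker duplication, and line permutation
(tested).

## Cross-validation and enrichment

- **Partitions.** For each testing proportion `Tst`, `n_partitions = 10`
  independent random holdouts of the target-environment line set
  (training fractions of 85/70/50/30% cannot form disjoint 10-fold CV, so
  repeated holdout is the faithful reading). Test-set size is
  `round(Tst × n)` with half-away-from-zero rounding, bounded away from 0
  and n. All masked cells of a test line (every target environment) are
  held out together: tested lines, untested environments.
- **GBLUP** trains on the unmasked target-environment records only.
  **GBLUP_Ad** appends whole enrichment sources — by default the target
  dataset's own auxiliary environments plus entire previous-season
  datasets — as observed records, including records of test lines in
  non-target environments. Enrichment never includes future seasons. A
  leakage guard drops (and counts) any source record coinciding with a
  masked (line, env) cell, and every assembled partition is audited for
  an empty masked ∩ observed intersection.
- **Scoring.** Masked cells are scored within each target environment
  (observed vs predicted across test lines), then averaged over
  environments and partitions; the pooled line × env alternative is
  available via `pool_envs`. Per-env-then-average is the default because
  it weights environments equally regardless of line counts.
- **Seeds.** A scenario master seed derives partition and fit seeds
  through `numpy.random.SeedSequence` spawn keys, so runs are
  reproducible byte-for-byte and fits are independent.

## Metrics

- COR: Pearson correlation; NaN (never 0) when a vector is constant.
- PM_10 / PM_20: `k = max(1, round(f·n))` (half-away rounding), top-k sets
  by value descending with ties broken by stable line-id order (PM is
  tie-sensitive, so the rule is fixed); score is `100·|A∩B|/k`. "Top"
  means the largest trait value.
- Relative efficiency: percentage change of the *sign-preserving squared*
  correlation against the reference model (GBLUP_Ad), so negative baseline
  correlations yield negative RE; a raw-percentage mode is provided for
  the matching metrics and for sensitivity checks. Zero or undefined
  references give NaN with a warning.
- Summaries report mean, sample sd (n−1), and `se = sd/√n` across
  partitions per (dataset, environment, model, Tst), excluding and
  counting undefined partitions; a dataset-averaged "Across" block is
  added when several datasets are summarised. No hypothesis tests are
  reported: holdout partitions overlap, so fold-wise variances have no
  unbiased estimator.

## Problem sizes used in the shipped checks

Test-suite and acceptance-script simulations use desk-scale sizes chosen
as the package's defaults: 40–50 lines for exact/oracle checks, 300 lines
× 1,000 markers × 5 environments for variance-component recovery, and a
150-line × 1,000-marker two-season pair (10 partitions, Tst 0.3/0.5/0.7,
2,000-draw chains after a 500-draw burn-in) for the enrichment comparison,
run once with related (0.9) and once with unrelated (0.0) auxiliary
correlation.

## Known limitations

- Environment main-effect variance is weakly identified with few
  environments (see above); interpret its point estimate accordingly.
- The G×E covariance is the identity-by-environment Hadamard structure;
  factor-analytic or covariate-driven environmental covariances are out
  of scope.
- Single trait, BLUE-level input only; no plot-level modelling, LD
  pruning, pedigree or single-step relationship matrices.
- The generator's auxiliary-correlation and season-overlap knobs are
  abstractions of environment relatedness; they reproduce the qualitative
  enrichment trade-off, not any particular program's magnitudes.
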