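# sparsegblup

Multi-environment Bayesian GBLUP for **sparse testing** in plant breeding:
predicting the performance of *tested lines in untested environments*, and
quantifying when enriching the training set with auxiliary environments
(an off-season nursery, previous seasons) helps — and when it hurts.

The package is aimed at quantitative geneticists and breeding-program
analysts who run multi-environment trials (METs) where not every line can
be phenotyped in every environment. It ships a synthetic MET generator, so
the whole pipeline is runnable and testable without any proprietary field
data.

## The model

For the adjusted line mean (BLUE) of line *j* in environment *i*,

```
Y_ij = μ + E_i + g_j + gE_ij + ε_ij
```

with

- `E ~ N(0, σ²_E I)` — random environment main effects,
- `g ~ N(0, σ²_g G)` — genomic line effects, `G` the VanRaden genomic
  relationship matrix computed from marker dosages,
- `gE ~ N(0, σ²_gE (Z_g G Z_gᵀ ∘ Z_E I Z_Eᵀ))` — genotype-by-environment
  deviations: an independent `MVN(0, σ²_gE G)` per environment (the
  Hadamard-product covariance, block-diagonal on a complete layout),
- `ε_ij ~ N(0, σ²_ε)` iid residuals.

Variance components carry scaled-inverse-chi-square priors (BGLR
convention: `prior_r2` of the phenotypic variance split equally across
random terms, `df = 5`), the grand mean a flat prior, and the posterior is
explored by a Gibbs sampler in which every full conditional is made
diagonal by simultaneously diagonalising each term's prior covariance and
data precision. A closed-form mixed-model oracle (`blup_oracle`) verifies
the sampler at fixed variance components.

Two cross-validation strategies implement the sparse-testing comparison.
For a target dataset and its target environments, a fraction
`Tst ∈ {0.15, 0.30, 0.50, 0.70}` of lines is masked in *all* target
environments over 10 repeated random holdouts:

- **GBLUP** — train only on the unmasked target-environment records;
- **GBLUP_Ad** — additionally train on whole auxiliary datasets (the
  off-site environments of the current season plus previous-season data).

Accuracy is scored per target environment on the masked cells with
Pearson correlation (COR) and the percentage of matching in the observed
vs predicted top 10% / 20% (PM_10, PM_20); models are compared by relative
efficiency, the percentage change in signed squared correlation against
GBLUP_Ad.

## Worked example

Simulate a two-season TPE pair (40% of the emulated study's cohort sizes,
800 markers, genetic correlation 0.8 between target and auxiliary merit),
then compare GBLUP with GBLUP_Ad at two testing proportions:

```python
from sparsegblup import (
    GenerativeParams, ScenarioPlan, compute_grm, filter_markers,
    impute_mean, make_study_designs, run_scenario, simulate_design_pair,
    standard_enrichment, summarize, MCMCSettings,
)

pair = make_study_designs(scale=0.4)[2]            # the TPE_3 season pair
params = GenerativeParams(n_markers=800, aux_genetic_correlation=0.8, seed=1)
markers, phenos, truths = simulate_design_pair(pair, params)
grm = compute_grm(impute_mean(filter_markers(markers)))

plan = ScenarioPlan(
    target_dataset="TPE_3_2022_2023",
    tst_props=(0.3, 0.5),
    n_partitions=5,
    enrichment=standard_enrichment("TPE_3_2022_2023", ["TPE_3_2021_2022"]),
    mcmc=MCMCSettings(n_iter=2000, burn_in=500, thin=2),
    seed=7,
)
preds, metrics = run_scenario(plan, phenos, grm)
s = summarize(metrics)
cols = ["model", "tst_prop", "COR_mean", "COR_se", "PM_20_mean", "COR_RE"]
print(s[s.env_or_across == "across_envs"][cols].round(3).to_string(index=False))
```

```
   model  tst_prop  COR_mean  COR_se  PM_20_mean  COR_RE
   GBLUP       0.3     0.113   0.064      25.000 -84.306
   GBLUP       0.5     0.053   0.077      34.286 -96.923
GBLUP_Ad       0.3     0.286   0.027      30.000   0.000
GBLUP_Ad       0.5     0.301   0.048      51.429   0.000
```

With related auxiliary environments, enrichment more than doubles the
across-environment correlation on the masked cells (0.113 → 0.286 at
Tst = 0.3) and lifts the top-20% coincidence at Tst = 0.5 from 34% to 51%;
the negative `COR_RE` values quantify how much the target-only GBLUP loses
relative to the enriched reference. Setting
`aux_genetic_correlation` near 0 in the generator reverses the gap —
unrelated enrichment data dilute, rather than sharpen, the prediction.

The same pipeline is available from the shell
(`sparsegblup simulate | grm | run-scenario | summarize | plot`); every
run directory contains a manifest (config, seeds, input checksums) that
reproduces its outputs byte-identically.

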