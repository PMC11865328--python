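# coabnet

Differential microbial co-abundance networks for hypertension cohorts.

Gut microbiome dysbiosis in hypertension is usually described through
differential abundance of individual taxa. `coabnet` instead targets the
*interactions*: which pairs of genera co-vary, how those co-abundances differ
between hypertensive and non-hypertensive participants, how their strength
tracks hypertension severity (grades 0–3 from blood pressure), and whether
genus-pair interactions carry extra variance of metabolic pathway abundances.
It is aimed at microbiome statisticians working with region-stratified
16S genus count tables plus host metadata.

## The method

1. **Latent correlation per stratum.** Counts are compositional: observed
   log proportions differ from latent log absolute abundances by a shared
   per-sample term. Per region × group stratum the latent covariance Σ is
   estimated by penalized least squares

   min over PSD Σ and b of ½‖S − Σ + b·1ᵀ + 1·bᵀ‖²_F + λ·Σ_{i<j}|Σ_ij|,

   where S is the sample covariance of log compositions and the rank-one
   terms absorb the closure. The solver alternates a closed-form b-update
   with an ADMM pass splitting the L1 proximal step from projection onto the
   PSD cone. Edge significance comes from a bootstrap over samples.
2. **Random-effects meta-analysis.** Per-region correlations are pooled on
   the Fisher-z scale (variance 1/(n−3)) with DerSimonian–Laird τ², and
   edges are flagged at Benjamini–Hochberg FDR < 0.05 per group network.
3. **Differential edges.** Each edge's pooled effects in the two groups are
   compared with Cochran's Q; edges with I² > 75% and p < 0.05 are
   differential and classified increased / decreased / reversed. The same
   machinery drives covariate adjustment (partial correlation against
   8 host covariates), replication against external cohorts, and
   heterogeneity across the four severity grades (df = 3) with a weighted
   trend of strength on grade.
4. **Interaction extra-variance.** For a pathway Y and genus pair (x1, x2),
   the gain ΔR² of Y = α + β₁x₁ + β₂x₂ + β₁₂x₁x₂ + ε over the model without
   the product term is F-tested per grade and ΔR² regressed on grade.

A synthetic cohort generator plants all of this structure (multivariate
log-normal latent abundances → softmax → multinomial counts; blood pressure
sampled within grade bands; grade-dependent correlations and pathway
interaction terms) and records a ground-truth manifest, so every stage is
testable end to end without access to cohort data.

## Worked example

The numbered scripts under `analysis/` run the full sequence on a planted
six-region cohort (`python analysis/01_simulate_cohort.py` through
`06_pathway_variance.py`). With the default seed the chain prints:

```
5 heterogeneous edges of 20 tested
planted ('g012', 'g013') [increased]: recovered as increased
planted ('g014', 'g015') [decreased]: recovered as decreased
planted ('g016', 'g017') [reversed]: recovered as reversed
covariate adjustment: 5/5 edges consistent (Q-test p > 0.05) after partial correlation
4 of 5 candidate edges heterogeneous across grades; 1 severity-associated (trend p < 0.05)
planted severity edge (g018, g019): slope 0.243 z/grade, trend p = 0.011, I2 = 95.0%
pathway funnel: 1 two-group, 1 four-grade, 1 pass all three filters: ['pw_interact']
  pw_interact x (g018, g019): slope +0.2008 dR2/grade, p = 0.031
```

i.e. all three planted differential edge classes are recovered, the planted
severity edge shows the planted positive strength-on-grade trend, adjustment
for the 8 covariates leaves the edges intact (they were planted independent
of the covariates), and the planted interaction pathway survives the
differential-abundance funnel with a positive extra-variance trend.

The same pipeline is available as one call (`coabnet run --config cfg.yaml`)
or programmatically via `coabnet.run_pipeline(PipelineConfig(...))`, which
writes every stage's TSV/GraphML/JSON output and a summary report.

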