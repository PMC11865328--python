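# Methods

## Compositional latent-correlation model

Observed genus counts are treated as a multinomial draw from a composition
x = softmax(w), where w is the vector of latent log absolute abundances.
For the log composition, cov(log x) = Σ − b·1ᵀ − 1·bᵀ with Σ = cov(w) and a
nuisance vector b absorbing the per-sample normalization. The estimator
solves

    min_{Σ ⪰ 0, b}  ½‖S − Σ + b1ᵀ + 1bᵀ‖²_F + λ Σ_{i<j}|Σ_ij|

with S the sample covariance of log((count + c)/(depth + p·c)), pseudocount
c = 0.5. The b-update is closed form (with D = Σ − S, b = (D1 − s1)/p,
s = 1ᵀD1/(2p)); the Σ-update is ADMM with variable splitting Σ = Z: the Σ
step is the PSD projection of (A + μ(Z − U))/(1 + μ), the Z step
soft-thresholds off-diagonals at λ/(2μ) (the penalty counts each unordered
pair once), and μ follows standard residual balancing from μ = 1. The two
updates alternate until the penalized objective is stable to 1e-6; the
objective is non-increasing across alternations and the returned Σ has
minimum eigenvalue ≥ −1e-8. Correlations are ρ_ij = Σ_ij/√(Σ_ii Σ_jj).

Numerical notes: convergence uses both ADMM residuals (scaled by p and
max|S|) and the outer objective change; the ADMM iteration cap is 500 per
alternation with up to 500 alternations — in practice a p = 30, n = 500
stratum converges in ~1000 total iterations (~0.15 s). With exactly two
taxa the latent scale is not identifiable (the covariance has fewer free
entries than the model); estimates remain internally consistent with the
log-ratio variance criterion but should not be interpreted. Small dense
panels (≈10 taxa with most taxa in correlated blocks) carry a visible
closure bias of order −1/p on null pairs; a larger λ (0.05–0.1) absorbs it.
The default λ = 0.01 is a light penalty appropriate for genus-scale panels;
`select_lambda` offers K-fold cross-validation on held-out covariance
reconstruction with ties broken toward sparsity.

Bootstrap: B resamples of samples with replacement at fixed λ; SE is the
resample standard deviation and the two-sided p-value uses the add-one rule
2·min(#{ρ* ≤ 0}+1, #{ρ* ≥ 0}+1)/(B+1). Strata below 20 samples are refused.

## Meta-analysis and differential edges

Pooling is DerSimonian–Laird on Fisher-z effects with within-stratum
variance 1/(n−3); the bootstrap SEs are carried as QC only. τ² is the
moment estimator truncated at zero; I² = max(0, (Q − df)/Q)·100. Edges are
pooled when estimable in ≥ 2 strata (configurable; a single-stratum pool
reduces to the per-stratum z-test). BH FDR is applied jointly over all
genus pairs within one group's network.

Differential testing compares the two groups' pooled effects per edge with
Cochran's Q (df = 1); the default differential universe is the union of
edges significant in either group. Flagged edges (I² > 75% and p < 0.05)
are classified by sign agreement and |z| ordering: reversed when signs
differ, otherwise increased/decreased by whether the case effect is larger
in magnitude. Covariate adjustment builds, per stratum, the Pearson
correlation matrix of the transformed genus pair plus the 8 covariates,
inverts it, and takes pcor_ij = −Ω_ij/√(Ω_ii Ω_jj); adjusted estimates are
re-pooled and compared to the unadjusted pooled effect with the same Q test
(consistent when p > 0.05). Replication pools external-cohort estimates
with the same machinery and reports replicated (p < 0.05, same sign) and
consistent (Q-test p > 0.05) fractions. Severity analysis fits one pooled
network per grade (region-stratified with a stratum floor of 20 and an
optional combined-sample fallback for sparse grades), tests candidate edges
across the four grade networks (df = 3), and fits a weighted least-squares
trend of pooled z on the numeric grade 0–3 (weights 1/se²; unweighted mode
available). Equal spacing of grades is an assumption, not an estimate.

## Feature transforms and univariate tests

Genus and pathway abundances are inverse-rank transformed,
Φ⁻¹((rank − 0.5)/n) with average ranks for ties, then residualized by OLS
on an intercept plus the eight covariates (age, sex, BMI, smoking,
antibiotic use, diabetes, hypercholesterolemia, obesity); collinear columns
are dropped with a warning. The transform/adjustment is applied once
globally, not re-fit per grade. Two-group tests are Wilcoxon rank-sum;
four-grade tests are Kruskal–Wallis plus a Spearman correlation with the
numeric grade; BH FDR is applied per feature family (genera and pathways
separately).

## Interaction extra-variance

Within each grade, the reduced model Y ~ 1 + x1 + x2 and the full model
adding x1·x2 are fitted by least squares on transformed values;
ΔR² = R²_full − R²_reduced ≥ 0 by nesting, and
F = ΔR²(n−4)/(1−R²_full) on (1, n−4) df. The BH family is all
pathway × pair × grade fits of a call (the conservative joint reading).
The ΔR²-on-grade trend is unweighted OLS on at most four points — with only
four grades there is no meaningful SE for ΔR² to weight by. Cells with
n < 10 or |corr(x1, x2)| > 0.999 are skipped. Whether pathway values should
be residualized before the interaction model was an open design point;
residualizing was chosen for consistency with the covariate adjustment
applied everywhere else.

## Synthetic cohort generator

The generator emulates a multi-region cross-sectional 16S cohort:

- **Latent abundances**: multivariate normal per (region, grade) with a
  block base correlation, group-differential edges (rho_control vs
  rho_case), severity edges (rho + slope·grade), and symmetric regional
  jitter (SD 0.02) resampled until the matrix is positive definite
  (minimum eigenvalue > 1e-6). Per-taxon mean log abundances are N(0, 1),
  giving realistic skewed compositions.
- **Counts**: multinomial at a rounded log-normal depth
  (log-mean log 30000, log-SD 0.3); rows sum exactly to their depth.
- **Blood pressure**: uniform within the assigned grade's clinical band,
  with one randomly chosen measure driving the grade and the other drawn in
  the normal range, so grade assignment round-trips exactly.
- **Covariates**: age N(53, 15), BMI N(23.4, 3.5), 55% female, 33% smokers;
  antibiotics/diabetes/hypercholesterolemia/obesity Bernoulli at
  0.05/0.10/0.10/0.15 (plausible cohort rates; the last four are package
  choices, configurable). Covariates are independent of the microbiome by
  default so adjustment tests have a known null.
- **Grades**: the default mix is proportional to 4644:1425:581:259, applied
  to the hypertensive group size per region by largest-remainder
  apportionment; the default per-region group sizes (332 non-hypertensive,
  168 hypertensive) reproduce the reference cohort's group totals over 14
  regions. Per-region per-grade sizes are configuration, not estimates.
- **Pathways**: Y = β₁x₁ + β₂x₂ + (γ₀ + γ_slope·grade)·x₁x₂ + ε on
  standardized latent scales, plus pure-noise pathways. Grade dependence of
  a pathway's mean arises only through γ(grade)·E[x₁x₂ | grade], which is
  how planted pathways become grade-differential.
- **Taxonomy**: eight phyla with a Firmicutes-heavy weighting (58%).

What the generator does **not** emulate: phylogenetic correlation
structure, sequencing error, zero inflation beyond multinomial sampling,
covariate–microbiome confounding (unless injected), longitudinal sampling,
or grade-dependent shifts in single-genus mean abundance. Passing recovery
tests therefore demonstrates correctness of the estimators under the
model's own assumptions, not robustness to real-data violations of them.

## Problem sizes in tests and validation

Recovery experiments run at deliberately moderate sizes chosen to give
stable operating characteristics: latent-correlation recovery at p = 30,
n = 500 over 5 seeds; differential detection at 14 strata × 200 samples per
group with 10 planted disjoint pairs at Δz = 0.8; interaction null
calibration over 500 replicates of n = 100; severity-trend sign recovery
over 100 generator replicates at n = 300 per grade; the end-to-end
determinism check on a 3-region, 15-taxon cohort. The full-scale defaults
(14 regions, 60 taxa, ~7000 participants, 100 bootstrap resamples) are what
`coabnet run` uses when invoked on a default configuration.

## Known limitations

- The penalized objective is a least-squares surrogate, not a likelihood;
  bootstrap p-values inherit the usual percentile-bootstrap small-B
  granularity (minimum 2/(B+1)).
- DL τ² is a moment estimator; with very few strata (K = 2–3) it is noisy
  and I² is coarse.
- The partial-correlation adjustment operates on Pearson correlations of
  transformed proportions and therefore carries compositional bias of order
  1/p; it is intended for genus-scale panels (p ≳ 30).
- With four grades the severity trend has 2 residual degrees of freedom;
  its p-values are exact under normality of pooled effects but fragile to a
  single outlying grade network.
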