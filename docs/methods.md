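# Methods

Statistical specification of the `ahaging` package. Notation: the abundance
matrix `X` holds log2 abundances with proteins `i = 1..p` in rows and samples
`j = 1..n` in columns; `age_j` is chronological age in years, `sex_j ∈ {0,1}`,
`bmi_j` in kg/m²; the cohort is split into an `older` and a `young` group.

## 1. Input data and imputation (`core_data`)

Abundance tables are TSV with a `protein_id` column and one column per
sample; empty cells and the markers `NA`, `NaN`, `nan`, `na` are missing.
Values already on the log2 scale are expected; `raw_intensity=True` applies
`log2(x + 1)`. Metadata TSV requires `sample_id`, `age`, `sex`, `bmi`,
`group`, and optional `opacity_grade` (ordinal 1–5, clinical lens-opacity
style).

Missing values in DIA-style proteomics are predominantly left-censored, so
all imputation methods fill from the low end of each protein's observed
distribution:

- `half_min` — half of the protein's observed minimum.
- `min_prob` (default) — draws from `N(q0.01 of the observed values,
  (0.3·SD)²)` with SD floored at 0.1; seeded, deterministic.
- `knn` — mean over the `k = 5` nearest samples by RMS distance over
  co-observed proteins.
- `median` — the protein's observed median (not left-censored; provided as a
  neutral baseline).

Proteins missing in more than 50% of samples are dropped (logged); proteins
with zero observed values are an error. Observed cells are never altered.

Per-protein z-scores use the sample SD (ddof=1); zero-variance proteins are
dropped with a warning. `log2FC = mean(older) − mean(young)` on the log2
scale.

## 2. Synthetic cohort generator (`synthetic`)

Defaults mirror a small clinical cross-sectional study: 33 older (50–91 y)
and 19 young (19–35 y) donors, 634 proteins. Each sample gets sex ~
Bernoulli(0.5), BMI ~ N(24, 3²) truncated to [15, 40], and a latent
biological-age offset `δ_j ~ N(0, σ_δ²)` (default σ_δ = 6 y) defining
biological age `b_j = age_j + δ_j` and the true ager class (DA δ ≤ −5, AA
δ ≥ +5, CA |δ| < 2).

Protein `i` in sample `j`:

```
x_ij = baseline_i + effect · curve_i(t_ij) + β_sex·sex_j + β_bmi·(bmi_j − mean) + ε_ij
```

with `baseline_i ~ N(16, 3²)`, `ε ~ N(0, σ_noise²)`, `t = age` for trend
proteins and `t = b` for clock proteins. Seven trajectory archetypes map the
age span to [0, 1]: `linear_up/down`, `plateau_up/down` (endpoint-normalized
logistic, midpoint 0.3 of the span, scale 0.1), `late_rise/fall` (midpoint
0.7), and `nonmonotone` (normalized Gaussian bump, SD 0.18 of the span,
peak at midspan). Planted trend/clock proteins default to the six *monotone*
shapes: a nonmonotone trajectory has no defined direction and near-zero
linear age coefficient, so it cannot satisfy the dual AP criterion by
construction and is only planted when explicitly requested (e.g. for
trajectory-clustering studies).

Missingness is censor-then-MCAR: the lowest `censor_quantile` (5%) of each
protein's values are censored, then 5% of the remaining cells are removed at
random; if a protein would lose every cell its largest value is kept. Ground
truth (planted ids, signed total effects, archetype labels, δ, ager classes)
round-trips through JSON.

## 3. Aging proteins (`differential`)

A protein is an AP iff

1. Wilcoxon rank-sum older vs young, two-sided, BH-adjusted `padj < 0.05`
   (exact null enumeration when both groups ≤ 12 and tie-free, otherwise
   normal approximation with continuity and tie correction), and
2. OLS `x ~ 1 + age + sex + bmi`, two-sided t-test on the age coefficient,
   BH-adjusted `padj < 0.05`, and
3. `sign(log2FC) = sign(age β)` (direction `up` iff log2FC > 0).

The per-protein linear models share one design matrix, so thousands of
proteins are fit with a single vectorized multi-response OLS (limma-style
layout, but no variance moderation — with ~50 samples per model shrinkage is
unnecessary). Missing BMI is mean-imputed with a logged warning; a
rank-deficient design flags every record `not_estimable`. Spearman
correlation against `opacity_grade` (per AP and for mean-z composite up/down
scores) is reported with |r| bins at 0.4/0.6 (weak/moderate/strong).
`compare_ap_sets` partitions two directed AP lists into concordant /
discordant / exclusive ids (e.g. for cross-fluid comparisons).

## 4. Trajectories (`trajectories`)

Z-scored abundances are smoothed over age by locally weighted polynomial
regression: degree 2, span 0.75, tricube weights `(1 − (d/h)³)³` with `h` the
distance to the `⌈span·n⌉`-th nearest point, evaluated on a 50-point grid over
the observed age range. The smoother is implemented directly (installed
libraries provide only degree-1 lowess) and is validated against exact
reproduction of lines and quadratics at span 1.

Fitted profiles are clustered with agglomerative hierarchical clustering
(Euclidean distance, complete linkage by default; average/ward available),
cut at `k = 7` clusters. Each cluster is tested for AP over-representation
with the upper-tail hypergeometric probability; BH across clusters,
`padj < 0.05` retains a cluster.

## 5. Age clock (`clock`)

**Split.** 33 training samples drawn uniformly without replacement (seeded).

**Stability selection.** Candidate features (APs) are standardized on the
training set. λ_max = max|Xᵀ(y − ȳ)|/n; the grid is 100 log-spaced values
spanning 4 decades down from λ_max. Each of 1,000 repetitions draws a fresh
random 10-fold partition, fits LASSO at the CV-minimum λ, and records the
nonzero set. The signature is the features retained in strictly more than
half the repetitions. Repetitions differ only in the CV partition (and
optionally a bootstrap resample) — with n = 33 the partition alone perturbs
the selected λ enough to expose unstable features.

**Ridge.** Closed-form ridge `β = (XᵀX + λI)⁻¹Xᵀy` of age on the standardized
signature proteins plus sex (sex kept on its 0/1 coding), intercept
unpenalized; λ at the CV minimum over a log grid `10⁻³…10⁵` unless fixed.

**Calibration.** OLS of predicted on chronological age over the training
samples gives `(intercept, slope)`; `unbiased = (predicted − intercept)/slope`.
This forces the mean Δage over the calibration samples to 0 exactly (the OLS
residuals sum to zero, and the transformation is their rescaling) — the
deterministic property checked by `scripts/acceptance.py`.

**Outputs.** Δage = unbiased − chronological; MAE = mean |Δage|; ager classes
DA (Δage ≤ −5), AA (≥ +5), CA (|Δage| < 2), else unclassified; per-protein
Mann–Whitney AUC (older vs young orientation fixed, ties half); a
random-signature null re-fits the ridge clock on size-matched random protein
sets and records the test-set Pearson r. Per-sample assessments use the
full-AP ridge model; the sparse signature model is reported alongside with
its own calibration and test-set r.

## 6. Modulators (`modulators`)

For each AP, `x ~ 1 + age + sex + bmi + Δage` with a two-sided t-test on the
Δage coefficient; a modulator has raw `p < 0.05` (BH values reported for
stricter filtering). Constant Δage is rejected as degenerate. Separately,
`x ~ 1 + age + sex + bmi + I(AA) + I(DA)` with CA as reference and
unclassified samples excluded yields AA−CA and DA−CA contrasts; a protein is
labelled `accelerating`/`decelerating` by the significant contrast (smaller p
wins if both).

## 7. Enrichment (`enrichment`)

GMT files (set name, description, tab-separated members) are tested against a
query set with the upper-tail hypergeometric probability. The universe
defaults to all quantified proteins — the sampling frame of a proteomics
experiment — not the genome. Set members are intersected with the universe;
zero-overlap-with-universe sets report NaN; BH spans tested sets.

## 8. Pipeline and reproducibility (`pipeline`, `cli`)

`run_pipeline` executes impute → APs → trajectories → clock → modulators →
optional enrichment from one config (YAML-loadable), writing TSV/JSON per
stage plus `report.json` (sorted keys, no timestamps; byte-identical across
re-runs). One global seed fans out per stage via
`stage_seed = (seed XOR crc32(stage_name)) mod 2³¹`, so per-stage randomness
is independent and stable under config changes elsewhere. Failures re-raise
as `RuntimeError` naming the stage. The `ahaging` console script exposes each
stage and the full run.

## Numerical and design choices

- **Library reuse with independent oracles.** scipy `mannwhitneyu`,
  `hypergeom.sf`, `scipy.cluster.hierarchy`, statsmodels `multipletests`,
  scikit-learn `LassoCV` do the standard computations; the test suite checks
  each against brute-force enumeration or closed forms so the package's
  contracts do not silently depend on library defaults.
- **Exact-vs-asymptotic Wilcoxon cutoff at group size 12** keeps the exact
  null cheap (≤ C(24,12) splits) while the cohort-scale 33-vs-19 comparison
  uses the tie-corrected normal approximation.
- **Validation problem sizes** (e.g. 634 proteins / 52 samples, 40 planted
  trend proteins at effect 1.5 and noise SD 0.5; 15 clock proteins at noise
  0.3 and σ_δ = 6) are the package's own desk-scale choices: large enough for
  stable operating characteristics (pooled AP sensitivity ≥ 0.9 at observed
  FDP ≤ 0.1 over 5 seeded replicates), small enough to run in minutes on one
  CPU.
- **Clock-recovery validation plants clock proteins only** (no trend
  proteins): trend proteins predict chronological age as well as clock
  proteins do, so they legitimately enter the signature and would make a
  "no false features" criterion ill-posed.
- **Modulator-recovery validation uses linear archetypes** (constant
  derivative in age → uniform power across the age range) with a stronger
  effect (2.5), chosen from a power calculation before measurement.
- **Known limitation:** planted same-shape clock proteins are nearly
  collinear, so LASSO may drop a shadowed twin; signature recovery is
  evaluated at the 80% level for this reason.
- The generator is cross-sectional only: no longitudinal repeat measures, no
  batch effects, no protein–protein correlation beyond the shared age/δ
  drivers, and missingness is censor-plus-MCAR (no MNAR beyond censoring).
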