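# Methods

## The statistical models

### Kernel BLUP (MBLUP, GBLUP, GMBLUP)

The core regression is y = 1μ + Σ_k Z_k u_k + ε with u_k ~ N(0, K_k σ²_k)
and ε ~ N(0, I σ²_ε). After BLUE adjustment there is one record per line, so
each incidence matrix Z_k is the identity. A kernel is K = W Wᵀ/m from a
centered, standardized feature matrix (population-SD convention, ddof = 0,
so the mean diagonal is exactly 1); one kernel gives MBLUP (metabolites) or
GBLUP (SNPs), two kernels give GMBLUP.

The Gibbs sampler works in each kernel's eigenbasis: with K = Q D Qᵀ and
u = Qα, the full conditional of α is diagonal — variance
(1/σ²_ε + 1/(d_i σ²_k))⁻¹ per component — so a sweep costs O(n) per kernel
after a one-time eigendecomposition. Eigenvalues ≤ 1e-10 are dropped
(rank-deficient kernels are handled exactly). μ has a flat prior; σ²
components have scaled inverse-χ² priors, density ∝ (σ²)^−(ν/2+1)
exp(−νs/2σ²), ν = 5, with s = 0.5·Var(y)·(ν−2)/ν so the prior mean is half
the phenotypic variance. Sampled variances are floored at 1e-10.
Heritabilities are formed per retained sample — for GMBLUP each kernel's
share uses the full denominator σ²_um + σ²_ug + σ²_ε — then averaged.

Phenotypes of held-out lines are handled by data augmentation: the kernel is
built once from all lines, test records are set missing and redrawn each
iteration from N(μ + u_i, σ²_ε). This matches the convention of building the
relationship matrix as an unsupervised step and masking only phenotypes
inside cross-validation; the posterior for the parameters is the same as
conditioning on the observed records only.

### BayesC

Per-feature effects follow the spike/slab mixture a_j = 0 with probability
π (fixed at 0.99) and a_j ~ N(0, σ²_a) otherwise, with a common slab
variance. Indicator and effect are sampled jointly per feature from the
marginal-likelihood ratio, in a freshly randomized feature order each sweep.
The slab prior scale is set so the implied signal variance
(1−π)·m·E[σ²_a] has prior mean Var(y)/2 (the half-phenotypic-variance rule
applied to the aggregate, since a per-effect statement would depend on m).
As π → 0 the model becomes SNP-ridge, whose predictions coincide with
kernel BLUP on K = W Wᵀ/m — tested as an equivalence oracle. A consequence
of the aggregate scaling worth knowing: under a null trait the posterior
inclusion mean sits near the prior 1−π for m in the hundreds but below it
for small m (larger per-effect slab ⇒ stronger Occam penalty).

### Bivariate GBLUP

Two traits (a grain-size trait and one auxiliary metabolite) share the
genomic kernel: rows of U are N(0, Σ_g ⊗ G)-distributed genetic values,
residual rows N(0, Σ_ϵ). Both 2×2 covariances carry inverse-Wishart priors
with ν = 4 and scale S = 0.5·diag(Var(y₁), Var(y₂))·(ν−p−1), so the prior
mean is again half the phenotypic variance per trait (ν = 4, p = 2 makes
the multiplier 1). Sampling again rotates into the kernel eigenbasis, where
the n line-updates decouple into 2×2 problems solved with closed-form
inverses and Cholesky factors; inverse-Wishart draws use the Bartlett
decomposition specialized to p = 2. Missing trait records (the CV designs
create them) are augmented from their conditional given the observed
co-trait, the current genetic values, and Σ_ϵ — this augmentation is what
moves information from an everywhere-observed auxiliary metabolite to a
masked target trait in Scenario 2.

### Chain accounting

`McmcSpec` defaults pin the study setting: 30,000 post-burn-in iterations
after 10,000 burn-in, thinned by 10 (3,000 retained). "30,000 samples" was
read as post-burn-in iterations, not retained draws. The analysis drivers,
tests and acceptance script pass explicit shorter chains (typically
900–12,000 post-burn-in depending on the check) because the desk-scale
problems mix quickly; sampler output at those lengths is verified against
closed-form BLUP and REML oracles in the test suite.

## Preprocessing

- **MAF filter**: markers with minor-allele frequency strictly below 0.05
  are removed; dosages are recoded per marker to count the minor allele
  (sign does not affect kernels, the fixed rule makes output reproducible).
  Missing dosages are imputed to the per-marker mean rounded to {0,1,2}.
- **Standardization** divides by the population SD (ddof = 0). Zero-variance
  columns are dropped with a logged warning.
- **Run/batch correction** fits, per metabolite and condition,
  abundance = μ + run + batch + e with run and batch random, by EM-REML on
  Henderson's equations, and returns the data minus the estimated nuisance
  effects. Each factor's estimated effects are re-centered (count-weighted)
  into the intercept because the intercept/random-mean split is unidentified
  as the residual variance approaches zero.
- **BLUEs**: per condition and trait, value = line (fixed) + replicate
  (random) + e; the fixed-effect solutions are the per-line BLUEs. On
  balanced data they equal line means exactly.
- **Conventional heritability**: value = μ + genotype (random) + replicate
  (random) + e, reported as σ²_geno/(σ²_geno + σ²_e) — the replicate
  variance is excluded from the denominator (the source does not print its
  formula; this choice is pinned by tests). An independent direct-REML
  optimizer in the test suite cross-checks the EM path.

## Cross-validation designs

All designs draw repeated random 80/20 splits; the split of repeat r is a
pure function of (master seed, r), so different models compared on the same
design see identical splits and win fractions / paired tests are properly
paired. Classification splits are drawn per condition and combined;
hyperparameters are tuned by inner 5-fold CV on the training set only
(features standardized inside folds for scale-sensitive models). Prediction
CV masks test phenotypes but keeps whole-population kernels. The
metabolite-subset experiment redraws random subsets of each size.
Multi-trait Scenario 1 masks trait and auxiliary on test lines; Scenario 2
masks only the trait. "A beats B" in win fractions means strictly greater;
ties are reported separately. A test-set Pearson correlation that is
undefined (constant predictions) becomes NaN, is excluded from means, and is
counted. Paired one-sided t and Wilcoxon signed-rank tests compare bivariate
against univariate GBLUP across the 25 paired repeats; Benjamini–Hochberg
adjusted p-values are written alongside raw ones (raw is the primary
display, matching how such scans are usually reported).

## The synthetic-data generator

Defaults mirror the study scale: 190 lines per condition, 73 metabolites,
2,000 markers (desk scale standing in for 385k), 4 subpopulations, 3
replicates, MAF ∈ [0.05, 0.5].

- **Genotypes.** Markers are sampled in clusters of 10 that tag one latent
  binomial(2, p) variant: each marker allele copies the latent allele with
  probability 0.95 and is redrawn from the subpopulation frequency
  otherwise. Marginals stay binomial; within-cluster dosage correlations are
  ≈ 0.9. This redundancy is deliberate and load-bearing: with fully
  independent markers at m ≫ n the relationship kernel's eigenvalues
  concentrate near 1 (Marchenko–Pastur) and heritability is nearly
  unidentifiable — the REML standard error at n = 300, m = 2000 is ≈ 0.2,
  and no estimator can recover h² to ±0.1. Dense arrays are informative
  in practice precisely because markers are redundant; ten tagging markers
  per effective locus is a crude but adequate stand-in. Subpopulation
  frequencies drift from the ancestral frequency by a bounded perturbation
  scaled by `subpop_divergence` (default 0.15), enough for PCA on G to
  separate groups. Clusters violating the MAF range are resampled.
- **Metabolites.** Metabolite j in block b (blocks of 4, emulating reported
  tightly correlated quadruples) is √ρ·z_b + √(1−ρ)·e_j with block
  correlation ρ (default 0.5); both the block factor and the idiosyncratic
  part carry a genetic component (random 5-marker subsets, 30% of variance),
  which makes the Mantel correlation between G and M positive but small.
  The HNT copy redraws the non-genetic parts and adds ±1 SD shifts (random
  sign) to 30 of 73 metabolites. Run (6 levels) and batch (2 levels) effects
  of SD 0.5 are added per (level, metabolite), centered across levels — an
  uncentered draw would shift condition means and be indistinguishable from
  a real condition effect.
- **Phenotypes.** Line mean = 10 + genetic value (50 QTL among the markers,
  scaled to variance h²_g = 0.5) + metabolite channel (a fixed random
  combination of that condition's noise-free metabolite signals,
  residualized on the genetic value and scaled to h²_m = 0.2) + residual.
  The residual is orthogonalized against the signal parts and exactly
  scaled, so the line-mean variance split is (h²_g, h²_m, rest) by
  construction; per-replicate noise (variance 0.3) is subtracted from the
  line-level residual budget so line means have unit variance. HNT means
  shift by −0.3. An auxiliary trait with genetic correlation `rho_aux` to
  the target (heritability max(h²_g, 0.3)) supports the multi-trait
  experiments.

What the generator does **not** emulate: haplotype-level LD decay, MAF/LD
dependence of QTL, metabolite annotation structure, genotype × condition
interaction of genetic effects (the same genetic values act in both
conditions), and whatever drove the real panel's logistic-regression
failure — on synthetic data the 1-SD shift is an easy linear problem and
logistic regression classifies nearly perfectly, unlike the reported
below-chance behaviour. Passing tests therefore demonstrate correctness of
the estimators and designs under a controlled truth, not field performance.

## Numerical and design notes

- Mantel test: Pearson correlation of strictly-upper-triangle kernel
  entries; permutations act jointly on rows and columns of one matrix;
  one-sided (positive) by default with p = (count+1)/(n_perm+1), n_perm
  default 999. Sidedness is a flag; the hypothesis of shared structure makes
  the positive side the default.
- Kernel PSD repair clips negative eigenvalues at zero (trace-preserving
  enough at the round-off magnitudes involved); PCA uses the double-centered
  kernel with a deterministic sign convention (largest-magnitude loading
  positive).
- RF vote ties follow scikit-learn's mean-probability rule (first class on
  exact ties). Default tuning grids (the study's were unreported): SVM/SVR
  C ∈ {0.1, 1, 10, 100}, γ ∈ {0.5, 1, 2}/m; RF 500 trees,
  mtry ∈ {√m, m/3, m}; XGBoost depth ∈ {2, 4, 6}, η ∈ {0.05, 0.1, 0.3},
  200 rounds. All overridable per ModelSpec.
- Null-trait posterior h² under the half-phenotypic-variance prior does not
  reach zero: the ν = 5 prior keeps ≈ 0.1 posterior mass at desk-scale n
  even when REML is ~0. This is a property of the stated prior, not of the
  sampler.
- Under a null auxiliary (r_g = 0) the bivariate model pays a small price
  for estimating a useless genetic correlation, so the mean Scenario-2 gain
  is slightly negative and the paired one-sided t-test is conservative; at
  the default scale (n = 190) its rejection rate is a few percent. At much
  smaller n the deficit dominates and the test becomes degenerate-
  conservative — another reason the calibration experiments run at the
  default scale.

## Problem sizes used by tests and the acceptance script

Sampler-oracle checks run at n = 50–300 with 2,400–12,000 post-burn-in
iterations; heritability recovery at n = 300, m = 2,000 over 10 fixed
generator seeds; the Scenario-2 experiments at the default n = 190 with 25
CV repeats (100 replicates for the null calibration); classification at the
default 190 + 190 lines with 25 repeats and the subset experiment at sizes
10–60 × 10 resamples. The acceptance script runs the same stages once each
at these sizes with 15–25 CV repeats.
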