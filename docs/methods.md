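# Methods

`cascadeqtl` analyses how common genetic variants regulate gene
expression as the signal propagates down the central dogma — transcript
abundance (RNA-seq counts), ribosome occupancy (ribo-seq counts) and
protein abundance (mass-spec log intensities) — and how that regulation
connects to a complex-trait GWAS. This note describes the generative
model behind the synthetic-data module, each analysis stage and its
assumptions, the numerical choices, and what the synthetic studies do and
do not demonstrate about real data.

## The cascade generative model

For gene *g* with causal cis dosage `G_c` (alt-allele count in {0,1,2}),
an optional second "specific" cis variant `G_s` in a different LD block,
shared hidden confounders `F` (n × K Gaussian, K = 5 by default) and
independent noise `ε`:

```
mRNA     M = β·G_c                                   + F·l_m + ε_m
ribo     R = λ_r·β·G_c + γ_r·G_s                     + F·l_r + ε_r
protein  P = λ_p·(λ_r·β·G_c + γ_r·G_s) + γ_p·G_s     + F·l_p + ε_p
```

* `β` — per-allele eQTL effect on the (log2-scale) transcript.
* `λ_r, λ_p ∈ [0,1]` — translational and post-translational attenuation.
  `λ_r = λ_p = 1` with `γ = 0` reproduces identical genetic effects at
  all three layers; `λ_r = 0` removes all mRNA-derived genetic signal
  downstream.
* `γ_r, γ_p` — genetic effects arising only at the ribo / protein layer
  (omics-specific QTLs). By default they act at the eQTL variant; with
  `separate_specific_variant` they act at a variant in a different LD
  block of the gene's window, modelling an omics-specific QTL that is
  genetically independent of the eQTL.

All layers share a log2 convention: mRNA and ribo are emitted as
negative-binomial counts (gamma–Poisson, dispersion 0.1 by default) whose
log2 mean is a gene baseline plus the latent predictor, so the per-allele
slope on log2-CPM equals the latent effect; protein is the latent
predictor as a log2 abundance directly. The asymmetry is deliberate: two
emission families, one latent cascade, mirroring sequencing counts versus
mass-spec intensities.

Genotypes are drawn from a latent Gaussian copula: each LD block shares a
factor with pairwise correlation `ld_rho`, and latent values are
thresholded at the Hardy–Weinberg genotype frequencies of each variant's
MAF. Blocks are separated by >2 Mb so one gene's ±1 Mb cis window never
reaches another gene's variants. The GWAS outcome is a continuous
liability — the sum of causal genes' protein-layer genetic components,
plus optional direct variant effects (horizontal pleiotropy) — scaled to
a chosen heritability, measured on an independently redrawn cohort so
two-sample MR assumptions hold by construction. A binary case/control
outcome is deliberately out of scope; the liability scale keeps every
downstream estimand linear.

## Preprocessing

Counts → log2-CPM with the standard +0.5 count / +1 library pseudocount;
genes with CPM < 1 (protein: log abundance < 1) in **more than** 75% of
samples are removed (strict "more than": a gene low in exactly 75% is
kept). Outlier samples are flagged by network connectivity — the sum of
a sample's Pearson correlations with all others — z-scored across
samples, at per-layer cutoffs (−5 RNA, −3.5 ribo, −6 protein defaults);
the correlations are summed signed, not folded. Quantile normalization
forces every sample onto the mean order-statistic distribution, with ties
receiving the mean of the reference values they span. Protein isoforms
collapse to one row per gene by highest median abundance (ties broken by
lexicographically smallest isoform id); missing protein values are
imputed with the per-gene minimum before normalization.

Hidden nuisance factors are estimated as principal components of the
gene-standardized matrix — a deterministic surrogate for latent-factor
methods, adequate here because the downstream use (residualize k factors,
then center/scale each gene) is method-agnostic. The elbow helper counts
factors whose variance explained exceeds both 1% and the Marchenko–Pastur
upper bulk edge for an iid matrix of the same shape; without the second
term every PC of a small matrix trivially clears a fixed 1%. Residualized
matrices have per-gene mean 0 and sd 1 (|mean| < 1e-8); genes whose
residuals are constant are dropped with a warning.

## Cis-QTL mapping

Per gene, all common variants (empirical MAF > 0.05) within the gene body
± 1 Mb are tested by simple linear regression on the residualized
expression. The gene-level empirical p-value permutes expression labels
(preserving LD), records the minimum nominal p per permutation, fits a
Beta(a, b) to the permutation minima by maximum likelihood
(method-of-moments initialization, L-BFGS-B) and evaluates its CDF at the
observed minimum; degenerate fits fall back to the direct rank p
(r+1)/(n_perm+1). Permutations are vectorized on the correlation scale
(one matrix product per gene), which is what keeps 1000-permutation scans
of hundreds of genes in seconds.

Study-wide FDR uses Storey q-values: π0 estimated on the λ grid
0.05–0.95 (step 0.05) with a cubic least-squares smoother evaluated at
the largest λ — the stable analogue of a df = 3 smoothing spline — and
clipped to (0, 1]. A calibration simulation comparing unweighted and
precision-weighted cubic fits, a quadratic fit and a GCV smoothing spline
found the unweighted cubic approximately unbiased in all regimes tested;
its sampling sd is nonetheless ~0.1–0.17 for vectors of a few hundred
p-values, which bounds how precisely any π1-based quantity can be
estimated at desk scale.

## Attenuation analyses

π1 replication: each discovery gene's lead variant is re-tested in the
replication layer; π1 = 1 − π0 of that p-vector. The 3×3 matrix over
layers, and the asymmetry statistic π1(downstream→upstream) −
π1(upstream→downstream), summarize directional sharing. The
direction-aware replication rate additionally requires slope sign
agreement at a grid of p cutoffs.

Effect profiles for an external eQTL panel are computed on **log2-scale
quantifications**, not standardized residuals, so the three layers are
compared in interpretable per-allele log2-fold-change units; the mean
|slope| per layer carries a normal-approximation 95% CI and pairwise
t-tests. Because |slope| of a noisy estimate is upward-biased when the
effect is within ~2 se of zero (folded-normal inflation), attenuation
ratios are only clean when the panel is ascertained for strong effects —
exactly the situation an external, independently discovered eQTL panel
provides, and the reason the attenuation study (below) profiles its
strong-effect class only.

### The attenuation study conditions

`simulate.attenuation_study` (500 genes, n = 200, λ_r = 0.75, λ_p = 0.8)
contains three gene classes: ~35% strong eQTL genes (|β| = 0.5 +
half-normal(0.3)) forming the external panel; ~45% weak genes (|β| ~
U(0.15, 0.35)) sitting near the detection limit — the class in which
downstream attenuation genuinely erases replication and which therefore
creates the asymmetric π1 matrix; and ~20% null genes so FDR control is
exercised. Residual noise increases down the cascade (mRNA 1.0, ribo
1.3, protein 1.8), reflecting ribo-seq and mass-spec being technically
noisier than RNA-seq; together with the attenuation this reproduces the
qualitative discovery ordering eQTL > rQTL > pQTL. Variants are common
(MAF 0.2–0.5). These choices were fixed once, after verifying across
seeds that ratio recovery and asymmetry are jointly attainable, and are
not tuned per run.

## Shared vs omics-specific QTL genes

Per gene and focal layer: an elastic net (mixing parameter 0.5, penalty
by 10-fold CV along a 15-point path) predicts residualized expression
from cis dosages; retention requires cross-validated correlation
R_cv > 0.1 with p < 0.05, where R_cv correlates *out-of-fold* predictions
with observations. The focal expression is then regressed (OLS) on the
other layers' imputed expression; near-collinear imputations (R² > 0.95
on those already included — e.g. mRNA and ribo under no translational
attenuation) are dropped, because jointly fitting two almost-identical
regressors amplifies a noise direction by the inverse of their angle and
corrupts the residual. The conditional model refits the same predictor
class on the conditioned expression **at the original model's penalty**,
so R_c² = cor²(imputed_original, imputed_conditional) compares the same
model before and after conditioning rather than adding re-tuning noise.

The permutation null shuffles the sample labels of the other layers'
imputed vectors — one shared permutation per iteration, preserving their
mutual correlation — rebuilds the conditional model, and recomputes R_c².
Empirical p = (#{perm R_c² ≤ observed} + 1)/(n_perm + 1): a small
observed R_c² relative to the null is evidence of cross-layer sharing.
After Benjamini–Hochberg across tested gene × layer pairs: shared iff
FDR < 0.1 and R_c² < 0.5; specific iff FDR > 0.1 and R_c² > 0.9;
otherwise unclassified. Entry requires a retained original model in the
focal layer plus at least one retained model in another layer (otherwise
conditioning is undefined).

A subtle calibration requirement, found empirically and worth stating:
the null is honest only when the cis genotype space is high-dimensional
relative to the sample count. A label-shuffled imputation vector can be
absorbed by the conditional elastic net only up to ~k/n of its variance
(k cis variants, n samples), whereas the observed genotype-derived
imputation is fully absorbable; with few cis variants this asymmetry
systematically deflates the null and pushes every gene toward "shared"
(protein-specific recovery was 31% at 10 variants/gene, 65% at 100, ~78%
at 200 with n = 185). Real ±1 Mb windows contain hundreds of common
SNPs, so the canonical `specificity_study` uses 200 cis variants per
gene.

## Colocalization

Per-variant evidence is the Wakefield approximate Bayes factor,
log ABF = ½(log(1−r) + r·z²) with r = prior_sd²/(prior_sd² + se²) and
prior_sd = 0.15 on standardized effects. The five single-causal-variant
hypotheses (none / QTL-only / GWAS-only / distinct variants / shared
variant) are enumerated with priors p1 = p2 = 1e-4, p12 = 1e-5 and
accumulated in log space (log-sum-exp); a single-variant region has
PP3 = 0 exactly. QTL slopes and standard errors come from the nominal
cis scan; GWAS evidence uses beta/se when present, else z with
se = 1/√n. The reporting threshold is PP4 ≥ 0.7. The coloc study region
uses a discovered-lead-eQTL effect size (QTL R² = 0.15 at n = 185, with
the realized R² fixed exactly by orthogonalized noise) and a GWAS locus
explaining 1% of outcome variance at n = 5000; a weaker QTL cannot
overcome the 1:10 prior odds p12/p2 regardless of implementation.

## TWAS

The gene-level summary-statistic association is
z_gene = Σ_i w_i (σ_i/σ_g) z_i with σ_g = √(wᵀΣw), Σ the dosage
covariance over the model's variants computed from the QTL cohort (the
models' training data — the standard practice when the GWAS cohort's LD
is unavailable). Protein isoforms combine by the Cauchy combination test
(T = mean tan((0.5 − p_i)π)), which is robust to dependence between
isoforms and needs no correlation estimate; this choice of omnibus test
is a stand-in — the combination method behind the original
protein-isoform omnibus analysis is not specified, and any valid omnibus
test could be substituted. Family-wise error is Bonferroni within layer
with boundary-inclusive significance at 0.05. Calibration of the null
depends on the reference LD being accurate and on weights aligned with
that LD: the TWAS-null study therefore trains its weights with the
package's own elastic net on a large cohort (n = 1000) over genes laid
two per LD block. Even perfectly calibrated, a 5%-level family-wise test
leaves any "zero hits in ≥95% of replicates" check operating exactly at
its nominal boundary — a structurally knife-edged criterion.

## Mendelian randomization

Two-sample (gene → outcome): instruments are greedily LD-clumped cis
SNPs (p < 0.05, window 1000 kb, r² ≤ 0.5); alleles are harmonized by
flipping swapped-allele outcome effects and dropping palindromic (A/T,
C/G) and allele-incompatible variants. The IVW estimate is the
fixed-effect weighted regression through the origin (weights 1/se_out²),
se = √(1/Σw x²); one instrument reduces to the Wald ratio. MR-Egger
orients exposure betas positive and adds a free intercept whose p-value
diagnoses directional pleiotropy; the covariance is model-based
(fixed-effect — the reported outcome standard errors are taken at face
value rather than rescaled by residual heterogeneity). The rescaling
convention would make the intercept z asymptotically scale-invariant
(≈1.4) under 30%-of-instruments mixture pleiotropy, capping power near
25% for any pleiotropy magnitude; the model-based convention keeps the
intercept test powered while remaining exact under the no-pleiotropy
null. A gene passes iff BH-FDR < 0.1 (across the gene × layer family)
and Egger intercept p > 0.05.

One-sample (layer → adjacent layer): two-stage least squares with
standard errors from residuals at the *observed* exposure, first-stage F
reported and F < 10 flagged as weak instruments; collinear instrument
columns are dropped. On standardized expression the stage-2 intercept is
mechanically ~0, so the intercept-based pleiotropy screen is vacuous in
this setting and the verdict effectively reduces to the FDR criterion —
a limitation inherited from applying an intercept test to centered data.
The two pathway verdicts (mRNA→ribo, ribo→protein) combine into
both-/single-/none-passed cascade classes; an untested pathway (no
instruments survive clumping) counts as not passed.

## Problem sizes and determinism

The acceptance checks run at: 500 genes × n = 200 for attenuation and
replication; 500 null genes × 1000 permutations for calibration plus 20
replicates of 200 genes for FDR control; 200 shared + 50
protein-specific genes (n = 185, 50 permutations) for the classifier; 50
replicates per colocalization arm; 200/100 simulated gene sets for Egger
error rates; 50 genes per cascade class; 20 TWAS-null replicates. All
randomness flows from explicit integer seeds; per-gene seeds derive from
a master seed so results are reproducible under any iteration order.

## What the synthetic studies do not show

The generator draws independent samples (no relatedness or ancestry
structure), uses block-equicorrelated LD rather than haplotype
recombination, emits a continuous liability rather than a case/control
trait, gives every gene the same baseline expression, and ties each
gene's signal to one (or two) truly causal cis variants. Passing tests
therefore demonstrate the estimators' correctness and calibration under
the stated model — not robustness to population structure, fine-scale
LD, expression-level heteroscedasticity, isoform complexity or
case/control ascertainment. The π0-smoother variance analysis above also
means π1-based statements at a few hundred genes carry irreducible
sampling noise of ±0.1 or so regardless of implementation.
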