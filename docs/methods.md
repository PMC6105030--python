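# Methods

`popgex` studies how the genetic architecture of gene expression differs
between populations, and what that does to genetic predictors of
expression carried from one population to another. Everything runs on
synthetic cohorts whose architecture is known exactly, so every estimator
can be checked against generative truth.

## Synthetic cohorts

**Allele frequencies.** Populations diverge from a shared ancestral pool
under a Balding–Nichols model: with ancestral frequency `p` (uniform on
(0.1, 0.9) by default) and divergence parameter `F`, a population's
frequency is Beta-distributed with mean `p` and variance `F·p(1−p)`. `F`
plays the role of the expected pairwise F_ST between two populations with
the same divergence. No generative model is implied by the biology being
emulated — any mechanism producing differentiated frequencies measurable
by F_ST would do — but Balding–Nichols is the standard choice and has the
F_ST calibration built in. Admixed cohorts are approximated by
intermediate `F` values; local-ancestry tracts are out of scope.
Genotypes are binomial(2, freq) per sample; there is no linkage
disequilibrium within a population beyond what frequency sharing induces.
That is the main respect in which these cohorts are easier than real
data: tagging of causal variants by nearby markers, and LD differences
between populations, are not represented, so passing tests show estimator
correctness under the model, not robustness to LD structure.

**Cis architecture.** Each gene has `n_causal` causal SNPs (default 1–5)
sampled uniformly from its cis window among SNPs with MAF ≥ 0.01 in every
population (rarer causal variants give untestable architectures). Causal
effects are drawn from a multivariate normal with unit marginals and
between-population correlation `rho_effects`; `rho = 0` is the
independent-effects null, `rho = 1` identical effects.

**Expression.** `y = a·g + e` with `e ~ N(0,1)` and `g` the genetic
value. The scale `a` is chosen so that `var(a·g)/(var(a·g)+1)` equals the
target h² using the *realized* sample variance of `g` in the simulated
cohort, not the theoretical `2pq`-based variance. This makes recovery
targets exact in expectation at finite n. Calibration is tested: over
200 replicate genes the mean realized genetic-variance fraction is within
±0.02 of target. A fixed `genetic_scale` can be supplied instead, which
carries one population's scaling into another so that heritability
differences arise mechanistically from allele-frequency change alone —
used for the divergence-mechanism experiments.

All randomness flows through explicitly seeded `numpy` generators; seeds
are required arguments, and the pipeline derives per-stage seeds by
hashing (master seed, stage name), so inserting a stage never shifts
another stage's draws.

## cis-eQTL mapping

Expression and dosage are residualized on an intercept plus covariates
(Frisch–Waugh), then each gene is tested against every SNP with
within-cohort MAF > 0.01 whose position lies in the closed interval
TSS ± 1 Mb (1-based coordinates, strand ignored). Per-SNP slope, SE and
two-sided t p-value use residual df = n − 2 − #covariates. FDR is
Benjamini–Hochberg over all SNP-gene tests in the run by default; a
per-gene option exists behind a flag (the common choice for this kind of
scan is global, and eSNP/eGene counting assumes it).

Covariates are genotype principal components (PCA of column-standardized,
LD-pruned dosages) and hidden expression factors. The hidden factors are
principal components of the expression matrix after residualizing on the
protected covariates — a variance-capturing stand-in for latent-factor
methods such as PEER. Factor-count grids {0, 10, 20, 30} and PC grids
{0, 3, 5, 10} are configurable; planted batch-shift confounders load on
factor 1 with |r| > 0.9 in tests.

LD pruning is a greedy positional scan: a SNP is dropped when its squared
dosage correlation with any previously kept SNP in the trailing window
(default 50 SNPs) exceeds the threshold (default r² > 0.3). Monomorphic
SNPs have undefined correlation and are always kept.

## Storey π0/π1

π0(λ) = #{p > λ}/(m(1−λ)) on the grid λ = 0.05, …, 0.95. The final
estimate extrapolates to λ → 1 with a least-squares cubic in λ evaluated
at the maximum grid point, clamped to [0, 1] (clamp events are logged).
This is the df-3 cubic-smoother family of the standard q-value recipe;
an R-style smoothing spline with exact df control has no direct scipy
equivalent, and on these grids the cubic fit behaves equivalently. With
fewer than 100 p-values the fixed-λ estimate at λ = 0.5 is used.
Calibration: null bias ≤ 0.02 at m = 10,000; a 70/30 null/alternative
mixture (alternatives two-sided normal, shift 3) is recovered within
[0.25, 0.35].

The replication rate takes discovery associations at FDR < 0.05 that are
present in a replication cohort and applies the π0 estimator to their
replication p-values; π1 = 1 − π0 is the expected true positive rate.

## cis heritability and genetic correlation (REML)

**GRMs.** K = W·Wᵀ/m with W the column-standardized dosages of the
gene's cis SNPs (sample mean and SD; monomorphic and MAF < 0.01 SNPs
dropped). For the bivariate model, all three matrices — A (population
1 block), B (population 2 block) and the cross block C — are blocks of
the single GRM of the stacked cohort with combined-sample
standardization. This matters: if A and B are standardized
per-population while C uses the combined sample, the joint genetic
covariance is not positive semidefinite (the between-population frequency
offsets give C a large near-rank-one component), and the covariance
component cannot move off zero. With all blocks from one PSD matrix, the
phenotypic covariance

    V = [ A·σg1² + I·σe1²     C·σg12        ]
        [ Cᵀ·σg12             B·σg2² + I·σe2² ]

is positive definite whenever |rG| ≤ 1 (the genetic part is a convex
combination of congruence transforms of the combined GRM). The residual
covariance is zero by construction: no individual belongs to both
populations.

**AI-REML.** The restricted log-likelihood is maximized by
average-information quasi-Newton steps (AI_ij = ½·yᵀP·V_i·P·V_j·P·y) with
step halving, a first-iteration EM step, and an EM fallback when the AI
system is singular — accepted iterations never decrease the likelihood.
Variances are floored at 1e-8·var(y) by projection; the covariance is
unconstrained during iteration. Convergence is |Δ log L| < 1e-8
(configurable), max 100 iterations; starting values σg² = σe² = var(y)/2,
σg12 = 0. When no ascent step is representable the iterate is pinned
against the |rG| = 1 positive-definiteness boundary; this is a
constrained maximum and is reported as converged (these are the genes
that pile up at ±1). A genetic variance at the zero floor makes rG
undefined; such fits are returned non-converged with reason "degenerate
genetic variance" and excluded from aggregation — this is the package's
convergence-screening rule.

The univariate fit uses a one-time eigendecomposition of the GRM so each
iteration is O(n); the bivariate fit is dense (LAPACK Cholesky
inversion, ~15 ms per iteration at n = 600 on one core). rG =
σg12/√(σg1²σg2²); its SE comes from the delta method on the inverse AI
matrix.

**Bending.** If the 2×2 genetic (co)variance matrix is not positive
definite (equivalently |rG| > 1), its eigenvalues are floored at
1e-6·trace and the matrix rebuilt, which pulls rG strictly inside
[−1, 1]; the event is recorded in the `bent` flag. The exact recipe used
by other implementations is unpublished; eigenvalue flooring is this
package's documented choice.

**Aggregation.** Mean rG with the SE of the mean over converged genes,
optionally restricted to genes whose minimum (or single-population) h²
exceeds each threshold in a grid.

Recovery under the study conditions (n = 300 per population, 80-SNP cis
blocks, 5 causal SNPs, h² = 0.3): planted ρ ∈ {0.3, 0.6, 0.9} is
recovered as mean rG within ±0.07 and strictly ordered; the h²-matched
independent-effects null gives mean rG within ±0.05 of zero with point
masses at both −1 and +1.

## Elastic-net prediction

Per gene, the penalized objective

    (1/2n)·Σ(y − b0 − Xw)² + λ·(α‖w‖₁ + (1−α)/2·‖w‖₂²)

is minimized over a geometric path of 100 λ values spanning three orders
of magnitude below λ_max (the smallest λ with an all-zero solution),
computed once per gene and shared across folds. Fitting is scikit-learn
coordinate descent (its objective matches the form above exactly with
`alpha=λ, l1_ratio=α`); columns are standardized internally and weights
returned on the dosage scale. α = 0 is rejected (λ_max undefined for pure
ridge); the working grid is {0.05, 0.5, 1}. λ is selected at the minimum
mean inner-CV squared error (10 folds).

Performance is nested cross-validation: 5 disjoint outer folds; per fold
a full inner-CV fit on the complement predicts the held-out fold, and
R² = 1 − Σ(y_o − y_p)²/Σ(y_o − ȳ_o)² is averaged over folds (negative
values possible and expected under the null — hence the R² ≥ 0 floor for
gene inclusion). The deployed model is refit on all samples; its nonzero
weights, effect/other alleles and training effect-allele frequencies form
the portable weight set. Expression is residualized on covariates before
fitting; covariates are never penalized regressors.

**Harmonization.** Test SNPs match by chrom:pos; exact allele matches use
the dosage, swapped ref/alt use 2 − dosage, strand-ambiguous (A/T, C/G)
test SNPs are excluded. Missing model SNPs default to mean imputation at
2× the training effect-allele frequency ("freq_impute"; keeps gene
coverage comparable across cohorts), with a strict "drop" option.
Predictions are flip-invariant to ref/alt labeling by construction.

**Transfer.** Per-gene Pearson correlation between predicted and observed
expression; π1 of the correlation p-values at each training-R² inclusion
threshold {0, 0.01, 0.05, 0.1, 0.2} (π1 is not estimated below 10 genes).

## F_ST and the divergence mechanism

Per-SNP differentiation uses the Weir–Cockerham (1984) two-deme estimator
θ = a/(a+b+c) from allele frequencies, sample sizes and observed
heterozygosity (fractional dosages in (0.5, 1.5) count as heterozygous; a
Hudson estimator is available behind a flag for sensitivity analysis).
SNPs monomorphic in the pooled sample are undefined and flagged. For
genome-wide calibration the multi-locus ratio-of-sums θ = Σa/Σ(a+b+c) is
the right summary — it matches the generative F within ±0.01 over 10,000
SNPs, whereas the per-SNP mean of ratios is biased downward because each
SNP's noisy between-population component also sits in its own
denominator. Per-model summaries follow the per-SNP form: the unweighted
mean F_ST over a model's SNPs, and a β-weighted version, mean(β·F_ST),
using the signed β (the literal reading of "multiplied by the model beta
value"); an absolute-β variant is provided since signed products can
cancel.

The mechanism test splits genes into divergent and similar groups by
|R²₁ − R²₂| at each threshold in {0.05, …, 0.3} and compares the model
F_ST summaries by two-sided Wilcoxon rank-sum (exact enumeration when
both groups ≤ 20, otherwise normal approximation with continuity
correction). In the planted design, half the genes draw causal SNPs from
a weakly diverged pool (F = 0.02) and half from a strongly diverged pool
(F = 0.4), with effects and genetic scale shared between populations so
that any performance drop comes from frequency change alone.

## Pipeline

A YAML-configured orchestrator runs simulate → eqtl → pi1 → rg → train →
predict → fst → report, with a JSON manifest (config hash, per-stage
outputs and wall-clock) enabling resume-at-first-incomplete-stage.
Default parameters are the working grids above (3 PCs, 10 hidden
factors, α ∈ {0.05, 0.5, 1}, FDR 0.05). All tabular I/O is TSV; genotypes
round-trip through minimal VCF v4.2 (GT/DS) and dosage tables. The demo
configuration (2 populations × 300 samples, 200 genes, 150 cis SNPs per
gene) completes on one core in well under 15 minutes.

## Problem sizes and limitations

The test suite and the acceptance script size their panels to desk
scale: bivariate-REML panels use 300 samples per population with 80-SNP
cis blocks (1,000 null fits, 300 genes per planted ρ); elastic-net
panels use 300 samples with 60-SNP blocks and 150–300 genes; F_ST
calibration uses 10,000 SNPs. These sizes keep every check a few minutes
on one core while leaving the statistical tolerances meaningful; the
acceptance script scales gene counts down further (they are reported in
its output as `n`).

Known limitations: no LD beyond frequency sharing (see above); no
explicit admixture tracts; the hidden-factor estimator is PCA, not a
variational factor model; per-gene rG estimates at n = 300 are
individually very noisy (only means over many genes are interpretable,
and the ±1 boundary masses are a real feature of the small-sample
likelihood); the bivariate fit defaults to intercept-only fixed effects
(PCs can be passed but are not included by default in simulation mode).
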