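# popgex

Cross-population genetic architecture of gene expression: cis-eQTL
mapping, replication π1, cis-heritability and bivariate genetic
correlation by AI-REML, elastic-net transcriptome prediction with nested
cross-validation, cross-population transfer of prediction models, and
F_ST-based analysis of why transfer fails.

## Who this is for

Statistical geneticists studying how well expression quantitative trait
loci (eQTLs) and transcriptome prediction models (PrediXcan/TWAS-style
SNP weight sets) carry between populations of different ancestry. Real
cohorts for this question are controlled-access; `popgex` ships a
first-class synthetic-cohort generator with known cis architecture so the
whole analysis chain can be exercised, validated against generative
truth, and reused on real genotype/expression tables where available.

## The models at the core

**cis-eQTL scan.** For each gene, OLS of expression on alt-allele dosage
plus covariates for every SNP with MAF > 0.01 within ±1 Mb of the TSS;
Benjamini–Hochberg FDR over all tests; eSNP/eGene counts at FDR < 0.05.
Replication is summarized by Storey's π1 = 1 − π0, the expected true
positive rate of discovery-significant pairs in an independent cohort.

**Genetic correlation.** Per gene, a bivariate mixed model on two
disjoint cohorts,

    y₁ = X₁b₁ + Z₁g₁ + e₁,   y₂ = X₂b₂ + Z₂g₂ + e₂

with phenotypic covariance built from cis-window genetic relationship
matrices (A, B and the cross-population block C, all blocks of one
combined-sample GRM). AI-REML estimates (σ²g1, σ²g2, σg12, σ²e1, σ²e2);
rG = σg12/√(σ²g1·σ²g2), constrained to [−1, 1] by bending (eigenvalue
flooring of the genetic covariance matrix). Per-gene estimates at n of a
few hundred are noisy — the interpretable quantity is the mean rG over
many genes, optionally restricted to genes above an h² threshold.

**Prediction.** Per-gene elastic net over cis dosages,
(1/2n)Σ(y−b0−Xw)² + λ(α‖w‖₁ + (1−α)/2‖w‖₂²), α ∈ {0.05, 0.5, 1}, λ
tuned by 10-fold inner CV on a shared 100-value path; performance is the
mean held-out R² over 5 outer folds (nested CV). Final weights are refit
on all samples and carried to a test cohort after allele harmonization
(flip 2−d on ref/alt swaps, drop strand-ambiguous SNPs, frequency-impute
missing ones). Transfer quality is the π1 of per-gene predicted-observed
correlations at training-R² inclusion thresholds {0, 0.01, 0.05, 0.1,
0.2}.

**Divergence mechanism.** Per-SNP Weir–Cockerham F_ST between the two
populations; per-model mean and β-weighted F_ST; Wilcoxon rank-sum
comparison of model F_ST between genes with divergent vs similar
predictive performance across |ΔR²| thresholds 0.05–0.3.

## Worked example

Run the full pipeline on a small synthetic design (two populations of
300, 60 genes, effect correlation 0.8):

```bash
popgex all --config examples/demo.yaml
cat demo_run/report.txt
```

or from Python:

```python
from popgex.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(
    populations=[
        {"label": "A", "n_samples": 300, "ancestry_fst": 0.1},
        {"label": "B", "n_samples": 300, "ancestry_fst": 0.1},
    ],
    n_genes=60, n_snps_per_gene=60, n_causal=3, rho_effects=0.8,
    n_pcs=3, n_hidden_factors=10, seed=11, output_dir="demo_run",
)
run_pipeline(cfg)
```

The report (`demo_run/report.txt`) contains, among other tables:

```
## cis-eQTL counts (FDR < 0.05)
A: eSNPs=98 eGenes=57
B: eSNPs=105 eGenes=59

## mean rG by h2 threshold
threshold  mean_rg  se_mean  n_genes
0.0        0.732    0.056    60
0.1        0.722    0.064    49
0.2        0.738    0.069    40
0.3        0.727    0.088    29
0.4        0.726    0.114    18

## alpha comparison (proportion lasso better)   (population A)
alpha  n_genes  n_lasso_better  proportion_lasso_better
0.05   60       56              0.933
0.5    60       49              0.817
```

Reading this: with three causal SNPs per gene, nearly every gene is an
eGene in both cohorts at n = 300. The mean per-gene rG estimate sits
near the planted effect correlation of 0.8 at every h² threshold — the
planted rho here is the same for all genes, so thresholding changes the
precision (watch `se_mean` grow as genes drop out) but not the level; a
rising profile appears when the architecture itself couples rG to h².
The lasso beats the near-ridge model (α = 0.05) for 93% of these
sparse-architecture genes but is much closer to the α = 0.5 mixture, the
signature of a sparse genetic architecture. The transfer table
(`transfer_pi1.tsv`) shows π1 of cross-population prediction at each
training-R² threshold, and `fst_divergence_test.tsv` the Wilcoxon
comparison of model F_ST between divergent and similar genes.

## Layout

- `src/popgex/synth_data.py` — population specs, SNP/genotype/expression
  containers, Balding–Nichols frequencies, architecture and expression
  simulation, h²-matched null, text-format writers
- `src/popgex/cis_eqtl.py` — LD pruning, genotype PCs, hidden expression
  factors, the cis scan, BH FDR, eSNP/eGene summaries
- `src/popgex/pi1.py` — Storey π0/π1 and replication π1
- `src/popgex/greml.py` — cis GRMs, univariate and bivariate AI-REML,
  bending, h²-threshold aggregation
- `src/popgex/elastic_net.py` — elastic-net CV, nested CV, model store,
  allele harmonization, transfer evaluation, α comparisons
- `src/popgex/divergence.py` — Weir–Cockerham F_ST, model summaries,
  divergence Wilcoxon sweep
- `src/popgex/pipeline.py`, `src/popgex/cli.py` — YAML-configured stage
  orchestration with manifest/resume, `popgex` CLI

See `docs/methods.md` for model assumptions, numerical choices and
limitations.
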