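"""Per-gene elastic-net expression predictors and cross-population transfer.

The penalized objective is

    (1/2n) sum(y - b0 - X w)^2 + lambda * (alpha ||w||_1 + (1-alpha)/2 ||w||_2^2)

with mixing parameter alpha in (0, 1]: alpha = 1 is the lasso (sparse
architecture), small alpha approaches ridge (polygenic).  lambda is chosen
by inner cross-validation on a geometric path of 100 values spanning three
orders of magnitude below lambda_max (the smallest lambda with an all-zero
solution); the path is computed once per gene and shared across folds.
Model performance is the nested-cross-validation R^2:

    R^2 = 1 - sum((y_o - y_p)^2) / sum((y_o - mean(y_o))^2)

averaged over outer folds, where predictions for each held-out fold come
from a model tuned only on the complement.  Trained weight sets are
portable units: they carry effect/other alleles and training effect-allele
frequencies so a test cohort can be harmonized (allele flips applied,
strand-ambiguous SNPs dropped, missing SNPs mean-imputed from the training
frequency).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.model_selection import KFold

from popgex.cis_eqtl import CovariateSet, _residualize
from popgex.pi1 import Pi1Estimate, estimate_pi0
from popgex.synth_data import ExpressionPanel, GeneAnnotation, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "PredictionModel",
    "CvPerformance",
    "TransferEvaluation",
    "fit_elastic_net_cv",
    "nested_cv_performance",
    "train_gene_models",
    "harmonize_and_predict",
    "evaluate_transfer",
    "compare_alpha_performance",
    "elastic_net_objective",
    "write_model_weights_tsv",
]

_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_N_LAMBDA = 100
_LAMBDA_RATIO = 1e-3


@dataclass
class PredictionModel:
    """Portable per-gene SNP weight set (PredictDB-style)."""

    gene_id: str
    training_population: str
    alpha: float
    intercept: float
    weights: pd.DataFrame  # snp_id, chrom, pos, effect_allele, other_allele, beta
    training_effect_allele_freq: dict  # snp_id -> freq
    lambda_selected: float

    def __post_init__(self) -> None:
        if len(self.weights) and (self.weights["beta"] == 0).any():
            raise ValueError(f"{self.gene_id}: zero-beta weight entries")
        if len(self.weights) and (
            self.weights["effect_allele"] == self.weights["other_allele"]
        ).any():
            raise ValueError(f"{self.gene_id}: effect allele equals other allele")


@dataclass
class CvPerformance:
    gene_id: str
    alpha: float
    outer_folds: int
    r2: float
    n_snps_in_model: int


@dataclass
class TransferEvaluation:
    training_population: str
    test_cohort: str
    gene_correlations: pd.DataFrame  # gene_id, pearson_r, p_value, training_r2
    pi1_by_threshold: dict  # threshold -> Pi1Estimate or None


def _standardize(X: np.ndarray):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Z = np.zeros_like(X)
    Z[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Z, mu, sd, keep


def _lambda_path(Z: np.ndarray, y: np.ndarray, alpha: float) -> np.ndarray:
    n = len(y)
    yc = y - y.mean()
    lam_max = np.abs(Z.T @ yc).max() / (n * alpha)
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max, lam_max * _LAMBDA_RATIO, _N_LAMBDA)


def elastic_net_objective(
    y: np.ndarray, X: np.ndarray, intercept: float, w: np.ndarray,
    lam: float, alpha: float,
) -> float:
    """(1/2n)||y - b0 - Xw||^2 + lam*(alpha||w||_1 + (1-alpha)/2||w||_2^2)."""
    n = len(y)
    resid = y - intercept - X @ w
    return float(
        (resid @ resid) / (2 * n)
        + lam * (alpha * np.abs(w).sum() + 0.5 * (1 - alpha) * (w @ w))
    )


def fit_elastic_net_cv(
    y,
    X,
    alpha: float,
    inner_folds: int = 10,
    seed: int | None = None,
    lambda_override: float | None = None,
):
    """Fit one elastic-net model; returns (intercept, weights, lambda).

    Columns of X are standardized internally; returned weights are on the
    original dosage scale.  Unless ``lambda_override`` is given, lambda is
    selected at the minimum mean inner-CV squared prediction error over the
    shared geometric path.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not (0.0 < alpha <= 1.0):
        raise ValueError(
            f"alpha must be in (0, 1]; ridge (alpha=0) has an unbounded "
            f"lambda path - use a small positive alpha instead (got {alpha})"
        )
    if np.var(y) == 0:
        raise ValueError("zero-variance phenotype")
    if lambda_override is None and n < inner_folds:
        raise ValueError(f"n={n} < inner_folds={inner_folds}")
    Z, mu, sd, keep = _standardize(X)
    Zk = Z[:, keep]
    if Zk.shape[1] == 0:
        return float(y.mean()), np.zeros(p), float("nan")

    if lambda_override is not None:
        lam = float(lambda_override)
    else:
        path = _lambda_path(Zk, y, alpha)
        cv = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
        sse = np.zeros(len(path))
        for train, test in cv.split(Zk):
            Zt = Zk[train]
            mu_t = Zt.mean(axis=0)
            y_t = y[train]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = enet_path(
                    np.asfortranarray(Zt - mu_t),
                    np.ascontiguousarray(y_t - y_t.mean()),
                    l1_ratio=alpha,
                    alphas=path,
                    tol=1e-4,
                    max_iter=3000,
                    check_input=False,
                )
            preds = (Zk[test] - mu_t) @ coefs + y_t.mean()
            sse += ((y[test][:, None] - preds) ** 2).sum(axis=0)
        lam = float(path[int(np.argmin(sse))])

    enet = ElasticNet(
        alpha=lam, l1_ratio=alpha, fit_intercept=True, max_iter=10000, tol=1e-9
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        enet.fit(Zk, y)
    w = np.zeros(p)
    w[keep] = enet.coef_ / sd[keep]
    intercept = float(y.mean() - w @ mu)
    return intercept, w, lam


def nested_cv_performance(
    y,
    X,
    alpha: float,
    outer_folds: int = 5,
    inner_folds: int = 10,
    seed: int | None = None,
    gene_id: str = "",
) -> CvPerformance:
    """Mean held-out R^2 over disjoint outer folds (inner CV per fold).

    R^2 uses the held-out observations' own mean; it can be negative.
    Folds whose held-out expression has zero variance are excluded with a
    logged notice.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    if outer_folds < 2:
        raise ValueError("outer_folds must be >= 2")
    if n < 2 * outer_folds:
        raise ValueError(f"n={n} too small for {outer_folds} outer folds")
    cv = KFold(n_splits=outer_folds, shuffle=True, random_state=seed)
    r2s = []
    n_snps = 0
    for k, (train, test) in enumerate(cv.split(X)):
        yo = y[test]
        ss_tot = float(((yo - yo.mean()) ** 2).sum())
        if ss_tot == 0:
            logger.info("%s: outer fold %d has zero-variance holdout", gene_id, k)
            continue
        b0, w, _ = fit_elastic_net_cv(
            y[train], X[train], alpha, inner_folds=inner_folds, seed=seed
        )
        yp = b0 + X[test] @ w
        ss_res = float(((yo - yp) ** 2).sum())
        r2s.append(1.0 - ss_res / ss_tot)
        n_snps = max(n_snps, int((w != 0).sum()))
    if not r2s:
        raise ValueError("no outer fold with nonzero holdout variance")
    return CvPerformance(
        gene_id=gene_id,
        alpha=alpha,
        outer_folds=outer_folds,
        r2=float(np.mean(r2s)),
        n_snps_in_model=n_snps,
    )


def train_gene_models(
    expression: ExpressionPanel,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | None = None,
    alpha_grid=(0.05, 0.5, 1.0),
    window_bp: int = 1_000_000,
    maf_min: float = 0.01,
    seed: int | None = None,
    outer_folds: int = 5,
    inner_folds: int = 10,
    training_population: str = "",
):
    """Train per-gene elastic-net models across the alpha grid.

    Expression is residualized on the covariates (hidden factors + PCs)
    before fitting; covariates are never penalized regressors.  Per gene
    and alpha, the nested-CV R^2 is recorded and a final model is refit on
    all samples; its nonzero weights populate the PredictionModel.

    Returns (models, performance): ``models`` maps (gene_id, alpha) to
    PredictionModel; ``performance`` is a DataFrame with one row per gene
    and alpha.
    """
    if list(expression.samples) != list(genotypes.samples):
        raise ValueError("expression and genotype sample orders differ")
    C = covariates.matrix() if covariates is not None else None
    Y = _residualize(expression.values.copy(), C)
    maf = genotypes.maf()
    positions = np.array([s.position for s in genotypes.snps])
    chroms = np.array([s.chromosome for s in genotypes.snps])
    freqs = genotypes.alt_freq()
    rng = np.random.default_rng(seed)

    models = {}
    perf_rows = []
    for j, gene in enumerate(expression.genes):
        in_cis = (
            (chroms == gene.chromosome)
            & (np.abs(positions - gene.tss) <= window_bp)
            & (maf > maf_min)
        )
        idx = np.flatnonzero(in_cis)
        if idx.size == 0:
            logger.info("gene %s: no cis SNPs, skipped", gene.gene_id)
            continue
        Xg = genotypes.dosages[:, idx]
        y = Y[:, j]
        gene_seed = int(rng.integers(2**31))
        for alpha in alpha_grid:
            perf = nested_cv_performance(
                y, Xg, alpha, outer_folds=outer_folds,
                inner_folds=inner_folds, seed=gene_seed, gene_id=gene.gene_id,
            )
            b0, w, lam = fit_elastic_net_cv(
                y, Xg, alpha, inner_folds=inner_folds, seed=gene_seed
            )
            nz = np.flatnonzero(w)
            weights = pd.DataFrame(
                {
                    "snp_id": [genotypes.snps[idx[i]].snp_id for i in nz],
                    "chrom": [genotypes.snps[idx[i]].chromosome for i in nz],
                    "pos": [genotypes.snps[idx[i]].position for i in nz],
                    "effect_allele": [
                        genotypes.snps[idx[i]].alt_allele for i in nz
                    ],
                    "other_allele": [
                        genotypes.snps[idx[i]].ref_allele for i in nz
                    ],
                    "beta": w[nz],
                }
            )
            models[(gene.gene_id, alpha)] = PredictionModel(
                gene_id=gene.gene_id,
                training_population=training_population,
                alpha=alpha,
                intercept=b0,
                weights=weights,
                training_effect_allele_freq={
                    genotypes.snps[idx[i]].snp_id: float(freqs[idx[i]])
                    for i in nz
                },
                lambda_selected=lam,
            )
            perf_rows.append(
                {
                    "gene_id": gene.gene_id,
                    "alpha": alpha,
                    "r2": perf.r2,
                    "n_snps_in_model": len(nz),
                    "lambda": lam,
                }
            )
    return models, pd.DataFrame(perf_rows)


def harmonize_and_predict(
    models: dict,
    test_genotypes: GenotypeMatrix,
    missing_policy: str = "freq_impute",
) -> tuple[ExpressionPanel, list]:
    """Predict expression in a test cohort after allele harmonization.

    Test SNPs are matched by chrom:pos.  Exact allele matches use the
    dosage as-is; swapped ref/alt use 2 - dosage; strand-ambiguous (A/T,
    C/G) test SNPs are excluded.  Unmatched model SNPs follow
    ``missing_policy``: "freq_impute" substitutes 2 x the training
    effect-allele frequency, "drop" omits the SNP (and the gene, if no SNP
    maps, which is then listed in the returned omissions).
    """
    if missing_policy not in ("freq_impute", "drop"):
        raise ValueError(f"unknown missing_policy: {missing_policy}")
    by_pos = {}
    for j, s in enumerate(test_genotypes.snps):
        by_pos[(s.chromosome, s.position)] = (j, s)
    n = test_genotypes.n_samples
    gene_models = {}
    for (gene_id, alpha), model in models.items():
        gene_models.setdefault(gene_id, model)
    if len({a for (_, a) in models}) > 1:
        logger.warning(
            "multiple alpha values in model set; using first model per gene"
        )
    preds = []
    genes = []
    omitted = []
    for gene_id, model in gene_models.items():
        pred = np.full(n, model.intercept, dtype=float)
        n_used = 0
        for _, row in model.weights.iterrows():
            hit = by_pos.get((row["chrom"], row["pos"]))
            dose = None
            if hit is not None:
                j, s = hit
                pair = (s.ref_allele, s.alt_allele)
                if pair in _AMBIGUOUS_PAIRS:
                    hit = None
                elif (
                    s.alt_allele == row["effect_allele"]
                    and s.ref_allele == row["other_allele"]
                ):
                    dose = test_genotypes.dosages[:, j]
                elif (
                    s.ref_allele == row["effect_allele"]
                    and s.alt_allele == row["other_allele"]
                ):
                    dose = 2.0 - test_genotypes.dosages[:, j]
            if dose is None:
                if missing_policy == "freq_impute":
                    f = model.training_effect_allele_freq.get(row["snp_id"], 0.0)
                    dose = np.full(n, 2.0 * f)
                else:
                    continue
            pred = pred + row["beta"] * dose
            n_used += 1
        if len(model.weights) and n_used == 0 and missing_policy == "drop":
            omitted.append(gene_id)
            continue
        preds.append(pred)
        genes.append(GeneAnnotation(gene_id, "NA", 1))
    values = (
        np.column_stack(preds) if preds else np.zeros((n, 0))
    )
    panel = ExpressionPanel(
        samples=list(test_genotypes.samples), genes=genes, values=values
    )
    return panel, omitted


def evaluate_transfer(
    predicted: ExpressionPanel,
    observed: ExpressionPanel,
    training_performance: pd.DataFrame,
    r2_thresholds=(0.0, 0.01, 0.05, 0.1, 0.2),
    training_population: str = "",
    test_cohort: str = "",
) -> TransferEvaluation:
    """Per-gene Pearson r of predicted vs observed expression and pi1 at
    each training-R^2 inclusion threshold."""
    if list(predicted.samples) != list(observed.samples):
        raise ValueError("predicted and observed sample orders differ")
    shared = [g for g in predicted.gene_ids if g in set(observed.gene_ids)]
    if not shared:
        raise ValueError("no shared genes between predicted and observed")
    train_r2 = training_performance.set_index("gene_id")["r2"]
    rows = []
    for gene_id in shared:
        yp = predicted.gene_vector(gene_id)
        yo = observed.gene_vector(gene_id)
        if np.ptp(yp) == 0 or np.ptp(yo) == 0:
            r, p = np.nan, np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                r, p = stats.pearsonr(yp, yo)
            if not (np.isfinite(r) and np.isfinite(p)):
                r, p = np.nan, np.nan
        rows.append(
            {
                "gene_id": gene_id,
                "pearson_r": r,
                "p_value": p,
                "training_r2": float(train_r2.get(gene_id, np.nan)),
            }
        )
    corr = pd.DataFrame(rows)
    pi1_by_threshold = {}
    for t in r2_thresholds:
        sub = corr[(corr["training_r2"] >= t) & corr["p_value"].notna()]
        if len(sub) < 10:
            logger.warning(
                "threshold %.2f: only %d genes, pi1 not estimated", t, len(sub)
            )
            pi1_by_threshold[t] = None
            continue
        pi1_by_threshold[t] = estimate_pi0(sub["p_value"].to_numpy())
    return TransferEvaluation(
        training_population=training_population,
        test_cohort=test_cohort,
        gene_correlations=corr,
        pi1_by_threshold=pi1_by_threshold,
    )


def compare_alpha_performance(perf_by_alpha: dict) -> pd.DataFrame:
    """Proportion of genes where the lasso (alpha = 1) outperforms each
    alternative alpha, over the shared gene universe.

    ``perf_by_alpha`` maps alpha to a DataFrame with gene_id and r2.
    Returns one row per non-lasso alpha with the count, proportion, and
    mean/median per-gene R^2 difference (lasso minus alternative).
    """
    if 1.0 not in perf_by_alpha:
        raise ValueError("comparison requires the lasso (alpha = 1.0) results")
    lasso = perf_by_alpha[1.0].set_index("gene_id")["r2"]
    rows = []
    for alpha, df in sorted(perf_by_alpha.items()):
        if alpha == 1.0:
            continue
        other = df.set_index("gene_id")["r2"]
        shared = lasso.index.intersection(other.index)
        if len(shared) == 0:
            raise ValueError(f"no shared genes between alpha=1 and alpha={alpha}")
        diff = lasso.loc[shared] - other.loc[shared]
        rows.append(
            {
                "alpha": alpha,
                "n_genes": len(shared),
                "n_lasso_better": int((diff > 0).sum()),
                "proportion_lasso_better": float((diff > 0).mean()),
                "mean_r2_difference": float(diff.mean()),
                "median_r2_difference": float(diff.median()),
            }
        )
    return pd.DataFrame(rows)


def write_model_weights_tsv(models: dict, path, extra_path=None) -> None:
    """Weights table (gene, snp, alleles, beta, training freq) plus an
    optional per-model extra table (gene, alpha, lambda, n_snps)."""
    rows = []
    extra = []
    for (gene_id, alpha), model in models.items():
        for _, w in model.weights.iterrows():
            rows.append(
                {
                    "gene_id": gene_id,
                    "alpha": alpha,
                    "snp_id": w["snp_id"],
                    "chrom": w["chrom"],
                    "pos": w["pos"],
                    "effect_allele": w["effect_allele"],
                    "other_allele": w["other_allele"],
                    "beta": w["beta"],
                    "training_freq": model.training_effect_allele_freq[w["snp_id"]],
                }
            )
        extra.append(
            {
                "gene_id": gene_id,
                "alpha": alpha,
                "lambda": model.lambda_selected,
                "n_snps": len(model.weights),
                "intercept": model.intercept,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    if extra_path is not None:
        pd.DataFrame(extra).to_csv(extra_path, sep="\t", index=False)
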