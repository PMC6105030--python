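"""cis-eQTL mapping with covariate adjustment and BH FDR.

Each gene is tested against every SNP within a fixed window of its
transcription start site (default +/- 1 Mb, closed interval) by ordinary
least squares of expression on alt-allele dosage plus covariates
(genotype principal components and hidden expression factors).  P-values
are adjusted by the Benjamini-Hochberg step-up procedure, by default over
all SNP-gene tests in the run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from popgex.synth_data import ExpressionPanel, GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CovariateSet",
    "EqtlSummary",
    "ld_prune",
    "genotype_pcs",
    "hidden_expression_factors",
    "map_cis_eqtls",
    "bh_fdr",
    "summarize_eqtls",
]


@dataclass
class CovariateSet:
    """Named covariate vectors aligned to a cohort's sample order."""

    samples: list
    columns: pd.DataFrame  # index-free; one column per covariate

    def __post_init__(self) -> None:
        if len(self.columns) != len(self.samples):
            raise ValueError(
                f"covariate rows ({len(self.columns)}) do not match samples "
                f"({len(self.samples)})"
            )
        for name in self.columns.columns:
            v = self.columns[name].to_numpy()
            if len(v) > 1 and np.ptp(v) == 0:
                raise ValueError(f"constant covariate column: {name}")

    @property
    def n_covariates(self) -> int:
        return self.columns.shape[1]

    def matrix(self) -> np.ndarray:
        return self.columns.to_numpy(dtype=float)

    @staticmethod
    def empty(samples) -> "CovariateSet":
        return CovariateSet(samples=list(samples), columns=pd.DataFrame(index=range(len(samples))))

    def concat(self, other: "CovariateSet") -> "CovariateSet":
        if list(self.samples) != list(other.samples):
            raise ValueError("covariate sets have different sample orders")
        cols = pd.concat(
            [self.columns.reset_index(drop=True), other.columns.reset_index(drop=True)],
            axis=1,
        )
        return CovariateSet(samples=list(self.samples), columns=cols)


@dataclass
class EqtlSummary:
    population: str
    n_esnps: int
    n_egenes: int
    fdr_threshold: float


def ld_prune(
    genotypes: GenotypeMatrix, window: int = 50, r2_threshold: float = 0.3
) -> list:
    """Greedy LD pruning: scan SNPs in position order; a SNP is dropped
    when its squared dosage correlation with any previously kept SNP within
    the trailing ``window`` SNPs exceeds ``r2_threshold``.

    Monomorphic SNPs have undefined correlation; they are skipped from r^2
    computation and always kept.  Returns the kept SNP id list.
    """
    if window < 2:
        raise ValueError(f"window must be >= 2, got {window}")
    X = genotypes.dosages
    sd = X.std(axis=0)
    mono = sd == 0
    Z = np.zeros_like(X)
    nz = ~mono
    Z[:, nz] = (X[:, nz] - X[:, nz].mean(axis=0)) / sd[nz]
    n = X.shape[0]
    kept: list[int] = []
    for j in range(X.shape[1]):
        if mono[j]:
            kept.append(j)
            continue
        drop = False
        for i in reversed(kept):
            if j - i >= window:
                break
            if mono[i]:
                continue
            r = float(Z[:, i] @ Z[:, j]) / n
            if r * r > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
    ids = genotypes.snp_ids
    return [ids[j] for j in kept]


def genotype_pcs(genotypes: GenotypeMatrix, n_pcs: int) -> CovariateSet:
    """Principal components of column-standardized dosages.

    PCs are the eigenvectors of the sample-sample covariance, ordered by
    decreasing eigenvalue, each unit-norm.  Monomorphic SNPs are excluded
    from standardization.  Input should be LD-pruned.
    """
    if n_pcs == 0:
        return CovariateSet.empty(genotypes.samples)
    X = genotypes.dosages
    sd = X.std(axis=0)
    keep = sd > 0
    if n_pcs >= min(X.shape[0], int(keep.sum())):
        raise ValueError(
            f"n_pcs={n_pcs} too large for {X.shape[0]} samples x "
            f"{int(keep.sum())} polymorphic SNPs"
        )
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, _ = np.linalg.svd(Z, full_matrices=False)
    cols = pd.DataFrame(
        {f"PC{k + 1}": U[:, k] for k in range(n_pcs)}
    )
    return CovariateSet(samples=list(genotypes.samples), columns=cols)


def _residualize(Y: np.ndarray, C: np.ndarray | None) -> np.ndarray:
    """Residualize columns of Y on [intercept, C] by least squares."""
    n = Y.shape[0]
    design = np.ones((n, 1))
    if C is not None and C.shape[1] > 0:
        design = np.hstack([design, C])
    coef, *_ = np.linalg.lstsq(design, Y, rcond=None)
    return Y - design @ coef


def hidden_expression_factors(
    expression: ExpressionPanel,
    n_factors: int,
    protect: CovariateSet | None = None,
) -> CovariateSet:
    """Hidden expression confounders as principal components of the
    expression matrix after residualizing on protected covariates.

    This is a variance-capturing stand-in for latent-factor methods (PEER):
    batch shifts and other broad confounders load on the top components.
    """
    n = len(expression.samples)
    if n_factors >= n:
        raise ValueError(f"n_factors={n_factors} must be < n_samples={n}")
    if n_factors == 0:
        return CovariateSet.empty(expression.samples)
    C = protect.matrix() if protect is not None else None
    R = _residualize(expression.values.copy(), C)
    R = R - R.mean(axis=0)
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    cols = pd.DataFrame({f"factor{k + 1}": U[:, k] for k in range(n_factors)})
    return CovariateSet(samples=list(expression.samples), columns=cols)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (monotone, ties shared)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def map_cis_eqtls(
    expression: ExpressionPanel,
    genotypes: GenotypeMatrix,
    covariates: CovariateSet | None = None,
    window_bp: int = 1_000_000,
    maf_min: float = 0.01,
    fdr_scope: str = "global",
) -> pd.DataFrame:
    """Test every gene against cis-window SNPs by OLS with covariates.

    Expression and dosages are residualized on [intercept, covariates]
    (Frisch-Waugh), then per-SNP slope, SE and two-sided t p-value are
    computed with residual degrees of freedom n - 2 - n_covariates.  SNPs
    with within-cohort MAF <= ``maf_min`` or monomorphic are excluded.
    FDR is BH over all tests (``fdr_scope='global'``) or within each gene
    (``'per_gene'``).

    Returns a DataFrame with columns gene_id, snp_id, chrom, pos, ref, alt,
    beta, se, t_stat, p_value, fdr.
    """
    if list(expression.samples) != list(genotypes.samples):
        raise ValueError("expression and genotype sample orders differ")
    if fdr_scope not in ("global", "per_gene"):
        raise ValueError(f"unknown fdr_scope: {fdr_scope}")
    n = len(expression.samples)
    C = covariates.matrix() if covariates is not None else None
    k = 0 if C is None else C.shape[1]
    if C is not None and C.shape[1] > 0:
        if np.linalg.matrix_rank(np.hstack([np.ones((n, 1)), C])) < C.shape[1] + 1:
            raise ValueError("rank-deficient covariate matrix")
    df_resid = n - 2 - k
    if df_resid < 1:
        raise ValueError("not enough samples for the covariate model")

    maf = genotypes.maf()
    positions = np.array([s.position for s in genotypes.snps])
    chroms = np.array([s.chromosome for s in genotypes.snps])
    Y = _residualize(expression.values.copy(), C)
    G = _residualize(genotypes.dosages.copy(), C)
    gss = (G * G).sum(axis=0)

    frames = []
    for j, gene in enumerate(expression.genes):
        in_cis = (
            (chroms == gene.chromosome)
            & (np.abs(positions - gene.tss) <= window_bp)
            & (maf > maf_min)
        )
        idx = np.flatnonzero(in_cis)
        if idx.size == 0:
            logger.info("gene %s: no testable cis SNPs, skipped", gene.gene_id)
            continue
        y = Y[:, j]
        gty = G[:, idx].T @ y
        denom = gss[idx]
        beta = gty / denom
        yss = float(y @ y)
        rss = yss - beta * gty
        rss = np.maximum(rss, 0.0)
        sigma2 = rss / df_resid
        se = np.sqrt(sigma2 / denom)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(se > 0, beta / se, np.inf * np.sign(beta))
        p = 2.0 * stats.t.sf(np.abs(t), df_resid)
        p = np.clip(p, np.finfo(float).tiny, 1.0)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": gene.gene_id,
                    "snp_id": [genotypes.snps[i].snp_id for i in idx],
                    "chrom": chroms[idx],
                    "pos": positions[idx],
                    "ref": [genotypes.snps[i].ref_allele for i in idx],
                    "alt": [genotypes.snps[i].alt_allele for i in idx],
                    "beta": beta,
                    "se": se,
                    "t_stat": t,
                    "p_value": p,
                }
            )
        )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id", "snp_id", "chrom", "pos", "ref", "alt",
                "beta", "se", "t_stat", "p_value", "fdr",
            ]
        )
    out = pd.concat(frames, ignore_index=True)
    if fdr_scope == "global":
        out["fdr"] = bh_fdr(out["p_value"].to_numpy())
    else:
        out["fdr"] = out.groupby("gene_id")["p_value"].transform(
            lambda s: bh_fdr(s.to_numpy())
        )
    return out


def summarize_eqtls(
    associations: pd.DataFrame,
    fdr_threshold: float = 0.05,
    population: str = "",
) -> EqtlSummary:
    """Count distinct eSNPs and eGenes at the FDR threshold."""
    passing = associations[associations["fdr"] < fdr_threshold]
    return EqtlSummary(
        population=population,
        n_esnps=int(passing["snp_id"].nunique()),
        n_egenes=int(passing["gene_id"].nunique()),
        fdr_threshold=fdr_threshold,
    )
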