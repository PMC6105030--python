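"""Weir-Cockerham F_ST and the divergent-vs-similar prediction test.

Per-SNP differentiation between two populations is measured by the
Weir & Cockerham (1984) estimator theta = a / (a + b + c), computed from
allele frequencies, sample sizes and observed heterozygosity.  Per-gene
prediction models are summarized by the mean F_ST of their SNPs and by a
beta-weighted mean (each SNP's F_ST multiplied by its elastic-net effect
size before averaging).  Genes are split into "divergent" and "similar"
groups by the absolute between-population difference in predictive R^2 at
a grid of thresholds, and the F_ST summaries of the two groups are
compared by two-sided Wilcoxon rank-sum tests.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from popgex.synth_data import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "FstRecord",
    "DivergenceTestResult",
    "weir_cockerham_fst",
    "weir_cockerham_fst_table",
    "global_fst",
    "hudson_fst_table",
    "model_fst_summary",
    "divergence_wilcoxon",
]


@dataclass
class FstRecord:
    snp_id: str
    fst: float  # may be slightly negative; NaN when undefined
    n1: int
    n2: int
    p1: float
    p2: float

    def __post_init__(self) -> None:
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("sample sizes must be >= 1")
        if np.isfinite(self.fst) and self.fst > 1.0 + 1e-12:
            raise ValueError(f"{self.snp_id}: F_ST > 1")


def _het_freq(dosages: np.ndarray) -> np.ndarray:
    """Observed heterozygote frequency per SNP; fractional dosages in
    (0.5, 1.5) are counted as heterozygous (integer-dosage assumption)."""
    return ((dosages > 0.5) & (dosages < 1.5)).mean(axis=0)


def _wc_components(n1, n2, p1, p2, h1, h2):
    """Weir & Cockerham (1984) a, b, c variance components, two demes."""
    r = 2.0
    nbar = (n1 + n2) / r
    nc = (r * nbar - (n1**2 + n2**2) / (r * nbar)) / (r - 1.0)
    pbar = (n1 * p1 + n2 * p2) / (r * nbar)
    s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1.0) * nbar)
    hbar = (n1 * h1 + n2 * h2) / (r * nbar)
    a = (nbar / nc) * (
        s2
        - (1.0 / (nbar - 1.0))
        * (pbar * (1.0 - pbar) - s2 * (r - 1.0) / r - hbar / 4.0)
    )
    b = (nbar / (nbar - 1.0)) * (
        pbar * (1.0 - pbar)
        - s2 * (r - 1.0) / r
        - hbar * (2.0 * nbar - 1.0) / (4.0 * nbar)
    )
    c = hbar / 2.0
    return a, b, c


def weir_cockerham_fst_table(
    genotypes_pop1: GenotypeMatrix, genotypes_pop2: GenotypeMatrix
) -> pd.DataFrame:
    """Per-SNP Weir-Cockerham theta over the SNPs shared by both cohorts.

    SNPs monomorphic in the pooled sample have undefined F_ST and are
    returned with NaN and flagged in the 'defined' column.
    """
    shared = [s for s in genotypes_pop1.snp_ids if s in set(genotypes_pop2.snp_ids)]
    if not shared:
        raise ValueError("no shared SNPs between populations")
    g1 = genotypes_pop1.subset_snps(shared)
    g2 = genotypes_pop2.subset_snps(shared)
    n1, n2 = g1.n_samples, g2.n_samples
    p1 = g1.alt_freq()
    p2 = g2.alt_freq()
    h1 = _het_freq(g1.dosages)
    h2 = _het_freq(g2.dosages)
    a, b, c = _wc_components(n1, n2, p1, p2, h1, h2)
    denom = a + b + c
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(denom != 0, a / denom, np.nan)
    pooled_p = (n1 * p1 + n2 * p2) / (n1 + n2)
    defined = (pooled_p > 0) & (pooled_p < 1) & (denom != 0)
    fst = np.where(defined, fst, np.nan)
    return pd.DataFrame(
        {
            "snp_id": shared,
            "chrom": [s.chromosome for s in g1.snps],
            "pos": [s.position for s in g1.snps],
            "fst": fst,
            "a": a,
            "denom": denom,
            "n1": n1,
            "n2": n2,
            "p1": p1,
            "p2": p2,
            "defined": defined,
        }
    )


def global_fst(fst_table: pd.DataFrame) -> float:
    """Multi-locus Weir-Cockerham theta: sum(a) / sum(a + b + c) over
    defined SNPs.

    This ratio-of-sums form (PLINK's "weighted" genome-wide F_ST) is the
    estimator whose expectation matches the generative divergence; the
    per-SNP mean of ratios is biased downward because each SNP's noisy
    between-population component also appears in its own denominator.
    """
    ok = fst_table["defined"].to_numpy()
    if not ok.any():
        raise ValueError("no SNP with defined F_ST")
    return float(fst_table.loc[ok, "a"].sum() / fst_table.loc[ok, "denom"].sum())


def weir_cockerham_fst(
    genotypes_pop1: GenotypeMatrix,
    genotypes_pop2: GenotypeMatrix,
    snp_id: str,
) -> FstRecord:
    """Weir-Cockerham theta for a single SNP."""
    for g, name in ((genotypes_pop1, "pop1"), (genotypes_pop2, "pop2")):
        if snp_id not in set(g.snp_ids):
            raise KeyError(f"SNP {snp_id} absent from {name}")
    table = weir_cockerham_fst_table(
        genotypes_pop1.subset_snps([snp_id]), genotypes_pop2.subset_snps([snp_id])
    )
    row = table.iloc[0]
    if not row["defined"]:
        logger.warning("SNP %s monomorphic in the pooled sample", snp_id)
    return FstRecord(
        snp_id=snp_id,
        fst=float(row["fst"]),
        n1=int(row["n1"]),
        n2=int(row["n2"]),
        p1=float(row["p1"]),
        p2=float(row["p2"]),
    )


def hudson_fst_table(
    genotypes_pop1: GenotypeMatrix, genotypes_pop2: GenotypeMatrix
) -> pd.DataFrame:
    """Hudson estimator (sensitivity alternative): 1 - Hw/Hb with
    sample-size-corrected within-population heterozygosity."""
    shared = [s for s in genotypes_pop1.snp_ids if s in set(genotypes_pop2.snp_ids)]
    g1 = genotypes_pop1.subset_snps(shared)
    g2 = genotypes_pop2.subset_snps(shared)
    n1, n2 = 2 * g1.n_samples, 2 * g2.n_samples
    p1, p2 = g1.alt_freq(), g2.alt_freq()
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fst = np.where(den > 0, num / den, np.nan)
    return pd.DataFrame(
        {"snp_id": shared, "fst": fst, "p1": p1, "p2": p2}
    )


def model_fst_summary(
    model, fst_records: pd.DataFrame, weight_abs: bool = False
) -> tuple[float, float]:
    """(mean F_ST, beta-weighted F_ST) over a prediction model's SNPs.

    weighted = mean over SNPs of beta * F_ST (the signed product by
    default; ``weight_abs=True`` uses mean(|beta| * F_ST) instead, since
    signed products can cancel).  SNPs with undefined F_ST are excluded
    with a notice.
    """
    if len(model.weights) == 0:
        raise ValueError(f"{model.gene_id}: empty model")
    fst = fst_records.set_index("snp_id")["fst"]
    vals = []
    betas = []
    for _, row in model.weights.iterrows():
        f = fst.get(row["snp_id"], np.nan)
        if not np.isfinite(f):
            logger.info(
                "%s: SNP %s has undefined F_ST, excluded",
                model.gene_id, row["snp_id"],
            )
            continue
        vals.append(float(f))
        betas.append(float(row["beta"]))
    if not vals:
        raise ValueError(f"{model.gene_id}: no model SNP with defined F_ST")
    vals = np.array(vals)
    betas = np.array(betas)
    w = np.abs(betas) if weight_abs else betas
    return float(vals.mean()), float((w * vals).mean())


def divergence_wilcoxon(
    r2_pop1: pd.Series,
    r2_pop2: pd.Series,
    summaries: pd.Series,
    threshold_grid=(0.05, 0.1, 0.15, 0.2, 0.25, 0.3),
    weighted: bool = False,
) -> pd.DataFrame:
    """Wilcoxon rank-sum comparison of model F_ST summaries between genes
    with divergent (|R2_1 - R2_2| > t) and similar predictive performance.

    Exact enumeration is used when both groups have <= 20 genes, otherwise
    the normal approximation with continuity correction.  An empty group
    yields a row with missing statistic and a warning.
    """
    if len(list(threshold_grid)) == 0:
        raise ValueError("empty threshold grid")
    shared = r2_pop1.index.intersection(r2_pop2.index).intersection(summaries.index)
    if len(shared) == 0:
        raise ValueError("no shared genes across inputs")
    gap = (r2_pop1.loc[shared] - r2_pop2.loc[shared]).abs()
    f = summaries.loc[shared]
    rows = []
    for t in threshold_grid:
        div = f[gap > t].dropna()
        sim = f[gap <= t].dropna()
        row = {
            "threshold": t,
            "n_divergent": len(div),
            "n_similar": len(sim),
            "mean_fst_divergent": float(div.mean()) if len(div) else np.nan,
            "mean_fst_similar": float(sim.mean()) if len(sim) else np.nan,
            "statistic": np.nan,
            "p_value": np.nan,
            "weighted": weighted,
        }
        if len(div) == 0 or len(sim) == 0:
            logger.warning("threshold %.2f: empty group, test skipped", t)
        else:
            method = "exact" if max(len(div), len(sim)) <= 20 else "asymptotic"
            res = stats.mannwhitneyu(
                div.to_numpy(), sim.to_numpy(),
                alternative="two-sided", method=method,
            )
            row["statistic"] = float(res.statistic)
            row["p_value"] = float(res.pvalue)
        rows.append(row)
    return pd.DataFrame(rows)
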