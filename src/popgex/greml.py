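"""cis-window GRMs and restricted maximum likelihood variance components.

For each gene, a genetic relationship matrix (GRM) is built from the
column-standardized dosages of its cis-window SNPs, K = W W'/m.  A
univariate average-information (AI) REML fit of

    y = X b + g + e,   var(y) = K sigma_g^2 + I sigma_e^2

yields the cis heritability h^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2).

The bivariate model stacks two disjoint populations.  With A and B the
within-population GRMs and C the cross-population block of the GRM built
on the combined sample, the phenotypic covariance is

    V = [ A sg1^2 + I se1^2      C sg12   ]
        [ C' sg12            B sg2^2 + I se2^2 ]

(no residual covariance: no individual belongs to both populations).  The
genetic correlation is rG = sg12 / sqrt(sg1^2 * sg2^2), constrained to
[-1, 1] by bending: when the 2x2 genetic (co)variance matrix loses
positive definiteness its eigenvalues are floored at a small positive
value, and the event is recorded.

AI-REML iterates a quasi-Newton update using the average-information
matrix, with step halving and an expectation-maximization fallback so the
restricted log-likelihood never decreases across accepted iterations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg.lapack import dpotrf, dpotri

from popgex.cis_eqtl import CovariateSet
from popgex.synth_data import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "Grm",
    "H2Estimate",
    "RgEstimate",
    "build_cis_grm",
    "cross_population_grm",
    "bivariate_grms",
    "reml_univariate_h2",
    "reml_bivariate_rg",
    "aggregate_rg",
    "write_grm_tsv",
    "read_grm_tsv",
]

_VAR_FLOOR_FRAC = 1e-8  # variance floor as a fraction of var(y)
_BEND_EIG_FRAC = 1e-6  # eigenvalue floor for bending, fraction of trace


@dataclass
class Grm:
    samples: list
    matrix: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.samples)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM shape does not match sample count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("GRM contains non-finite entries")
        if self.n_snps_used < 1:
            raise ValueError("GRM built from zero SNPs")


@dataclass
class H2Estimate:
    gene_id: str
    population: str
    sigma_g2: float
    sigma_e2: float
    h2: float
    se: float
    converged: bool
    n_iter: int
    loglik: float = float("nan")


@dataclass
class RgEstimate:
    gene_id: str
    pop_pair: tuple
    sigma_g1_2: float
    sigma_g2_2: float
    sigma_g1g2: float
    rg: float
    se_rg: float
    converged: bool
    bent: bool
    n_iter: int
    reason: str = ""
    h2_1: float = float("nan")
    h2_2: float = float("nan")


def _standardized_dosages(
    dosages: np.ndarray, maf_min: float
) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize, returning (W, kept_mask); monomorphic and
    MAF-filtered SNPs are dropped."""
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    sd = dosages.std(axis=0)
    keep = (sd > 0) & (maf >= maf_min)
    W = (dosages[:, keep] - dosages[:, keep].mean(axis=0)) / sd[keep]
    return W, keep


def build_cis_grm(
    genotypes: GenotypeMatrix,
    snp_subset=None,
    maf_min: float = 0.01,
) -> Grm:
    """K = W W'/m over the retained cis SNPs (within-cohort
    standardization, sample frequencies)."""
    g = genotypes if snp_subset is None else genotypes.subset_snps(snp_subset)
    W, keep = _standardized_dosages(g.dosages, maf_min)
    m = int(keep.sum())
    if m == 0:
        raise ValueError("all SNPs removed by MAF/monomorphism filtering")
    return Grm(samples=list(g.samples), matrix=W @ W.T / m, n_snps_used=m)


def cross_population_grm(
    genotypes1: GenotypeMatrix,
    genotypes2: GenotypeMatrix,
    snp_subset=None,
    maf_min: float = 0.01,
) -> Grm:
    """GRM on the stacked two-population cohort with combined-sample
    standardization; its off-diagonal block is the cross-population C."""
    if snp_subset is None:
        snp_subset = [s for s in genotypes1.snp_ids if s in set(genotypes2.snp_ids)]
    g1 = genotypes1.subset_snps(snp_subset)
    g2 = genotypes2.subset_snps(snp_subset)
    stacked = np.vstack([g1.dosages, g2.dosages])
    W, keep = _standardized_dosages(stacked, maf_min)
    m = int(keep.sum())
    if m == 0:
        raise ValueError("all SNPs removed by MAF/monomorphism filtering")
    return Grm(
        samples=list(g1.samples) + list(g2.samples),
        matrix=W @ W.T / m,
        n_snps_used=m,
    )


def bivariate_grms(
    genotypes1: GenotypeMatrix,
    genotypes2: GenotypeMatrix,
    snp_subset=None,
    maf_min: float = 0.01,
) -> tuple[Grm, Grm, Grm]:
    """(A, B, combined) GRMs over one shared SNP set.

    All three come from the single GRM of the stacked cohort with
    combined-sample standardization: A and B are its diagonal blocks and
    the cross-population C is its off-diagonal block.  Taking all blocks
    from one positive-semidefinite matrix keeps the bivariate covariance V
    positive definite whenever |rG| <= 1; mixing per-population diagonal
    blocks with a combined cross block does not have that guarantee (the
    between-population frequency offsets give the cross block a large
    near-rank-one component).  SNPs must be polymorphic and above the MAF
    floor in each cohort and in the pooled sample.
    """
    if snp_subset is None:
        snp_subset = [s for s in genotypes1.snp_ids if s in set(genotypes2.snp_ids)]
    g1 = genotypes1.subset_snps(snp_subset)
    g2 = genotypes2.subset_snps(snp_subset)

    def _kept(dosages):
        freq = dosages.mean(axis=0) / 2.0
        sd = dosages.std(axis=0)
        return (sd > 0) & (np.minimum(freq, 1 - freq) >= maf_min)

    keep = _kept(g1.dosages) & _kept(g2.dosages) & _kept(
        np.vstack([g1.dosages, g2.dosages])
    )
    ids = [sid for sid, k in zip(g1.snp_ids, keep) if k]
    if not ids:
        raise ValueError("no SNPs shared and polymorphic in both cohorts")
    combined = cross_population_grm(g1, g2, snp_subset=ids, maf_min=0.0)
    n1 = g1.n_samples
    A = Grm(
        samples=list(g1.samples),
        matrix=combined.matrix[:n1, :n1],
        n_snps_used=combined.n_snps_used,
    )
    B = Grm(
        samples=list(g2.samples),
        matrix=combined.matrix[n1:, n1:],
        n_snps_used=combined.n_snps_used,
    )
    return A, B, combined


# ---------------------------------------------------------------------------
# univariate AI-REML (eigen-rotated: O(n) per iteration after one O(n^3))


def _design(n: int, covariates: CovariateSet | None) -> np.ndarray:
    X = np.ones((n, 1))
    if covariates is not None and covariates.n_covariates > 0:
        X = np.hstack([X, covariates.matrix()])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular fixed-effect design matrix")
    return X


def reml_univariate_h2(
    grm: Grm,
    phenotype,
    covariates: CovariateSet | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    gene_id: str = "",
    population: str = "",
) -> H2Estimate:
    """AI-REML fit of the one-GRM mixed model; h^2 with delta-method SE.

    Variance components are constrained nonnegative by projection to a
    small floor; average-information steps are halved until the restricted
    log-likelihood does not decrease, with an EM fallback.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.size
    if n != len(grm.samples):
        raise ValueError("phenotype length does not match GRM")
    vary = float(np.var(y, ddof=1))
    if vary <= 0:
        raise ValueError("phenotype has zero variance")
    X = _design(n, covariates)
    p = X.shape[1]

    lam, U = np.linalg.eigh(grm.matrix)
    yt = U.T @ y
    Xt = U.T @ X

    floor = _VAR_FLOOR_FRAC * vary
    theta = np.array([vary / 2.0, vary / 2.0])  # (sigma_g2, sigma_e2)

    def loglik_parts(th):
        d = th[0] * lam + th[1]
        if np.any(d <= 0):
            return None
        dinv = 1.0 / d
        XtD = Xt * dinv[:, None]
        M = Xt.T @ XtD
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        Minv = np.linalg.inv(M)
        q = dinv * yt - XtD @ (Minv @ (XtD.T @ yt))
        ll = -0.5 * (np.log(d).sum() + logdetM + float(yt @ q))
        return ll, d, dinv, XtD, Minv, q

    parts = loglik_parts(theta)
    if parts is None:  # pragma: no cover - cannot happen with positive start
        raise RuntimeError("non-positive-definite start")
    ll = parts[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, d, dinv, XtD, Minv, q = parts
        u_g = lam * q
        u_e = q

        def P_apply(v):
            return dinv * v - XtD @ (Minv @ (XtD.T @ v))

        # tr(P V_i): diag of P in rotated basis
        diag_corr = np.einsum("ij,jk,ik->i", XtD, Minv, XtD)
        diagP = dinv - diag_corr
        tr_g = float(lam @ diagP)
        tr_e = float(diagP.sum())
        grad = -0.5 * np.array([tr_g - float(q @ u_g), tr_e - float(q @ u_e)])
        Pu_g = P_apply(u_g)
        Pu_e = P_apply(u_e)
        AI = 0.5 * np.array(
            [
                [float(u_g @ Pu_g), float(u_g @ Pu_e)],
                [float(u_e @ Pu_g), float(u_e @ Pu_e)],
            ]
        )
        if it == 1:
            # one EM step for stability
            step = theta**2 * np.array(
                [float(q @ u_g) - tr_g, float(q @ u_e) - tr_e]
            ) / n
        else:
            try:
                step = np.linalg.solve(AI, grad)
            except np.linalg.LinAlgError:
                step = theta**2 * np.array(
                    [float(q @ u_g) - tr_g, float(q @ u_e) - tr_e]
                ) / n
        scale = 1.0
        accepted = False
        for _ in range(8):
            cand = np.maximum(theta + scale * step, floor)
            cand_parts = loglik_parts(cand)
            if cand_parts is not None and cand_parts[0] >= ll - 1e-12:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            # no ascent step representable: constrained stationary point
            converged = True
            break
        new_ll = cand_parts[0]
        theta = cand
        parts = cand_parts
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    sg, se_var = float(theta[0]), float(theta[1])
    total = sg + se_var
    h2 = float(np.clip(sg / total, 0.0, 1.0))
    # delta-method SE from the final AI matrix
    try:
        _, d, dinv, XtD, Minv, q = parts
        u_g = lam * q
        u_e = q

        def P_apply(v):
            return dinv * v - XtD @ (Minv @ (XtD.T @ v))

        AI = 0.5 * np.array(
            [
                [float(u_g @ P_apply(u_g)), float(u_g @ P_apply(u_e))],
                [float(u_e @ P_apply(u_g)), float(u_e @ P_apply(u_e))],
            ]
        )
        cov = np.linalg.inv(AI)
        grad_h = np.array([se_var / total**2, -sg / total**2])
        se_h2 = float(np.sqrt(max(grad_h @ cov @ grad_h, 0.0)))
    except np.linalg.LinAlgError:
        se_h2 = float("nan")
    return H2Estimate(
        gene_id=gene_id,
        population=population,
        sigma_g2=sg,
        sigma_e2=se_var,
        h2=h2,
        se=se_h2,
        converged=converged,
        n_iter=it,
        loglik=ll,
    )


# ---------------------------------------------------------------------------
# bivariate AI-REML


def _chol_inv(V: np.ndarray):
    """(Vinv, logdet) via LAPACK Cholesky; None if not PD."""
    c, info = dpotrf(V, lower=1)
    if info != 0:
        return None
    logdet = 2.0 * float(np.log(np.diag(c)).sum())
    vi, info = dpotri(c, lower=1)
    if info != 0:  # pragma: no cover
        return None
    Vinv = np.tril(vi) + np.tril(vi, -1).T
    return Vinv, logdet


def reml_bivariate_rg(
    grm1: Grm,
    grm2: Grm,
    grm_cross: Grm,
    y1,
    y2,
    covariates1: CovariateSet | None = None,
    covariates2: CovariateSet | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
    gene_id: str = "",
    pop_pair: tuple = ("pop1", "pop2"),
) -> RgEstimate:
    """Bivariate AI-REML genetic correlation between two disjoint cohorts.

    Estimates (sg1^2, sg2^2, sg12, se1^2, se2^2) on the stacked phenotype;
    if a genetic variance collapses to the zero boundary, rG is undefined
    and the estimate is returned non-converged ("degenerate genetic
    variance").  If the 2x2 genetic (co)variance matrix is not positive
    definite the bending step floors its eigenvalues so that |rG| < 1, and
    the ``bent`` flag is set.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n1, n2 = y1.size, y2.size
    if n1 != len(grm1.samples) or n2 != len(grm2.samples):
        raise ValueError("phenotype lengths do not match GRMs")
    if len(grm_cross.samples) != n1 + n2:
        raise ValueError("cross GRM must cover the stacked cohort")
    if set(grm1.samples) & set(grm2.samples):
        raise ValueError("populations must have disjoint sample sets")

    A = grm1.matrix
    B = grm2.matrix
    C = grm_cross.matrix[:n1, n1:]
    y = np.concatenate([y1, y2])
    n = n1 + n2

    X1 = _design(n1, covariates1)
    X2 = _design(n2, covariates2)
    p1, p2 = X1.shape[1], X2.shape[1]
    X = np.zeros((n, p1 + p2))
    X[:n1, :p1] = X1
    X[n1:, p1:] = X2

    v1 = float(np.var(y1, ddof=1))
    v2 = float(np.var(y2, ddof=1))
    if v1 <= 0 or v2 <= 0:
        raise ValueError("phenotype has zero variance")
    floor = _VAR_FLOOR_FRAC * np.array([v1, v2, np.nan, v1, v2])
    # theta = (sg1^2, sg2^2, sg12, se1^2, se2^2)
    theta = np.array([v1 / 2, v2 / 2, 0.0, v1 / 2, v2 / 2])

    def build_V(th):
        V = np.zeros((n, n))
        V[:n1, :n1] = th[0] * A
        V[n1:, n1:] = th[1] * B
        V[:n1, n1:] = th[2] * C
        V[n1:, :n1] = th[2] * C.T
        V[np.diag_indices(n1)] += th[3]
        idx = np.diag_indices(n2)
        V[idx[0] + n1, idx[1] + n1] += th[4]
        return V

    def project(th):
        out = th.copy()
        for i in (0, 1, 3, 4):
            out[i] = max(out[i], floor[i])
        return out

    def evaluate(th):
        res = _chol_inv(build_V(th))
        if res is None:
            return None
        Vinv, logdetV = res
        W = Vinv @ X
        M = X.T @ W
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        Minv = np.linalg.inv(M)
        P = Vinv - W @ Minv @ W.T
        q = P @ y
        ll = -0.5 * (logdetV + logdetM + float(y @ q))
        return ll, P, q

    state = evaluate(theta)
    if state is None:  # pragma: no cover
        raise RuntimeError("non-positive-definite start")
    ll = state[0]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        _, P, q = state
        q1, q2 = q[:n1], q[n1:]
        U = np.zeros((n, 5))
        U[:n1, 0] = A @ q1
        U[n1:, 1] = B @ q2
        U[:n1, 2] = C @ q2
        U[n1:, 2] = C.T @ q1
        U[:n1, 3] = q1
        U[n1:, 4] = q2
        P11 = P[:n1, :n1]
        P22 = P[n1:, n1:]
        P12 = P[:n1, n1:]
        traces = np.array(
            [
                float((P11 * A).sum()),
                float((P22 * B).sum()),
                2.0 * float((P12 * C).sum()),
                float(np.trace(P11)),
                float(np.trace(P22)),
            ]
        )
        quad = U.T @ q  # y'P V_i P y
        grad = -0.5 * (traces - quad)
        PU = P @ U
        AI = 0.5 * (U.T @ PU)

        if it == 1:
            step = np.zeros(5)
            for i in (0, 1, 3, 4):
                step[i] = theta[i] ** 2 * (quad[i] - traces[i]) / n
        else:
            try:
                step = np.linalg.solve(AI, grad)
            except np.linalg.LinAlgError:
                step = np.zeros(5)
                for i in (0, 1, 3, 4):
                    step[i] = theta[i] ** 2 * (quad[i] - traces[i]) / n
        scale = 1.0
        accepted = False
        for _ in range(8):
            cand = project(theta + scale * step)
            cand_state = evaluate(cand)
            if cand_state is not None and cand_state[0] >= ll - 1e-12:
                accepted = True
                break
            scale *= 0.5
        if not accepted:
            # stalled against the positive-definiteness boundary (|rG| -> 1):
            # a constrained maximum; bending below restores |rG| <= 1
            converged = True
            break
        theta = cand
        new_ll = cand_state[0]
        state = cand_state
        if abs(new_ll - ll) < tol:
            ll = new_ll
            converged = True
            break
        ll = new_ll

    sg1, sg2, sc = float(theta[0]), float(theta[1]), float(theta[2])
    h2_1 = sg1 / (sg1 + theta[3])
    h2_2 = sg2 / (sg2 + theta[4])

    at_boundary = sg1 <= floor[0] * 1.001 or sg2 <= floor[1] * 1.001
    if at_boundary:
        return RgEstimate(
            gene_id=gene_id,
            pop_pair=pop_pair,
            sigma_g1_2=sg1,
            sigma_g2_2=sg2,
            sigma_g1g2=sc,
            rg=float("nan"),
            se_rg=float("nan"),
            converged=False,
            bent=False,
            n_iter=it,
            reason="degenerate genetic variance",
            h2_1=h2_1,
            h2_2=h2_2,
        )

    G = np.array([[sg1, sc], [sc, sg2]])
    bent = False
    eigval, eigvec = np.linalg.eigh(G)
    if eigval.min() <= 0:
        bent = True
        floor_eig = _BEND_EIG_FRAC * float(np.trace(G))
        Gb = eigvec @ np.diag(np.maximum(eigval, floor_eig)) @ eigvec.T
        g1b, g2b, scb = Gb[0, 0], Gb[1, 1], Gb[0, 1]
    else:
        g1b, g2b, scb = sg1, sg2, sc
    rg = float(np.clip(scb / np.sqrt(g1b * g2b), -1.0, 1.0))

    # delta-method SE from the AI matrix at the (unbent) estimate
    se_rg = float("nan")
    try:
        _, P, q = state
        q1, q2 = q[:n1], q[n1:]
        U = np.zeros((n, 5))
        U[:n1, 0] = A @ q1
        U[n1:, 1] = B @ q2
        U[:n1, 2] = C @ q2
        U[n1:, 2] = C.T @ q1
        U[:n1, 3] = q1
        U[n1:, 4] = q2
        AI = 0.5 * (U.T @ (P @ U))
        cov = np.linalg.inv(AI)[np.ix_([0, 1, 2], [0, 1, 2])]
        r = sc / np.sqrt(sg1 * sg2)
        grad_r = np.array(
            [-r / (2 * sg1), -r / (2 * sg2), 1.0 / np.sqrt(sg1 * sg2)]
        )
        se_rg = float(np.sqrt(max(grad_r @ cov @ grad_r, 0.0)))
    except np.linalg.LinAlgError:
        pass

    return RgEstimate(
        gene_id=gene_id,
        pop_pair=pop_pair,
        sigma_g1_2=sg1,
        sigma_g2_2=sg2,
        sigma_g1g2=sc,
        rg=rg,
        se_rg=se_rg,
        converged=converged,
        bent=bent,
        n_iter=it,
        h2_1=h2_1,
        h2_2=h2_2,
    )


def aggregate_rg(
    estimates,
    h2_by_population: pd.DataFrame | None = None,
    h2_threshold_grid=(0.0,),
    mode: str = "min",
) -> pd.DataFrame:
    """Mean rG (with SE of the mean) over converged genes passing each h^2
    inclusion threshold.

    ``estimates`` is a list of RgEstimate or a DataFrame with columns
    gene_id, rg, converged (and h2_1/h2_2 if ``h2_by_population`` is not
    given).  ``mode`` selects the filtering h^2: "min" (both populations
    exceed the threshold) or a population column name from
    ``h2_by_population`` (single-population thresholding).
    """
    if not isinstance(estimates, pd.DataFrame):
        estimates = pd.DataFrame(
            [
                {
                    "gene_id": e.gene_id,
                    "rg": e.rg,
                    "converged": e.converged,
                    "h2_1": e.h2_1,
                    "h2_2": e.h2_2,
                }
                for e in estimates
            ]
        )
    df = estimates[estimates["converged"]].copy()
    if h2_by_population is not None:
        h2 = h2_by_population.set_index("gene_id") if "gene_id" in h2_by_population else h2_by_population
        if mode == "min":
            filt = h2.min(axis=1)
        else:
            if mode not in h2.columns:
                raise ValueError(f"unknown h2 filtering mode/population: {mode}")
            filt = h2[mode]
        df["h2_filter"] = df["gene_id"].map(filt)
    else:
        if mode != "min":
            raise ValueError("population mode requires h2_by_population")
        df["h2_filter"] = df[["h2_1", "h2_2"]].min(axis=1)
    rows = []
    for t in h2_threshold_grid:
        sub = df[df["h2_filter"] > t] if t > 0 else df
        n = len(sub)
        if n == 0:
            rows.append(
                {"threshold": t, "mean_rg": np.nan, "se_mean": np.nan, "n_genes": 0}
            )
        elif n == 1:
            rows.append(
                {
                    "threshold": t,
                    "mean_rg": float(sub["rg"].iloc[0]),
                    "se_mean": np.nan,
                    "n_genes": 1,
                }
            )
        else:
            rows.append(
                {
                    "threshold": t,
                    "mean_rg": float(sub["rg"].mean()),
                    "se_mean": float(sub["rg"].std(ddof=1) / np.sqrt(n)),
                    "n_genes": n,
                }
            )
    return pd.DataFrame(rows)


def write_grm_tsv(grm: Grm, path) -> None:
    """Lower-triangle text format: id1, id2, n_snps, value."""
    with open(path, "w") as fh:
        fh.write("id1\tid2\tn_snps\tvalue\n")
        for i, s1 in enumerate(grm.samples):
            for j in range(i + 1):
                fh.write(
                    f"{s1}\t{grm.samples[j]}\t{grm.n_snps_used}\t"
                    f"{grm.matrix[i, j]:.10g}\n"
                )


def read_grm_tsv(path) -> Grm:
    df = pd.read_csv(path, sep="\t")
    samples = list(dict.fromkeys(df["id1"]))
    index = {s: i for i, s in enumerate(samples)}
    n = len(samples)
    K = np.zeros((n, n))
    for _, row in df.iterrows():
        i, j = index[row["id1"]], index[row["id2"]]
        K[i, j] = K[j, i] = row["value"]
    return Grm(samples=samples, matrix=K, n_snps_used=int(df["n_snps"].iloc[0]))
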