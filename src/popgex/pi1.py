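"""Storey pi0/pi1 estimation and the replication true-positive rate.

pi1 = 1 - pi0 estimates the fraction of true alternatives in a collection
of p-values, assuming null p-values are uniform.  Here it serves as the
replication rate: significant discovery associations are carried into an
independent cohort and pi1 is computed on their replication p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["Pi1Estimate", "estimate_pi0", "replication_pi1"]

_DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass
class Pi1Estimate:
    pi0: float
    n_pvalues: int
    method: str  # "smoother" or "fixed"
    lambda_used: float

    @property
    def pi1(self) -> float:
        return 1.0 - self.pi0


def estimate_pi0(p_values, lambda_grid=None) -> Pi1Estimate:
    """Storey pi0 with cubic-smoother extrapolation to lambda -> 1.

    pi0(lambda) = #{p > lambda} / (m * (1 - lambda)) is computed on the
    grid; a least-squares cubic in lambda is evaluated at the maximum grid
    value and clamped to [0, 1].  With fewer than 100 p-values (or if the
    smoother fails) the fixed-lambda estimate at lambda = 0.5 is used.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    lam = (
        _DEFAULT_LAMBDA_GRID
        if lambda_grid is None
        else np.asarray(lambda_grid, dtype=float)
    )
    if np.any((lam <= 0) | (lam >= 1)):
        raise ValueError("lambda grid must lie in (0, 1)")
    lam = np.sort(lam)
    m = p.size
    pi0_lam = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])

    if m < 100 or lam.size < 4:
        l0 = 0.5
        pi0 = float((p > l0).sum() / (m * (1.0 - l0)))
        pi0c = float(np.clip(pi0, 0.0, 1.0))
        return Pi1Estimate(pi0=pi0c, n_pvalues=m, method="fixed", lambda_used=l0)

    try:
        coef = np.polyfit(lam, pi0_lam, deg=3)
        pi0 = float(np.polyval(coef, lam.max()))
    except np.linalg.LinAlgError:  # pragma: no cover - degenerate grid
        l0 = 0.5
        pi0 = float((p > l0).sum() / (m * (1.0 - l0)))
        return Pi1Estimate(
            pi0=float(np.clip(pi0, 0.0, 1.0)),
            n_pvalues=m,
            method="fixed",
            lambda_used=l0,
        )
    clamped = float(np.clip(pi0, 0.0, 1.0))
    if clamped != pi0:
        logger.info("pi0 smoother extrapolation %.4f clamped to %.4f", pi0, clamped)
    return Pi1Estimate(
        pi0=clamped, n_pvalues=m, method="smoother", lambda_used=float(lam.max())
    )


def _unit_keys(df: pd.DataFrame) -> pd.Series:
    if "unit" in df.columns:
        return df["unit"]
    if {"gene_id", "snp_id"}.issubset(df.columns):
        return df["gene_id"].astype(str) + ":" + df["snp_id"].astype(str)
    if "gene_id" in df.columns:
        return df["gene_id"].astype(str)
    raise ValueError("discovery table needs 'unit' or 'gene_id'[+'snp_id'] columns")


def replication_pi1(
    discovery: pd.DataFrame,
    discovery_fdr: float,
    replication_pvalues: dict,
    lambda_grid=None,
) -> Pi1Estimate:
    """pi1 of replication p-values for discovery-significant units.

    ``discovery`` carries an ``fdr`` column and unit keys (either a 'unit'
    column, or 'gene_id' [+ 'snp_id'] combined as "gene:snp");
    ``replication_pvalues`` maps the same unit keys to replication
    p-values.  Only discovery units with fdr < threshold that are present
    in the replication mapping are used.
    """
    keys = _unit_keys(discovery)
    passing = keys[discovery["fdr"] < discovery_fdr]
    shared = [k for k in passing if k in replication_pvalues]
    if not shared:
        raise ValueError("no shared units between discovery and replication")
    p = np.array([replication_pvalues[k] for k in shared], dtype=float)
    return estimate_pi0(p, lambda_grid=lambda_grid)
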