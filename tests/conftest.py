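"""Shared fixtures: small two-population cohorts with known architecture."""

import numpy as np
import pytest

from popgex.synth_data import (
    GeneAnnotation,
    GeneArchitectureTruth,
    PopulationSpec,
    draw_population_frequencies,
    simulate_genotypes,
)


@pytest.fixture(scope="session")
def two_pops():
    return [
        PopulationSpec("popA", 300, 0.1),
        PopulationSpec("popB", 300, 0.1),
    ]


@pytest.fixture(scope="session")
def shared_snps(two_pops):
    return draw_population_frequencies(120, two_pops, seed=11)


@pytest.fixture(scope="session")
def cohort_pair(two_pops, shared_snps):
    gA = simulate_genotypes(shared_snps, two_pops[0], seed=21)
    gB = simulate_genotypes(shared_snps, two_pops[1], seed=22)
    return gA, gB


def make_shared_truth(snps, labels, rho, h2, n_causal=5, seed=0):
    """Truth whose per-population effects have pairwise correlation rho."""
    rng = np.random.default_rng(seed)
    eligible = [
        s for s in snps
        if all(0.01 <= s.per_population_freq[l] <= 0.99 for l in labels)
    ]
    chosen = sorted(rng.choice(len(eligible), size=n_causal, replace=False))
    causal = [eligible[i] for i in chosen]
    base = rng.standard_normal(n_causal)
    betas = {}
    for l in labels:
        z = rng.standard_normal(n_causal)
        betas[l] = rho * base + np.sqrt(max(1 - rho**2, 0.0)) * z if rho < 1 else base.copy()
    return GeneArchitectureTruth(
        gene_id=f"gene_seed{seed}",
        causal_snp_ids=[s.snp_id for s in causal],
        beta_by_population=betas,
        h2_by_population={l: h2 for l in labels},
        rho_effects=rho,
        annotation=GeneAnnotation(f"gene_seed{seed}", causal[0].chromosome, causal[0].position),
    )
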