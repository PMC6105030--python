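"""Synthetic multi-population genotype and expression cohorts.

Populations diverge from a shared ancestral allele-frequency pool under a
Balding-Nichols model: for ancestral frequency p and divergence parameter F,
each population's frequency is Beta-distributed with mean p and variance
F*p*(1-p).  Gene expression is generated from a sparse cis architecture --
a few causal SNPs within the cis window -- with per-population effect
vectors drawn from a bivariate (or equicorrelated multivariate) normal with
unit marginals and correlation ``rho_effects``, then scaled so the realized
genetic variance fraction matches a target heritability h^2.

The ``simulate_h2_matched_null`` routine regenerates phenotypes with
independent effects (rho = 0) while preserving each population's h^2; it is
the null input for validating that the bivariate-REML genetic correlation
is unbiased at small sample sizes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "SnpRecord",
    "GenotypeMatrix",
    "GeneAnnotation",
    "GeneArchitectureTruth",
    "ExpressionPanel",
    "draw_population_frequencies",
    "simulate_genotypes",
    "simulate_gene_architecture",
    "simulate_expression",
    "genetic_value",
    "genetic_scale_for_h2",
    "simulate_h2_matched_null",
    "write_vcf",
    "write_dosage_tsv",
    "write_expression_tsv",
    "write_truth_tsv",
]

# non-strand-ambiguous allele pairs cycled over simulated SNPs
_ALLELE_CYCLE = (("A", "G"), ("C", "T"), ("G", "A"), ("T", "C"))


@dataclass(frozen=True)
class PopulationSpec:
    """A simulated population: label, cohort size and divergence from the
    ancestral frequency pool (Balding-Nichols F)."""

    label: str
    n_samples: int
    ancestry_fst: float

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError(f"n_samples must be >= 2, got {self.n_samples}")
        if not (0.0 < self.ancestry_fst < 1.0):
            raise ValueError(
                f"ancestry_fst must be in (0, 1), got {self.ancestry_fst}"
            )


@dataclass(frozen=True)
class SnpRecord:
    snp_id: str
    chromosome: str
    position: int  # 1-based
    ref_allele: str
    alt_allele: str
    per_population_freq: dict  # label -> alt-allele frequency

    def __post_init__(self) -> None:
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are equal")
        for label, f in self.per_population_freq.items():
            if not (0.0 <= f <= 1.0):
                raise ValueError(
                    f"{self.snp_id}: frequency for {label} outside [0,1]: {f}"
                )


@dataclass
class GenotypeMatrix:
    """samples x SNPs alt-allele dosage matrix with SNP metadata.

    Dosages are real-valued in [0, 2] to admit imputed data.
    """

    samples: list
    snps: list  # of SnpRecord
    dosages: np.ndarray  # (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if self.dosages.size and (
            self.dosages.min() < 0.0 or self.dosages.max() > 2.0
        ):
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_ids) -> np.ndarray:
        lookup = {s.snp_id: i for i, s in enumerate(self.snps)}
        try:
            return np.array([lookup[sid] for sid in snp_ids], dtype=int)
        except KeyError as exc:
            raise KeyError(f"SNP not present in genotype matrix: {exc}") from exc

    def subset_snps(self, snp_ids) -> "GenotypeMatrix":
        idx = self.snp_index(snp_ids)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=[self.snps[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def alt_freq(self) -> np.ndarray:
        """Sample alt-allele frequency per SNP."""
        return self.dosages.mean(axis=0) / 2.0

    def maf(self) -> np.ndarray:
        f = self.alt_freq()
        return np.minimum(f, 1.0 - f)


@dataclass(frozen=True)
class GeneAnnotation:
    gene_id: str
    chromosome: str
    tss: int  # 1-based


@dataclass
class GeneArchitectureTruth:
    """Ground-truth cis architecture for one simulated gene."""

    gene_id: str
    causal_snp_ids: list
    beta_by_population: dict  # label -> effect vector over causal SNPs
    h2_by_population: dict  # label -> target heritability in [0,1]
    rho_effects: float
    annotation: GeneAnnotation | None = None

    def __post_init__(self) -> None:
        if len(self.causal_snp_ids) < 1:
            raise ValueError(f"{self.gene_id}: empty causal SNP set")
        if not (-1.0 <= self.rho_effects <= 1.0):
            raise ValueError(f"{self.gene_id}: |rho_effects| > 1")
        for label, h2 in self.h2_by_population.items():
            if not (0.0 <= h2 <= 1.0):
                raise ValueError(f"{self.gene_id}: h2 for {label} outside [0,1]")


@dataclass
class ExpressionPanel:
    """samples x genes expression matrix plus gene annotation."""

    samples: list
    genes: list  # of GeneAnnotation
    values: np.ndarray  # (n_samples, n_genes)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples), len(self.genes)):
            raise ValueError(
                f"expression shape {self.values.shape} does not match "
                f"{len(self.samples)} samples x {len(self.genes)} genes"
            )

    @property
    def gene_ids(self) -> list:
        return [g.gene_id for g in self.genes]

    def gene_vector(self, gene_id: str) -> np.ndarray:
        try:
            j = self.gene_ids.index(gene_id)
        except ValueError:
            raise KeyError(f"gene not in panel: {gene_id}")
        return self.values[:, j]


def draw_population_frequencies(
    n_snps: int,
    pops: list,
    ancestral_freq_range: tuple = (0.1, 0.9),
    seed: int | None = None,
    chromosome: str = "1",
    start_position: int = 1000,
    spacing: int = 5000,
    id_prefix: str = "snp",
) -> list:
    """Draw per-population alt-allele frequencies for ``n_snps`` SNPs.

    The ancestral frequency p is uniform on ``ancestral_freq_range``; each
    population's frequency is Balding-Nichols Beta with mean p and variance
    F*p*(1-p), F = that population's ``ancestry_fst``.  Positions are
    strictly increasing along ``chromosome`` at the given spacing.
    """
    if n_snps < 1:
        raise ValueError(f"n_snps must be >= 1, got {n_snps}")
    if not pops:
        raise ValueError("pops must be a nonempty list of PopulationSpec")
    lo, hi = ancestral_freq_range
    if not (0.0 < lo < hi < 1.0):
        raise ValueError(
            f"ancestral_freq_range must be a nondegenerate interval within "
            f"(0, 1), got {ancestral_freq_range}"
        )
    rng = np.random.default_rng(seed)
    p = rng.uniform(lo, hi, size=n_snps)
    freqs = {}
    for pop in pops:
        F = pop.ancestry_fst
        if F < 1e-12:
            freqs[pop.label] = p.copy()
        else:
            a = p * (1.0 - F) / F
            b = (1.0 - p) * (1.0 - F) / F
            freqs[pop.label] = rng.beta(a, b)
    alleles = itertools.cycle(_ALLELE_CYCLE)
    records = []
    for i in range(n_snps):
        ref, alt = next(alleles)
        records.append(
            SnpRecord(
                snp_id=f"{id_prefix}{i + 1}",
                chromosome=chromosome,
                position=start_position + i * spacing,
                ref_allele=ref,
                alt_allele=alt,
                per_population_freq={
                    pop.label: float(freqs[pop.label][i]) for pop in pops
                },
            )
        )
    return records


def simulate_genotypes(
    snps: list, pop: PopulationSpec, seed: int | None = None
) -> GenotypeMatrix:
    """Binomial(2, freq) dosages per sample per SNP for one population."""
    for s in snps:
        if pop.label not in s.per_population_freq:
            raise KeyError(
                f"population label {pop.label!r} missing from SNP "
                f"{s.snp_id} frequency mapping"
            )
    rng = np.random.default_rng(seed)
    f = np.array([s.per_population_freq[pop.label] for s in snps])
    dosages = rng.binomial(2, f, size=(pop.n_samples, len(snps))).astype(float)
    samples = [f"{pop.label}_{i + 1}" for i in range(pop.n_samples)]
    return GenotypeMatrix(samples=samples, snps=list(snps), dosages=dosages)


def simulate_gene_architecture(
    gene_id: str,
    cis_snps: list,
    n_causal: int,
    h2_by_population: dict,
    rho_effects: float,
    seed: int | None = None,
    annotation: GeneAnnotation | None = None,
    maf_min: float = 0.01,
) -> GeneArchitectureTruth:
    """Sample causal SNPs and correlated per-population effect vectors.

    Causal SNPs are sampled uniformly without replacement from the cis SNPs
    whose frequency exceeds ``maf_min`` in every population (untestable
    architectures with near-monomorphic causal variants are avoided by
    default; pass maf_min=0 to disable).  Effects have unit marginal
    variance and pairwise correlation ``rho_effects`` between populations;
    rho = 0 gives the independent-effects null.
    """
    labels = list(h2_by_population)
    eligible = [
        s
        for s in cis_snps
        if all(
            min(s.per_population_freq[l], 1 - s.per_population_freq[l]) >= maf_min
            for l in labels
            if l in s.per_population_freq
        )
    ]
    if n_causal < 1 or n_causal > len(eligible):
        raise ValueError(
            f"{gene_id}: n_causal={n_causal} outside [1, {len(eligible)}] "
            f"eligible cis SNPs (maf_min={maf_min})"
        )
    k = len(labels)
    if k > 1 and rho_effects < -1.0 / (k - 1):
        raise ValueError(
            f"equicorrelation rho={rho_effects} not positive semidefinite "
            f"for {k} populations"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(eligible), size=n_causal, replace=False)
    causal = [eligible[i] for i in sorted(chosen)]
    cov = np.full((k, k), rho_effects)
    np.fill_diagonal(cov, 1.0)
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(k))
    z = rng.standard_normal((n_causal, k))
    effects = z @ L.T
    return GeneArchitectureTruth(
        gene_id=gene_id,
        causal_snp_ids=[s.snp_id for s in causal],
        beta_by_population={l: effects[:, j].copy() for j, l in enumerate(labels)},
        h2_by_population=dict(h2_by_population),
        rho_effects=float(rho_effects),
        annotation=annotation,
    )


def genetic_value(
    genotypes: GenotypeMatrix, truth: GeneArchitectureTruth, pop_label: str
) -> np.ndarray:
    """g = dosages over causal SNPs . beta for the given population."""
    idx = genotypes.snp_index(truth.causal_snp_ids)
    beta = np.asarray(truth.beta_by_population[pop_label], dtype=float)
    return genotypes.dosages[:, idx] @ beta


def genetic_scale_for_h2(g: np.ndarray, h2: float) -> float:
    """Scale a such that var(a*g) / (var(a*g) + 1) = h2, using the realized
    sample variance of g (residual noise has unit variance)."""
    if not (0.0 <= h2 <= 1.0):
        raise ValueError(f"h2 outside [0,1]: {h2}")
    if h2 == 0.0:
        return 0.0
    var_g = float(np.var(g, ddof=1))
    if var_g <= 0.0:
        raise ValueError("degenerate genetic variance")
    if h2 == 1.0:
        return 1.0 / np.sqrt(var_g)
    return float(np.sqrt(h2 / ((1.0 - h2) * var_g)))


def simulate_expression(
    genotypes: GenotypeMatrix,
    truth: GeneArchitectureTruth,
    pop_label: str,
    seed: int | None = None,
    genetic_scale: float | None = None,
) -> np.ndarray:
    """y = a*g + e with e ~ N(0, 1), a chosen so the realized genetic
    variance fraction equals the population's target h2.

    When ``genetic_scale`` is given it is used instead of the h2-derived
    scale (useful for carrying a training population's scale into a second
    population, so that heritability differences arise mechanistically from
    allele-frequency differences).  h2 = 1 returns the noiseless genetic
    value; h2 = 0 returns pure noise.
    """
    rng = np.random.default_rng(seed)
    g = genetic_value(genotypes, truth, pop_label)
    h2 = truth.h2_by_population[pop_label]
    a = genetic_scale if genetic_scale is not None else genetic_scale_for_h2(g, h2)
    if genetic_scale is None and h2 == 1.0:
        return a * g
    e = rng.standard_normal(genotypes.n_samples)
    return a * g + e


def simulate_h2_matched_null(
    panel_truths: list,
    genotypes_by_pop: dict,
    n_replicates: int,
    seed: int | None = None,
) -> list:
    """Regenerate expression with independent effects (rho forced to 0)
    while preserving each population's h2.

    Returns a list of ``n_replicates`` dicts mapping population label to an
    ExpressionPanel over that population's samples.  This is the h2-matched
    null used to verify the genetic-correlation estimator is unbiased: the
    downstream mean rG over many genes should be near zero.
    """
    if n_replicates < 1:
        raise ValueError(f"n_replicates must be >= 1, got {n_replicates}")
    rng = np.random.default_rng(seed)
    labels = list(genotypes_by_pop)
    replicates = []
    for _ in range(n_replicates):
        values = {l: [] for l in labels}
        genes = []
        for truth in panel_truths:
            n_causal = len(truth.causal_snp_ids)
            z = rng.standard_normal((n_causal, len(labels)))
            null_truth = GeneArchitectureTruth(
                gene_id=truth.gene_id,
                causal_snp_ids=list(truth.causal_snp_ids),
                beta_by_population={l: z[:, j].copy() for j, l in enumerate(labels)},
                h2_by_population=dict(truth.h2_by_population),
                rho_effects=0.0,
                annotation=truth.annotation,
            )
            genes.append(
                truth.annotation
                if truth.annotation is not None
                else GeneAnnotation(truth.gene_id, "1", 1)
            )
            for l in labels:
                y = simulate_expression(
                    genotypes_by_pop[l],
                    null_truth,
                    l,
                    seed=int(rng.integers(2**31)),
                )
                values[l].append(y)
        replicates.append(
            {
                l: ExpressionPanel(
                    samples=list(genotypes_by_pop[l].samples),
                    genes=genes,
                    values=np.column_stack(values[l]),
                )
                for l in labels
            }
        )
    return replicates


# ---------------------------------------------------------------------------
# text-format writers


def write_vcf(genotypes: GenotypeMatrix, path, dosage_field: bool = True) -> None:
    """Minimal VCF v4.2 with GT (rounded) and optionally DS per sample."""
    fmt = "GT:DS" if dosage_field else "GT"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description='
                '"Alt allele dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in genotypes.samples)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snps):
            calls = []
            for d in genotypes.dosages[:, j]:
                g = int(round(d))
                gt = {0: "0/0", 1: "0/1", 2: "1/1"}[min(max(g, 0), 2)]
                calls.append(f"{gt}:{d:g}" if dosage_field else gt)
            fh.write(
                f"{snp.chromosome}\t{snp.position}\t{snp.snp_id}\t"
                f"{snp.ref_allele}\t{snp.alt_allele}\t.\t.\t.\t{fmt}\t"
                + "\t".join(calls)
                + "\n"
            )


def write_dosage_tsv(genotypes: GenotypeMatrix, path) -> None:
    """Rows = SNPs: snp_id, chrom, pos, ref, alt, then one column/sample."""
    df = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "chrom": [s.chromosome for s in genotypes.snps],
            "pos": [s.position for s in genotypes.snps],
            "ref": [s.ref_allele for s in genotypes.snps],
            "alt": [s.alt_allele for s in genotypes.snps],
        }
    )
    dose = pd.DataFrame(
        genotypes.dosages.T, columns=[str(s) for s in genotypes.samples]
    )
    pd.concat([df, dose], axis=1).to_csv(path, sep="\t", index=False)


def write_expression_tsv(panel: ExpressionPanel, path) -> None:
    """Genes x samples table with gene annotation columns."""
    df = pd.DataFrame(
        {
            "gene_id": panel.gene_ids,
            "chrom": [g.chromosome for g in panel.genes],
            "tss": [g.tss for g in panel.genes],
        }
    )
    vals = pd.DataFrame(panel.values.T, columns=[str(s) for s in panel.samples])
    pd.concat([df, vals], axis=1).to_csv(path, sep="\t", index=False)


def write_truth_tsv(truths: list, path) -> None:
    rows = []
    for t in truths:
        for pop, beta in t.beta_by_population.items():
            for sid, b in zip(t.causal_snp_ids, beta):
                rows.append(
                    {
                        "gene_id": t.gene_id,
                        "snp_id": sid,
                        "pop": pop,
                        "beta": b,
                        "h2": t.h2_by_population[pop],
                        "rho": t.rho_effects,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
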