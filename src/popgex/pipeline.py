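"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order: simulate -> eqtl -> pi1 -> rg -> train ->
predict -> fst -> report.  Each stage's randomness derives
deterministically from the master seed and the stage name, so inserting a
stage never shifts another stage's draws.  A JSON manifest records
completion, output paths and wall-clock per stage; rerunning with the
same configuration resumes at the first incomplete stage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from popgex import cis_eqtl, divergence, elastic_net, greml, pi1 as pi1_mod
from popgex.synth_data import (
    ExpressionPanel,
    GeneAnnotation,
    GenotypeMatrix,
    PopulationSpec,
    SnpRecord,
    draw_population_frequencies,
    simulate_expression,
    simulate_gene_architecture,
    simulate_genotypes,
    write_dosage_tsv,
    write_expression_tsv,
    write_truth_tsv,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "stage_seed",
    "load_genotypes",
    "read_gene_annotation",
    "simulate_cohorts",
    "run_pipeline",
    "report_summary",
]

STAGES = ["simulate", "eqtl", "pi1", "rg", "train", "predict", "fst", "report"]

_ALLOWED_PCS = {0, 3, 5, 10}
_ALLOWED_FACTORS = {0, 10, 20, 30}


@dataclass
class PipelineConfig:
    """Validated parameters for a full synthetic-cohort run.

    Defaults reproduce the headline analysis grids: 3 genotype PCs, 10
    hidden expression factors, alpha grid {0.05, 0.5, 1}, FDR 0.05,
    training-R^2 inclusion thresholds {0, 0.01, 0.05, 0.1, 0.2} and F_ST
    difference thresholds 0.05-0.3.
    """

    populations: list = field(
        default_factory=lambda: [
            {"label": "pop1", "n_samples": 300, "ancestry_fst": 0.1},
            {"label": "pop2", "n_samples": 300, "ancestry_fst": 0.1},
        ]
    )
    n_genes: int = 200
    n_snps_per_gene: int = 150
    n_causal: int = 3
    h2_range: tuple = (0.05, 0.6)
    rho_effects: float = 0.8
    cis_window_bp: int = 1_000_000
    maf_min: float = 0.01
    n_pcs: int = 3
    n_hidden_factors: int = 10
    alpha_grid: tuple = (0.05, 0.5, 1.0)
    fdr_threshold: float = 0.05
    r2_thresholds: tuple = (0.0, 0.01, 0.05, 0.1, 0.2)
    fst_thresholds: tuple = (0.05, 0.1, 0.15, 0.2, 0.25, 0.3)
    h2_threshold_grid: tuple = (0.0, 0.1, 0.2, 0.3, 0.4)
    seed: int = 42
    output_dir: str = "popgex_run"

    def __post_init__(self) -> None:
        if len(self.populations) < 2:
            raise ValueError("at least two populations are required")
        self.populations = [
            p if isinstance(p, dict) else dict(p) for p in self.populations
        ]
        for p in self.populations:
            PopulationSpec(p["label"], p["n_samples"], p["ancestry_fst"])
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if not (1 <= self.n_causal <= self.n_snps_per_gene):
            raise ValueError("n_causal outside [1, n_snps_per_gene]")
        lo, hi = self.h2_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("h2_range must be within [0, 1]")
        if not (-1.0 <= self.rho_effects <= 1.0):
            raise ValueError("rho_effects outside [-1, 1]")
        if self.n_pcs not in _ALLOWED_PCS:
            raise ValueError(f"n_pcs must be one of {sorted(_ALLOWED_PCS)}")
        if self.n_hidden_factors not in _ALLOWED_FACTORS:
            raise ValueError(
                f"n_hidden_factors must be one of {sorted(_ALLOWED_FACTORS)}"
            )
        for a in self.alpha_grid:
            if not (0.0 < a <= 1.0):
                raise ValueError(f"alpha {a} outside (0, 1]")
        if not (0.0 < self.fdr_threshold < 1.0):
            raise ValueError("fdr_threshold outside (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        for key in (
            "h2_range", "alpha_grid", "r2_thresholds", "fst_thresholds",
            "h2_threshold_grid",
        ):
            d[key] = list(d[key])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class RunManifest:
    config_hash: str
    stages: dict = field(default_factory=dict)  # name -> {complete, outputs, seconds}

    def stage_complete(self, name: str) -> bool:
        return self.stages.get(name, {}).get("complete", False)

    def record(self, name: str, outputs: list, seconds: float) -> None:
        for dep in STAGES[: STAGES.index(name)]:
            if not self.stage_complete(dep):
                raise RuntimeError(
                    f"stage {name} cannot complete before dependency {dep}"
                )
        self.stages[name] = {
            "complete": True,
            "outputs": [str(o) for o in outputs],
            "seconds": round(seconds, 3),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "stages": self.stages}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(config_hash=raw["config_hash"], stages=raw["stages"])


def stage_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed: hash of (master_seed, stage name), < 2^31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# genotype I/O


def load_genotypes(path, format: str = "vcf") -> GenotypeMatrix:
    """Read a genotype matrix from VCF (GT or DS) or a dosage TSV.

    In VCF mode the DS field is preferred when present; multi-allelic
    records are skipped with a logged count.
    """
    if format == "vcf":
        return _load_vcf(path)
    if format == "dosage_tsv":
        return _load_dosage_tsv(path)
    raise ValueError(f"unknown genotype format: {format}")


def _load_vcf(path) -> GenotypeMatrix:
    samples: list = []
    snps: list = []
    rows: list = []
    n_multi = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                samples = line.split("\t")[9:]
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(f"{path}: malformed VCF record at line {lineno}")
            chrom, pos, vid, ref, alt = fields[:5]
            if "," in alt:
                n_multi += 1
                continue
            fmt = fields[8].split(":")
            try:
                ds_idx = fmt.index("DS") if "DS" in fmt else None
                gt_idx = fmt.index("GT") if "GT" in fmt else None
                doses = []
                for call in fields[9:]:
                    parts = call.split(":")
                    if ds_idx is not None:
                        doses.append(float(parts[ds_idx]))
                    elif gt_idx is not None:
                        gt = parts[gt_idx].replace("|", "/")
                        doses.append(float(sum(int(a) for a in gt.split("/"))))
                    else:
                        raise ValueError("record has neither GT nor DS")
                rows.append(doses)
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: malformed VCF record at line {lineno}: {exc}"
                ) from exc
            snps.append(
                SnpRecord(
                    snp_id=vid if vid != "." else f"{chrom}:{pos}",
                    chromosome=chrom,
                    position=int(pos),
                    ref_allele=ref,
                    alt_allele=alt,
                    per_population_freq={},
                )
            )
    if n_multi:
        logger.info("%s: skipped %d multi-allelic records", path, n_multi)
    dosages = np.array(rows, dtype=float).T if rows else np.zeros((len(samples), 0))
    return GenotypeMatrix(samples=samples, snps=snps, dosages=dosages)


def read_gene_annotation(path) -> list:
    """BED-like tab-separated gene annotation: chrom, tss, gene_id
    (header optional; extra columns ignored)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if str(df.iloc[0, 1]).strip().lower() in ("tss", "start"):
        df = df.iloc[1:]
    return [
        GeneAnnotation(str(r[2]), str(r[0]), int(r[1]))
        for _, r in df.iterrows()
    ]


def _load_dosage_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    meta_cols = ["snp_id", "chrom", "pos", "ref", "alt"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    snps = [
        SnpRecord(
            snp_id=str(r["snp_id"]),
            chromosome=str(r["chrom"]),
            position=int(r["pos"]),
            ref_allele=str(r["ref"]),
            alt_allele=str(r["alt"]),
            per_population_freq={},
        )
        for _, r in df.iterrows()
    ]
    return GenotypeMatrix(
        samples=sample_cols,
        snps=snps,
        dosages=df[sample_cols].to_numpy(dtype=float).T,
    )


# ---------------------------------------------------------------------------
# simulation stage


def simulate_cohorts(config: PipelineConfig, seed: int):
    """Generate genotypes, architectures and expression for every
    population on a shared gene grid.

    Each gene owns a block of ``n_snps_per_gene`` SNPs on its own
    chromosome with the TSS at the block center, so cis windows are
    gene-local.  Returns (genotypes_by_pop, expression_by_pop, truths,
    snps).
    """
    rng = np.random.default_rng(seed)
    pops = [
        PopulationSpec(p["label"], p["n_samples"], p["ancestry_fst"])
        for p in config.populations
    ]
    spacing = max(1, 2_000_000 // max(config.n_snps_per_gene, 1))
    blocks = [
        draw_population_frequencies(
            config.n_snps_per_gene,
            pops,
            seed=int(rng.integers(2**31)),
            chromosome=f"chr{gidx + 1}",
            spacing=spacing,
            id_prefix=f"g{gidx + 1}_snp",
        )
        for gidx in range(config.n_genes)
    ]
    snps = [s for block in blocks for s in block]
    genotypes = {
        p.label: simulate_genotypes(snps, p, seed=int(rng.integers(2**31)))
        for p in pops
    }
    lo, hi = config.h2_range
    truths = []
    panels = {p.label: [] for p in pops}
    genes = []
    for gidx in range(config.n_genes):
        block = blocks[gidx]
        tss = block[len(block) // 2].position
        ann = GeneAnnotation(f"gene{gidx + 1}", block[0].chromosome, tss)
        h2 = float(rng.uniform(lo, hi))
        truth = simulate_gene_architecture(
            ann.gene_id,
            block,
            config.n_causal,
            {p.label: h2 for p in pops},
            config.rho_effects,
            seed=int(rng.integers(2**31)),
            annotation=ann,
        )
        truths.append(truth)
        genes.append(ann)
        for p in pops:
            y = simulate_expression(
                genotypes[p.label], truth, p.label, seed=int(rng.integers(2**31))
            )
            panels[p.label].append(y)
    expression = {
        p.label: ExpressionPanel(
            samples=list(genotypes[p.label].samples),
            genes=genes,
            values=np.column_stack(panels[p.label]),
        )
        for p in pops
    }
    return genotypes, expression, truths, snps


# ---------------------------------------------------------------------------
# full pipeline


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute all stages in order, resuming from an existing manifest.

    Any stage failure halts downstream stages; the manifest records what
    completed.  Rerunning with an identical configuration is
    deterministic.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != config.config_hash():
            logger.warning("config changed; restarting pipeline from scratch")
            manifest = RunManifest(config_hash=config.config_hash())
    else:
        manifest = RunManifest(config_hash=config.config_hash())

    state: dict = {}

    def _run_stage(name, fn):
        if manifest.stage_complete(name):
            logger.info("stage %s already complete, skipped", name)
            return
        t0 = time.time()
        try:
            outputs = fn(stage_seed(config.seed, name))
        except Exception:
            manifest.save(manifest_path)
            logger.error("stage %s failed; downstream stages not run", name)
            raise
        manifest.record(name, outputs, time.time() - t0)
        manifest.save(manifest_path)

    # --- simulate
    def _simulate(seed):
        genotypes, expression, truths, snps = simulate_cohorts(config, seed)
        state.update(genotypes=genotypes, expression=expression, truths=truths)
        paths = []
        for label, g in genotypes.items():
            p = out / f"genotypes_{label}.tsv"
            write_dosage_tsv(g, p)
            paths.append(p)
        for label, e in expression.items():
            p = out / f"expression_{label}.tsv"
            write_expression_tsv(e, p)
            paths.append(p)
        truth_path = out / "truth.tsv"
        write_truth_tsv(truths, truth_path)
        paths.append(truth_path)
        return paths

    _run_stage("simulate", _simulate)
    if "genotypes" not in state:  # resumed: reload from stage outputs
        state["genotypes"] = {
            p["label"]: load_genotypes(
                out / f"genotypes_{p['label']}.tsv", "dosage_tsv"
            )
            for p in config.populations
        }
        state["expression"] = {
            p["label"]: _load_expression(out / f"expression_{p['label']}.tsv")
            for p in config.populations
        }

    labels = [p["label"] for p in config.populations]
    genotypes = state["genotypes"]
    expression = state["expression"]

    # covariates per population (PCs from genotypes; factors from expression)
    covariates = {}
    for label in labels:
        pcs = (
            cis_eqtl.genotype_pcs(genotypes[label], config.n_pcs)
            if config.n_pcs
            else cis_eqtl.CovariateSet.empty(genotypes[label].samples)
        )
        factors = (
            cis_eqtl.hidden_expression_factors(
                expression[label], config.n_hidden_factors, protect=pcs
            )
            if config.n_hidden_factors
            else cis_eqtl.CovariateSet.empty(genotypes[label].samples)
        )
        covariates[label] = pcs.concat(factors)

    # --- eqtl
    def _eqtl(seed):
        paths = []
        assoc = {}
        for label in labels:
            df = cis_eqtl.map_cis_eqtls(
                expression[label],
                genotypes[label],
                covariates[label],
                window_bp=config.cis_window_bp,
                maf_min=config.maf_min,
            )
            assoc[label] = df
            p = out / f"eqtl_{label}.tsv"
            df.to_csv(p, sep="\t", index=False)
            paths.append(p)
        state["associations"] = assoc
        return paths

    _run_stage("eqtl", _eqtl)
    if "associations" not in state:
        state["associations"] = {
            l: pd.read_csv(out / f"eqtl_{l}.tsv", sep="\t") for l in labels
        }
    associations = state["associations"]

    # --- pi1 (pairwise replication between populations)
    def _pi1(seed):
        rows = []
        for disc in labels:
            for repl in labels:
                if disc == repl:
                    continue
                repl_p = {
                    f"{g}:{s}": p
                    for g, s, p in zip(
                        associations[repl]["gene_id"],
                        associations[repl]["snp_id"],
                        associations[repl]["p_value"],
                    )
                }
                try:
                    est = pi1_mod.replication_pi1(
                        associations[disc], config.fdr_threshold, repl_p
                    )
                    rows.append(
                        {
                            "discovery": disc,
                            "replication": repl,
                            "pi1": est.pi1,
                            "n_pvalues": est.n_pvalues,
                            "method": est.method,
                        }
                    )
                except ValueError as exc:
                    logger.warning("pi1 %s->%s: %s", disc, repl, exc)
        df = pd.DataFrame(rows)
        p = out / "pi1_replication.tsv"
        df.to_csv(p, sep="\t", index=False)
        state["pi1_table"] = df
        return [p]

    _run_stage("pi1", _pi1)

    # --- rg (bivariate REML between the first two populations, per gene)
    def _rg(seed):
        l1, l2 = labels[0], labels[1]
        gene_ids = expression[l1].gene_ids
        positions = np.array([s.position for s in genotypes[l1].snps])
        chroms = np.array([s.chromosome for s in genotypes[l1].snps])
        snp_ids = np.array(genotypes[l1].snp_ids)
        rows = []
        for ann in expression[l1].genes:
            cis_mask = (chroms == ann.chromosome) & (
                np.abs(positions - ann.tss) <= config.cis_window_bp
            )
            cis = list(snp_ids[cis_mask])
            try:
                A, B, C = greml.bivariate_grms(
                    genotypes[l1], genotypes[l2], snp_subset=cis,
                    maf_min=config.maf_min,
                )
            except ValueError:
                continue
            y1 = expression[l1].gene_vector(ann.gene_id)
            y2 = expression[l2].gene_vector(ann.gene_id)
            est = greml.reml_bivariate_rg(
                A, B, C, y1, y2, gene_id=ann.gene_id, pop_pair=(l1, l2)
            )
            rows.append(
                {
                    "gene_id": ann.gene_id,
                    "pop_pair": f"{l1}-{l2}",
                    "h2_1": est.h2_1,
                    "h2_2": est.h2_2,
                    "rg": est.rg,
                    "se": est.se_rg,
                    "converged": est.converged,
                    "bent": est.bent,
                }
            )
        df = pd.DataFrame(rows)
        p = out / "rg_per_gene.tsv"
        df.to_csv(p, sep="\t", index=False)
        agg = greml.aggregate_rg(
            df.rename(columns={"rg": "rg"}),
            h2_threshold_grid=config.h2_threshold_grid,
        )
        p2 = out / "rg_by_h2_threshold.tsv"
        agg.to_csv(p2, sep="\t", index=False)
        state["rg_table"] = df
        return [p, p2]

    _run_stage("rg", _rg)

    # --- train (elastic-net models per population and alpha)
    def _train(seed):
        paths = []
        models_by_pop = {}
        perf_by_pop = {}
        for label in labels:
            models, perf = elastic_net.train_gene_models(
                expression[label],
                genotypes[label],
                covariates[label],
                alpha_grid=config.alpha_grid,
                window_bp=config.cis_window_bp,
                maf_min=config.maf_min,
                seed=seed,
                training_population=label,
            )
            models_by_pop[label] = models
            perf_by_pop[label] = perf
            p = out / f"models_{label}.tsv"
            elastic_net.write_model_weights_tsv(
                models, p, extra_path=out / f"models_{label}_extra.tsv"
            )
            perf.to_csv(out / f"cv_performance_{label}.tsv", sep="\t", index=False)
            paths.extend([p, out / f"cv_performance_{label}.tsv"])
        state["models"] = models_by_pop
        state["performance"] = perf_by_pop
        return paths

    _run_stage("train", _train)

    # --- predict (cross-population transfer, alpha = 0.5 models)
    def _predict(seed):
        models_by_pop = state["models"]
        perf_by_pop = state["performance"]
        alpha_star = 0.5 if 0.5 in config.alpha_grid else config.alpha_grid[0]
        rows = []
        for train_label in labels:
            half_models = {
                k: m
                for k, m in models_by_pop[train_label].items()
                if k[1] == alpha_star
            }
            for test_label in labels:
                if test_label == train_label:
                    continue
                predicted, _ = elastic_net.harmonize_and_predict(
                    half_models, genotypes[test_label]
                )
                perf = perf_by_pop[train_label]
                perf_a = perf[perf["alpha"] == alpha_star]
                ev = elastic_net.evaluate_transfer(
                    predicted,
                    expression[test_label],
                    perf_a,
                    r2_thresholds=config.r2_thresholds,
                    training_population=train_label,
                    test_cohort=test_label,
                )
                for t, est in ev.pi1_by_threshold.items():
                    rows.append(
                        {
                            "train": train_label,
                            "test": test_label,
                            "r2_threshold": t,
                            "pi1": est.pi1 if est else np.nan,
                            "n_genes": est.n_pvalues if est else 0,
                        }
                    )
        df = pd.DataFrame(rows)
        p = out / "transfer_pi1.tsv"
        df.to_csv(p, sep="\t", index=False)
        state["transfer_table"] = df
        return [p]

    _run_stage("predict", _predict)

    # --- fst (divergence test between the first two populations)
    def _fst(seed):
        l1, l2 = labels[0], labels[1]
        fst_table = divergence.weir_cockerham_fst_table(
            genotypes[l1], genotypes[l2]
        )
        p1 = out / "fst_per_snp.tsv"
        fst_table.drop(columns=["defined"]).to_csv(p1, sep="\t", index=False)
        alpha_star = 0.5 if 0.5 in config.alpha_grid else config.alpha_grid[0]
        perf1 = state["performance"][l1]
        perf2 = state["performance"][l2]
        r2_1 = perf1[perf1["alpha"] == alpha_star].set_index("gene_id")["r2"]
        r2_2 = perf2[perf2["alpha"] == alpha_star].set_index("gene_id")["r2"]
        summaries = {}
        for (gene_id, alpha), model in state["models"][l1].items():
            if alpha != alpha_star or len(model.weights) == 0:
                continue
            try:
                mean_fst, _ = divergence.model_fst_summary(model, fst_table)
                summaries[gene_id] = mean_fst
            except ValueError:
                continue
        summaries = pd.Series(summaries)
        test = divergence.divergence_wilcoxon(
            r2_1, r2_2, summaries, threshold_grid=config.fst_thresholds
        )
        p2 = out / "fst_divergence_test.tsv"
        test.to_csv(p2, sep="\t", index=False)
        state["fst_test"] = test
        return [p1, p2]

    _run_stage("fst", _fst)

    # --- report
    def _report(seed):
        p = out / "report.txt"
        report_summary(manifest, out, config, path=p)
        return [p]

    _run_stage("report", _report)
    return manifest


def _load_expression(path) -> ExpressionPanel:
    df = pd.read_csv(path, sep="\t")
    meta = ["gene_id", "chrom", "tss"]
    sample_cols = [c for c in df.columns if c not in meta]
    genes = [
        GeneAnnotation(str(r["gene_id"]), str(r["chrom"]), int(r["tss"]))
        for _, r in df.iterrows()
    ]
    return ExpressionPanel(
        samples=sample_cols,
        genes=genes,
        values=df[sample_cols].to_numpy(dtype=float).T,
    )


def report_summary(
    manifest: RunManifest, out_dir, config: PipelineConfig, path=None
) -> str:
    """Assemble the summary report from completed stage outputs.

    Emits eSNP/eGene counts, mean rG per h^2 threshold, alpha-comparison
    proportions, transfer pi1 by threshold, and the divergence-test rows.
    """
    missing = [s for s in STAGES[:-1] if not manifest.stage_complete(s)]
    if missing:
        raise RuntimeError(f"incomplete stages: {', '.join(missing)}")
    out = Path(out_dir)
    labels = [p["label"] for p in config.populations]
    lines = ["# popgex pipeline summary", ""]

    lines.append("## cis-eQTL counts (FDR < %g)" % config.fdr_threshold)
    for label in labels:
        df = pd.read_csv(out / f"eqtl_{label}.tsv", sep="\t")
        s = cis_eqtl.summarize_eqtls(df, config.fdr_threshold, label)
        lines.append(f"{label}: eSNPs={s.n_esnps} eGenes={s.n_egenes}")
    lines.append("")

    lines.append("## replication pi1 between populations")
    lines.append((out / "pi1_replication.tsv").read_text().rstrip())
    lines.append("")

    lines.append("## mean rG by h2 threshold")
    lines.append((out / "rg_by_h2_threshold.tsv").read_text().rstrip())
    lines.append("")

    lines.append("## alpha comparison (proportion lasso better)")
    for label in labels:
        perf = pd.read_csv(out / f"cv_performance_{label}.tsv", sep="\t")
        by_alpha = {
            a: g[["gene_id", "r2"]] for a, g in perf.groupby("alpha")
        }
        if 1.0 in by_alpha and len(by_alpha) > 1:
            cmp_df = elastic_net.compare_alpha_performance(by_alpha)
            lines.append(f"### {label}")
            lines.append(cmp_df.to_csv(sep="\t", index=False).rstrip())
    lines.append("")

    lines.append("## transfer pi1 by training-R2 threshold")
    lines.append((out / "transfer_pi1.tsv").read_text().rstrip())
    lines.append("")

    lines.append("## F_ST divergence test")
    lines.append((out / "fst_divergence_test.tsv").read_text().rstrip())
    lines.append("")

    text = "\n".join(lines)
    if path is not None:
        Path(path).write_text(text)
    return text
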