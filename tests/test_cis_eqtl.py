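"""cis-eQTL mapping: LD pruning, PCs, hidden factors, OLS scan, BH FDR."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from popgex.cis_eqtl import (
    CovariateSet,
    bh_fdr,
    genotype_pcs,
    hidden_expression_factors,
    ld_prune,
    map_cis_eqtls,
    summarize_eqtls,
)
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
)


def _matrix_from_dosages(dosages, positions=None, chrom="1"):
    n, m = dosages.shape
    snps = [
        SnpRecord(
            f"s{j}", chrom, (positions[j] if positions is not None else 100 + j * 10),
            "A", "G", {},
        )
        for j in range(m)
    ]
    return GenotypeMatrix([f"i{i}" for i in range(n)], snps, dosages)


def _brute_force_prune(dosages, window, r2_threshold):
    """Independent greedy rule: drop SNP j if r2 with any kept SNP within
    the trailing window exceeds the threshold."""
    kept = []
    for j in range(dosages.shape[1]):
        xj = dosages[:, j]
        if np.std(xj) == 0:
            kept.append(j)
            continue
        drop = False
        for i in kept:
            if j - i >= window or np.std(dosages[:, i]) == 0:
                continue
            r = np.corrcoef(dosages[:, i], xj)[0, 1]
            if r * r > r2_threshold:
                drop = True
                break
        if not drop:
            kept.append(j)
    return kept


class TestLdPrune:
    def test_uncorrelated_all_kept(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.5, size=(200, 6)).astype(float)
        # independence at n=200 gives r2 below any sensible threshold
        g = _matrix_from_dosages(X)
        assert len(ld_prune(g, window=5, r2_threshold=0.3)) == 6

    def test_duplicate_column_removed(self):
        rng = np.random.default_rng(2)
        x = rng.binomial(2, 0.4, size=50).astype(float)
        X = np.column_stack([x, x])
        g = _matrix_from_dosages(X)
        assert ld_prune(g, window=5, r2_threshold=0.9) == ["s0"]

    def test_monomorphic_always_kept(self):
        X = np.column_stack([np.ones(20), np.ones(20) * 2])
        g = _matrix_from_dosages(X)
        assert len(ld_prune(g, window=5, r2_threshold=0.1)) == 2

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(3)
        base = rng.binomial(2, 0.5, size=40).astype(float)
        X = np.column_stack([
            base,
            base + rng.binomial(1, 0.1, size=40),  # high LD with col 0
            rng.binomial(2, 0.5, size=40),
            base,                                   # duplicate of col 0
            rng.binomial(2, 0.3, size=40),
        ])
        X = np.clip(X, 0, 2)
        g = _matrix_from_dosages(X)
        kept = ld_prune(g, window=5, r2_threshold=0.3)
        expected = [f"s{j}" for j in _brute_force_prune(X, 5, 0.3)]
        assert kept == expected

    def test_window_too_small_raises(self):
        g = _matrix_from_dosages(np.zeros((5, 2)))
        with pytest.raises(ValueError, match="window"):
            ld_prune(g, window=1)


class TestGenotypePcs:
    def test_pc1_separates_populations(self):
        pops = [PopulationSpec("a", 60, 0.3), PopulationSpec("b", 60, 0.3)]
        snps = draw_population_frequencies(400, pops, seed=4)
        ga = simulate_genotypes(snps, pops[0], seed=5)
        gb = simulate_genotypes(snps, pops[1], seed=6)
        merged = GenotypeMatrix(
            ga.samples + gb.samples, snps,
            np.vstack([ga.dosages, gb.dosages]),
        )
        pcs = genotype_pcs(merged, 2)
        pc1 = pcs.columns["PC1"].to_numpy()
        assert max(pc1[:60].max(), -pc1[:60].min()) is not None
        # zero overlap between the two label groups on PC1
        assert pc1[:60].max() < pc1[60:].min() or pc1[60:].max() < pc1[:60].min()

    def test_zero_pcs_empty_set(self, cohort_pair):
        gA, _ = cohort_pair
        assert genotype_pcs(gA, 0).n_covariates == 0

    def test_orthonormal(self, cohort_pair):
        gA, _ = cohort_pair
        pcs = genotype_pcs(gA, 4).matrix()
        np.testing.assert_allclose(pcs.T @ pcs, np.eye(4), atol=1e-8)

    def test_too_many_pcs_raises(self):
        g = _matrix_from_dosages(
            np.random.default_rng(0).binomial(2, 0.5, (10, 5)).astype(float)
        )
        with pytest.raises(ValueError, match="n_pcs"):
            genotype_pcs(g, 9)


class TestHiddenFactors:
    def _panel(self, values):
        n, m = values.shape
        genes = [GeneAnnotation(f"g{j}", "1", 100 + j) for j in range(m)]
        return ExpressionPanel([f"i{i}" for i in range(n)], genes, values)

    def test_zero_factors_empty(self):
        panel = self._panel(np.random.default_rng(1).normal(size=(30, 10)))
        assert hidden_expression_factors(panel, 0).n_covariates == 0

    def test_recovers_planted_batch_shift(self):
        rng = np.random.default_rng(2)
        values = rng.normal(size=(80, 50))
        batch = np.zeros(80)
        batch[:40] = 1.0
        values += np.outer(batch, rng.normal(size=50) * 3)
        panel = self._panel(values)
        f1 = hidden_expression_factors(panel, 2).columns["factor1"].to_numpy()
        assert abs(np.corrcoef(f1, batch)[0, 1]) > 0.9

    def test_orthogonal_to_protected(self):
        rng = np.random.default_rng(3)
        panel = self._panel(rng.normal(size=(50, 30)))
        protect = CovariateSet(
            panel.samples, pd.DataFrame({"c": rng.normal(size=50)})
        )
        fac = hidden_expression_factors(panel, 3, protect=protect)
        for col in fac.columns:
            r = np.corrcoef(fac.columns[col], protect.columns["c"])[0, 1]
            assert abs(r) < 1e-6

    def test_too_many_factors_raises(self):
        panel = self._panel(np.random.default_rng(1).normal(size=(10, 5)))
        with pytest.raises(ValueError, match="n_factors"):
            hidden_expression_factors(panel, 10)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_all_ones(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_empty_returns_empty(self):
        assert bh_fdr([]).size == 0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0), min_size=2, max_size=40
        )
    )
    def test_monotone_in_rank_and_order_invariant(self, ps):
        p = np.array(ps)
        adj = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-12)
        assert np.all(adj >= p - 1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        np.testing.assert_allclose(adj[perm], bh_fdr(p[perm]))


def _single_gene_panel(y, tss=100_000, chrom="1", samples=None):
    return ExpressionPanel(
        samples or [f"i{i}" for i in range(len(y))],
        [GeneAnnotation("gene1", chrom, tss)],
        y[:, None],
    )


class TestMapCisEqtls:
    def test_window_boundary_closed_interval(self):
        rng = np.random.default_rng(1)
        X = rng.binomial(2, 0.5, size=(50, 3)).astype(float)
        tss = 2_000_000
        positions = [tss + 1_000_000, tss + 1_000_001, tss - 999_999]
        g = _matrix_from_dosages(X, positions=positions)
        panel = _single_gene_panel(rng.normal(size=50), tss=tss)
        df = map_cis_eqtls(panel, g, window_bp=1_000_000, maf_min=0.0)
        assert set(df["snp_id"]) == {"s0", "s2"}

    def test_planted_eqtl_is_top_hit(self, cohort_pair, shared_snps):
        gA, _ = cohort_pair
        hits = 0
        for rep in range(100):
            t = simulate_gene_architecture(
                "gene1", shared_snps, 1, {"popA": 0.3, "popB": 0.3}, 0.0,
                seed=rep,
            )
            y = simulate_expression(gA, t, "popA", seed=5000 + rep)
            ann = GeneAnnotation("gene1", "1", shared_snps[0].position)
            panel = ExpressionPanel(list(gA.samples), [ann], y[:, None])
            df = map_cis_eqtls(panel, gA, window_bp=10_000_000, maf_min=0.01)
            top = df.loc[df["p_value"].idxmin(), "snp_id"]
            hits += top == t.causal_snp_ids[0]
        assert hits >= 95

    def test_null_pvalues_uniform(self, cohort_pair):
        gA, _ = cohort_pair
        rng = np.random.default_rng(9)
        pools = []
        for rep in range(5):
            y = rng.normal(size=gA.n_samples)
            panel = _single_gene_panel(
                y, tss=gA.snps[0].position, samples=list(gA.samples)
            )
            df = map_cis_eqtls(panel, gA, window_bp=10_000_000, maf_min=0.01)
            pools.append(df["p_value"].to_numpy())
        from scipy import stats

        ks = stats.kstest(np.concatenate(pools), "uniform")
        assert ks.pvalue > 0.01

    def test_permuted_expression_yields_no_egenes(self, cohort_pair, shared_snps):
        gA, _ = cohort_pair
        rng = np.random.default_rng(13)
        genes, values = [], []
        for i in range(200):
            t = simulate_gene_architecture(
                f"gene{i}", shared_snps, 2, {"popA": 0.4, "popB": 0.4}, 0.0,
                seed=i,
            )
            y = simulate_expression(gA, t, "popA", seed=700 + i)
            values.append(rng.permutation(y))
            genes.append(GeneAnnotation(f"gene{i}", "1", shared_snps[0].position))
        panel = ExpressionPanel(list(gA.samples), genes, np.column_stack(values))
        df = map_cis_eqtls(panel, gA, window_bp=10_000_000, maf_min=0.01)
        summary = summarize_eqtls(df, 0.05)
        assert summary.n_egenes <= 1

    def test_rank_deficient_covariates_raise(self, cohort_pair):
        gA, _ = cohort_pair
        x = np.random.default_rng(1).normal(size=gA.n_samples)
        cov = CovariateSet(
            list(gA.samples), pd.DataFrame({"a": x, "b": 2 * x})
        )
        panel = _single_gene_panel(
            np.random.default_rng(2).normal(size=gA.n_samples),
            tss=gA.snps[0].position, samples=list(gA.samples),
        )
        with pytest.raises(ValueError, match="rank-deficient"):
            map_cis_eqtls(panel, gA, covariates=cov, window_bp=10_000_000)


class TestSummarize:
    def test_counting(self):
        df = pd.DataFrame(
            {
                "gene_id": ["g1", "g1", "g1", "g2"],
                "snp_id": ["s1", "s2", "s1", "s9"],
                "fdr": [0.01, 0.02, 0.04, 0.9],
            }
        )
        s = summarize_eqtls(df, 0.05)
        assert (s.n_esnps, s.n_egenes) == (2, 1)

    def test_no_passing_pairs(self):
        df = pd.DataFrame({"gene_id": ["g"], "snp_id": ["s"], "fdr": [0.5]})
        s = summarize_eqtls(df, 0.05)
        assert (s.n_esnps, s.n_egenes) == (0, 0)
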