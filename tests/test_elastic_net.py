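"""Elastic-net fitting, nested CV, allele harmonization, transfer."""

import numpy as np
import pandas as pd
import pytest

from popgex.elastic_net import (
    PredictionModel,
    compare_alpha_performance,
    elastic_net_objective,
    evaluate_transfer,
    fit_elastic_net_cv,
    harmonize_and_predict,
    nested_cv_performance,
)
from popgex.synth_data import (
    ExpressionPanel,
    GeneAnnotation,
    GenotypeMatrix,
    SnpRecord,
)


def _fista_oracle(y, X, alpha, lam, n_iter=20000):
    """Independent proximal-gradient (FISTA) solver for the elastic net."""
    n, p = X.shape
    yc = y - y.mean()
    L = np.linalg.eigvalsh(X.T @ X / n).max() + lam * (1 - alpha)
    w = np.zeros(p)
    z = w.copy()
    t = 1.0
    for _ in range(n_iter):
        grad = X.T @ (X @ z - yc) / n + lam * (1 - alpha) * z
        u = z - grad / L
        w_new = np.sign(u) * np.maximum(np.abs(u) - lam * alpha / L, 0.0)
        t_new = (1 + np.sqrt(1 + 4 * t * t)) / 2
        z = w_new + (t - 1) / t_new * (w_new - w)
        w, t = w_new, t_new
    return float(y.mean()), w


def _toy_instance(seed=0, n=20, p=10):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)  # pre-standardized so scales coincide
    beta = np.zeros(p)
    beta[:3] = [1.5, -1.0, 0.5]
    y = X @ beta + rng.standard_normal(n) * 0.5
    return y, X


class TestFitElasticNet:
    def test_lambda_max_gives_null_model(self):
        y, X = _toy_instance(1)
        n = len(y)
        lam_max = np.abs(X.T @ (y - y.mean())).max() / (n * 0.5)
        b0, w, _ = fit_elastic_net_cv(y, X, 0.5, lambda_override=lam_max * 1.0001)
        assert np.all(w == 0)
        assert b0 == pytest.approx(y.mean())

    def test_vanishing_penalty_matches_ols(self):
        rng = np.random.default_rng(2)
        n, p = 50, 5
        X = rng.standard_normal((n, p))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.standard_normal(n)
        b0, w, _ = fit_elastic_net_cv(y, X, 1.0, lambda_override=1e-8)
        design = np.column_stack([np.ones(n), X])
        ols = np.linalg.lstsq(design, y, rcond=None)[0]
        np.testing.assert_allclose(w, ols[1:], atol=1e-4)
        assert b0 == pytest.approx(ols[0], abs=1e-4)

    def test_objective_matches_independent_solver(self):
        y, X = _toy_instance(3)
        lam, alpha = 0.1, 0.5
        b0, w, _ = fit_elastic_net_cv(y, X, alpha, lambda_override=lam)
        b0_o, w_o = _fista_oracle(y, X, alpha, lam)
        obj = elastic_net_objective(y, X, b0, w, lam, alpha)
        obj_o = elastic_net_objective(y, X, b0_o, w_o, lam, alpha)
        assert obj <= obj_o + 1e-6

    def test_kkt_conditions_hold(self):
        for seed in range(20):
            y, X = _toy_instance(seed, n=30, p=8)
            lam, alpha = 0.05, 0.5
            b0, w, _ = fit_elastic_net_cv(y, X, alpha, lambda_override=lam)
            n = len(y)
            grad = -X.T @ (y - b0 - X @ w) / n + lam * (1 - alpha) * w
            for j in range(len(w)):
                if w[j] != 0:
                    assert abs(grad[j] + lam * alpha * np.sign(w[j])) < 1e-6
                else:
                    assert abs(grad[j]) <= lam * alpha + 1e-6

    def test_alpha_zero_rejected(self):
        y, X = _toy_instance(4)
        with pytest.raises(ValueError, match="alpha"):
            fit_elastic_net_cv(y, X, 0.0)

    def test_zero_variance_phenotype_rejected(self):
        _, X = _toy_instance(5)
        with pytest.raises(ValueError, match="zero-variance"):
            fit_elastic_net_cv(np.ones(len(X)), X, 0.5)


class TestNestedCv:
    def test_deterministic_signal(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.5, size=(300, 20)).astype(float)
        y = 2.0 * X[:, 7]
        perf = nested_cv_performance(y, X, 1.0, seed=1)
        assert perf.r2 >= 0.95

    def test_pure_noise_r2_near_zero(self):
        rng = np.random.default_rng(7)
        r2s = []
        for rep in range(100):
            X = rng.binomial(2, 0.5, size=(100, 20)).astype(float)
            y = rng.standard_normal(100)
            r2s.append(nested_cv_performance(y, X, 0.5, seed=rep).r2)
        assert np.mean(r2s) <= 0.02
        assert min(r2s) < 0  # negatives expected under the null

    def test_fold_assignment_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.binomial(2, 0.4, size=(80, 15)).astype(float)
        y = X[:, 3] + rng.standard_normal(80)
        a = nested_cv_performance(y, X, 0.5, seed=11)
        b = nested_cv_performance(y, X, 0.5, seed=11)
        assert a.r2 == b.r2

    def test_too_few_samples_raises(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.4, size=(8, 5)).astype(float)
        with pytest.raises(ValueError, match="outer folds"):
            nested_cv_performance(rng.normal(size=8), X, 0.5, outer_folds=5)


def _snp(snp_id, pos, ref, alt, chrom="1"):
    return SnpRecord(snp_id, chrom, pos, ref, alt, {})


def _model(weights_rows, intercept=0.0, freqs=None):
    w = pd.DataFrame(
        weights_rows,
        columns=["snp_id", "chrom", "pos", "effect_allele", "other_allele", "beta"],
    )
    return PredictionModel(
        gene_id="gene1",
        training_population="popA",
        alpha=0.5,
        intercept=intercept,
        weights=w,
        training_effect_allele_freq=freqs or {},
        lambda_selected=0.1,
    )


class TestHarmonizePredict:
    def test_dosage_arithmetic(self):
        model = _model([["snpA", "1", 100, "G", "A", 0.5]], freqs={"snpA": 0.3})
        g = GenotypeMatrix(
            ["i0", "i1", "i2"],
            [_snp("snpA", 100, "A", "G")],
            np.array([[0.0], [1.0], [2.0]]),
        )
        panel, omitted = harmonize_and_predict({("gene1", 0.5): model}, g)
        np.testing.assert_allclose(panel.values[:, 0], [0.0, 0.5, 1.0])
        assert omitted == []

    def test_flip_invariance(self):
        rng = np.random.default_rng(10)
        dos = rng.binomial(2, 0.4, size=(20, 3)).astype(float)
        snps = [
            _snp("s1", 100, "A", "G"),
            _snp("s2", 200, "C", "T"),
            _snp("s3", 300, "G", "A"),
        ]
        model = _model(
            [
                ["s1", "1", 100, "G", "A", 0.5],
                ["s2", "1", 200, "T", "C", -0.8],
                ["s3", "1", 300, "A", "G", 0.3],
            ],
            intercept=1.0,
            freqs={"s1": 0.4, "s2": 0.5, "s3": 0.6},
        )
        g = GenotypeMatrix([f"i{i}" for i in range(20)], snps, dos)
        swapped_snps = [
            _snp("s1", 100, "G", "A"),
            _snp("s2", 200, "T", "C"),
            _snp("s3", 300, "A", "G"),
        ]
        g_swapped = GenotypeMatrix(
            [f"i{i}" for i in range(20)], swapped_snps, 2.0 - dos
        )
        p1, _ = harmonize_and_predict({("gene1", 0.5): model}, g)
        p2, _ = harmonize_and_predict({("gene1", 0.5): model}, g_swapped)
        np.testing.assert_allclose(p1.values, p2.values, atol=1e-12)

    def test_ambiguous_snps_excluded_and_freq_imputed(self):
        model = _model(
            [["s1", "1", 100, "T", "A", 1.0]], intercept=0.0, freqs={"s1": 0.25}
        )
        g = GenotypeMatrix(
            ["i0", "i1"], [_snp("s1", 100, "A", "T")], np.array([[0.0], [2.0]])
        )
        panel, _ = harmonize_and_predict({("gene1", 0.5): model}, g)
        # A/T is strand-ambiguous: dosage replaced by 2 * training freq
        np.testing.assert_allclose(panel.values[:, 0], [0.5, 0.5])

    def test_drop_policy_omits_unmapped_gene(self):
        model = _model(
            [["s1", "1", 100, "G", "A", 1.0]], freqs={"s1": 0.25}
        )
        g = GenotypeMatrix(
            ["i0"], [_snp("sX", 999, "A", "G")], np.array([[1.0]])
        )
        panel, omitted = harmonize_and_predict(
            {("gene1", 0.5): model}, g, missing_policy="drop"
        )
        assert omitted == ["gene1"]
        assert panel.values.shape[1] == 0

    def test_zero_weight_model_constant_prediction(self):
        model = _model([], intercept=2.5)
        g = GenotypeMatrix(
            ["i0", "i1"], [_snp("s1", 100, "A", "G")], np.array([[0.0], [2.0]])
        )
        panel, _ = harmonize_and_predict({("gene1", 0.5): model}, g)
        np.testing.assert_allclose(panel.values[:, 0], 2.5)


def _panels(n_samples, n_genes, seed, noise=0.1, permute=False):
    rng = np.random.default_rng(seed)
    pred = rng.normal(size=(n_samples, n_genes))
    obs = pred + noise * rng.normal(size=pred.shape)
    if permute:
        obs = obs[rng.permutation(n_samples)]
    samples = [f"i{i}" for i in range(n_samples)]
    genes = [GeneAnnotation(f"g{j}", "1", 100 + j) for j in range(n_genes)]
    return (
        ExpressionPanel(samples, genes, pred),
        ExpressionPanel(samples, genes, obs),
    )


class TestEvaluateTransfer:
    def _training_perf(self, n_genes, r2=0.3):
        return pd.DataFrame(
            {"gene_id": [f"g{j}" for j in range(n_genes)], "r2": r2}
        )

    def test_near_perfect_prediction(self):
        pred, obs = _panels(100, 60, seed=1)
        ev = evaluate_transfer(pred, obs, self._training_perf(60))
        for t, est in ev.pi1_by_threshold.items():
            assert est is not None and est.pi1 >= 0.95

    def test_permuted_observations(self):
        pred, obs = _panels(100, 6000, seed=2, permute=True)
        ev = evaluate_transfer(pred, obs, self._training_perf(6000))
        for t, est in ev.pi1_by_threshold.items():
            assert est is not None and est.pi1 <= 0.05

    def test_sparse_threshold_reports_missing(self):
        pred, obs = _panels(50, 12, seed=3)
        perf = self._training_perf(12, r2=0.02)
        ev = evaluate_transfer(pred, obs, perf, r2_thresholds=(0.0, 0.1))
        assert ev.pi1_by_threshold[0.1] is None


class TestCompareAlpha:
    def test_single_gene_proportion_binary(self):
        by_alpha = {
            1.0: pd.DataFrame({"gene_id": ["g"], "r2": [0.5]}),
            0.05: pd.DataFrame({"gene_id": ["g"], "r2": [0.3]}),
        }
        out = compare_alpha_performance(by_alpha)
        assert out.loc[0, "proportion_lasso_better"] in (0.0, 1.0)

    def test_requires_lasso(self):
        with pytest.raises(ValueError, match="lasso"):
            compare_alpha_performance(
                {0.5: pd.DataFrame({"gene_id": ["g"], "r2": [0.1]})}
            )

    def test_counts_over_shared_genes(self):
        by_alpha = {
            1.0: pd.DataFrame({"gene_id": ["g1", "g2", "g3"], "r2": [0.5, 0.2, 0.4]}),
            0.05: pd.DataFrame({"gene_id": ["g1", "g2"], "r2": [0.3, 0.25]}),
        }
        out = compare_alpha_performance(by_alpha)
        assert out.loc[0, "n_genes"] == 2
        assert out.loc[0, "n_lasso_better"] == 1
        assert out.loc[0, "proportion_lasso_better"] == pytest.approx(0.5)
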