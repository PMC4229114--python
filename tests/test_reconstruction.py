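import numpy as np
import pytest
from scipy.stats import rankdata

from ena import (
    ExpressionMatrix,
    ReconstructionConfig,
    ValidationError,
    evaluate,
    generate_scale_free,
    reconstruct,
    reconstruct_shrinkage_pcor,
    reconstruct_softcor,
    reconstruct_space,
    simulate_expression,
)
from ena.reconstruction import default_space_lambda, shrinkage_intensity
from ena.simulation import SimulationConfig


def make_expr(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        tuple(f"{prefix}{i}" for i in range(values.shape[0])),
        tuple(f"s{j}" for j in range(values.shape[1])),
        values,
    )


def fourier_expr(p, n):
    """Genes with exactly identity sample correlation (orthogonal,
    mean-zero Fourier components)."""
    t = np.arange(n)
    rows = [np.cos(2 * np.pi * (k + 1) * t / n) for k in range(p)]
    return make_expr(rows)


class TestSoftcor:
    def test_duplicate_genes_score_one(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(50)
        net = reconstruct_softcor(make_expr([x, x.copy(), rng.standard_normal(50)]))
        assert net.scores[0, 1] == pytest.approx(1.0)

    def test_beta_one_equals_absolute_correlation(self):
        rng = np.random.default_rng(1)
        expr = make_expr(rng.standard_normal((4, 40)))
        net = reconstruct_softcor(expr, ReconstructionConfig(method="softcor", beta=1.0))
        expected = np.abs(np.corrcoef(expr.values))
        np.fill_diagonal(expected, 0.0)
        np.testing.assert_allclose(net.scores, expected, atol=1e-12)

    def test_beta_never_changes_ranking(self):
        rng = np.random.default_rng(2)
        expr = make_expr(rng.standard_normal((6, 30)))
        r1 = rankdata(-reconstruct_softcor(expr, ReconstructionConfig(beta=1.0)).tri_values())
        r6 = rankdata(-reconstruct_softcor(expr, ReconstructionConfig(beta=6.0)).tri_values())
        np.testing.assert_array_equal(r1, r6)

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(3)
        net = reconstruct_softcor(make_expr(rng.standard_normal((5, 25))))
        assert np.all((net.scores >= 0) & (net.scores <= 1))


class TestShrinkagePcor:
    def test_identity_correlation_gives_zero_scores(self):
        net = reconstruct_shrinkage_pcor(fourier_expr(4, 32))
        assert np.abs(net.scores).max() < 1e-10

    def test_chain_partial_correlation_ordering(self, chain_expression_factory):
        expr = chain_expression_factory([0.8, 0.8], n=1000, noise_sd=0.1, seed=0)
        net = reconstruct_shrinkage_pcor(expr)
        assert net.scores[0, 1] > net.scores[0, 2]
        assert net.scores[1, 2] > net.scores[0, 2]

    def test_intensity_clipped_to_unit_interval(self):
        rng = np.random.default_rng(5)
        for p, n in [(5, 10), (10, 4), (3, 100)]:
            lam = shrinkage_intensity(make_expr(rng.standard_normal((p, n))))
            assert 0.0 <= lam <= 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            reconstruct_shrinkage_pcor(make_expr(np.eye(3)[:, :2]))


class TestSpace:
    def test_two_gene_positive_dependence(self):
        rng = np.random.default_rng(7)
        a = rng.standard_normal(200)
        b = 0.9 * a + 0.25 * rng.standard_normal(200)
        net = reconstruct_space(make_expr([a, b]))
        assert net.scores[0, 1] > 0.3

    def test_independent_genes_all_zero_at_moderate_lambda(self):
        # a penalty twice the Bonferroni default wipes out spurious edges
        rng = np.random.default_rng(8)
        expr = make_expr(rng.standard_normal((10, 500)))
        lam = 2 * default_space_lambda(500, 10)
        net = reconstruct_space(expr, ReconstructionConfig(lam=lam))
        assert np.abs(net.scores).max() == 0.0

    def test_chain_recovery_shrinks_indirect_edge(self, chain_expression_factory):
        expr = chain_expression_factory([0.9, 0.9], n=1000, noise_sd=0.1, seed=1)
        net = reconstruct_space(expr)
        assert abs(net.scores[0, 1]) > abs(net.scores[0, 2])
        assert abs(net.scores[1, 2]) > abs(net.scores[0, 2])
        assert net.scores[0, 2] == 0.0  # indirect edge killed by the lasso

    def test_output_is_sparse_partial_correlation(self):
        cfg = SimulationConfig(44, 57, 100, 0.5, seed=2)
        truth = generate_scale_free(cfg)
        net = reconstruct_space(simulate_expression(truth, cfg))
        off = net.tri_values()
        assert np.count_nonzero(off) < off.size / 2
        assert np.abs(off).max() <= 1.0

    def test_parameter_recovery_auc(self):
        """True edges occupy the top ranks when n >> p."""
        cfg = SimulationConfig(20, 25, 1000, 0.25, seed=42)
        truth = generate_scale_free(cfg)
        net = reconstruct_space(simulate_expression(truth, cfg))
        assert evaluate(net, truth).auc > 0.9

    def test_zero_variance_gene_named(self):
        vals = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(ValidationError, match="g0"):
            reconstruct_space(make_expr(vals))


class TestSharedContracts:
    @pytest.mark.parametrize("method", ["space", "shrinkage_pcor", "softcor"])
    def test_symmetric_zero_diagonal_input_order(self, method):
        rng = np.random.default_rng(11)
        expr = make_expr(rng.standard_normal((6, 50)))
        net = reconstruct(expr, method)
        assert net.gene_ids == expr.gene_ids
        np.testing.assert_array_equal(net.scores, net.scores.T)
        assert np.all(np.diag(net.scores) == 0)

    @pytest.mark.parametrize("method", ["shrinkage_pcor", "softcor"])
    def test_affine_rescaling_invariance(self, method):
        rng = np.random.default_rng(12)
        expr = make_expr(rng.standard_normal((5, 40)))
        scale = rng.uniform(0.5, 20.0, size=(5, 1))
        shift = rng.uniform(-5, 5, size=(5, 1))
        rescaled = make_expr(expr.values * scale + shift)
        a = reconstruct(expr, method)
        b = reconstruct(rescaled, method)
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_space_standardisation_invariance(self):
        rng = np.random.default_rng(13)
        expr = make_expr(rng.standard_normal((5, 60)))
        scale = rng.uniform(0.5, 20.0, size=(5, 1))
        a = reconstruct_space(expr)
        b = reconstruct_space(make_expr(expr.values * scale + 3.0))
        np.testing.assert_allclose(a.scores, b.scores, atol=1e-8)

    def test_unknown_method_rejected(self):
        rng = np.random.default_rng(14)
        with pytest.raises(ValidationError, match="unknown method"):
            reconstruct(make_expr(rng.standard_normal((3, 10))), "aracne")
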