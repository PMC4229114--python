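import numpy as np
import pytest
from scipy.stats import rankdata

import ena.ensemble as ens_mod
from ena import (
    EnsembleConfig,
    ValidationError,
    bootstrap_ena,
    multidataset_ena,
    multimethod_ena,
    pool_expressions,
    rank_product_aggregate,
    reconstruct,
    simulate_expression,
)
from ena.netio import ExpressionMatrix
from ena.simulation import SimulationConfig, generate_scale_free


@pytest.fixture(scope="module")
def small_dataset():
    cfg = SimulationConfig(17, 20, 40, 0.5, seed=30)
    truth = generate_scale_free(cfg)
    return truth, simulate_expression(truth, cfg)


def ranking(net):
    return rankdata(-np.abs(net.tri_values()))


class TestBootstrap:
    def test_degenerate_ensemble_matches_plain_reconstruction(self, small_dataset):
        _, expr = small_dataset
        plain = reconstruct(expr, "softcor")
        ens = bootstrap_ena(expr, "softcor", EnsembleConfig(B=1, sample_fraction=1.0, seed=1))
        np.testing.assert_array_equal(ranking(plain), ranking(ens))

    def test_worker_count_does_not_change_result(self, small_dataset):
        _, expr = small_dataset
        a = bootstrap_ena(expr, "softcor", EnsembleConfig(B=6, seed=5, workers=1))
        b = bootstrap_ena(expr, "softcor", EnsembleConfig(B=6, seed=5, workers=3))
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_seed_determinism(self, small_dataset):
        _, expr = small_dataset
        cfg = EnsembleConfig(B=4, seed=9)
        a = bootstrap_ena(expr, "shrinkage_pcor", cfg)
        b = bootstrap_ena(expr, "shrinkage_pcor", cfg)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_too_small_replicates_rejected(self, small_dataset):
        _, expr = small_dataset
        tiny = expr.subset_samples(range(3))
        with pytest.raises(ValidationError):
            bootstrap_ena(tiny, "softcor", EnsembleConfig(B=2, sample_fraction=0.5))

    def test_sporadic_failures_skipped_with_warning(self, small_dataset, monkeypatch):
        _, expr = small_dataset
        real = ens_mod.reconstruct
        calls = {"n": 0}

        def flaky(e, method, cfg):
            calls["n"] += 1
            if calls["n"] == 2:
                raise RuntimeError("boom")
            return real(e, method, cfg)

        monkeypatch.setattr(ens_mod, "reconstruct", flaky)
        with pytest.warns(RuntimeWarning, match="boom"):
            net = bootstrap_ena(expr, "softcor", EnsembleConfig(B=10, seed=2))
        assert len(net.provenance) == 9

    def test_excessive_failures_hard_error(self, small_dataset, monkeypatch):
        _, expr = small_dataset

        def broken(e, method, cfg):
            raise RuntimeError("dead")

        monkeypatch.setattr(ens_mod, "reconstruct", broken)
        with pytest.raises(ValidationError, match="failed"), pytest.warns(RuntimeWarning):
            bootstrap_ena(expr, "softcor", EnsembleConfig(B=5, seed=2))


class TestMultiMethod:
    def test_identical_copies_preserve_ranking(self, small_dataset):
        _, expr = small_dataset
        net = reconstruct(expr, "softcor")
        agg = rank_product_aggregate([net, net, net])
        np.testing.assert_array_equal(ranking(net), ranking(agg))

    def test_reversed_rankings_give_symmetric_products(self):
        """Two exactly reversed rankings: pairs with rank r and K+1-r end
        up with identical rank products r*(K+1-r)."""
        rng = np.random.default_rng(0)
        vals = np.sort(rng.uniform(0.1, 1.0, 6))[::-1]  # distinct, descending
        p = 4
        i, j = np.tril_indices(p, k=-1)
        s1 = np.zeros((p, p))
        s1[i, j] = s1[j, i] = vals
        s2 = np.zeros((p, p))
        s2[i, j] = s2[j, i] = vals[::-1]
        n1 = ens_mod.WeightedNetwork(tuple("abcd"), s1)
        n2 = ens_mod.WeightedNetwork(tuple("abcd"), s2)
        agg = rank_product_aggregate([n1, n2]).tri_values()
        k = 6
        expected = (np.arange(1, 7) * (k + 1 - np.arange(1, 7))) ** -0.5
        np.testing.assert_allclose(np.sort(agg), np.sort(expected), rtol=1e-12)

    def test_requires_at_least_one_method(self, small_dataset):
        with pytest.raises(ValidationError):
            EnsembleConfig(methods=())

    def test_single_method_failure_is_fatal(self, small_dataset, monkeypatch):
        _, expr = small_dataset

        def broken(e, method, cfg):
            raise RuntimeError("dead method")

        monkeypatch.setattr(ens_mod, "reconstruct", broken)
        with pytest.raises((ValidationError, RuntimeError)):
            multimethod_ena(expr, EnsembleConfig(B=1, methods=("softcor", "shrinkage_pcor")))


class TestMultiDataset:
    def test_identical_datasets_match_single_dataset_ensemble(self, small_dataset):
        _, expr = small_dataset
        cfg = EnsembleConfig(B=1, methods=("softcor", "shrinkage_pcor"), seed=3)
        single = multimethod_ena(expr, cfg)
        double = multidataset_ena([expr, expr], cfg)
        np.testing.assert_array_equal(ranking(single), ranking(double))

    def test_gene_intersection_contract(self):
        rng = np.random.default_rng(40)
        base = rng.standard_normal((4, 30))
        e1 = ExpressionMatrix(("A", "B", "C"), tuple(f"s{j}" for j in range(30)), base[:3])
        e2 = ExpressionMatrix(("B", "C", "D"), tuple(f"t{j}" for j in range(30)), base[1:])
        cfg = EnsembleConfig(B=1, methods=("softcor",))
        with pytest.warns(RuntimeWarning, match="shared genes"):
            net = multidataset_ena([e1, e2], cfg)
        assert net.gene_ids == ("B", "C")

    def test_empty_intersection_rejected(self):
        rng = np.random.default_rng(41)
        e1 = ExpressionMatrix(("A", "B"), ("s1", "s2", "s3"), rng.standard_normal((2, 3)))
        e2 = ExpressionMatrix(("C", "D"), ("s1", "s2", "s3"), rng.standard_normal((2, 3)))
        with pytest.raises(ValidationError):
            multidataset_ena([e1, e2], EnsembleConfig(B=1, methods=("softcor",)))

    def test_flat_and_nested_orders_both_run(self, small_dataset):
        _, expr = small_dataset
        half1 = expr.subset_samples(range(20))
        half2 = expr.subset_samples(range(20, 40))
        for flat in (False, True):
            cfg = EnsembleConfig(B=2, methods=("softcor",), seed=4, flat=flat)
            net = multidataset_ena([half1, half2], cfg)
            assert net.gene_ids == expr.gene_ids


class TestPooling:
    def test_pooled_matrix_concatenates_common_genes(self):
        rng = np.random.default_rng(50)
        e1 = ExpressionMatrix(("A", "B"), ("s1", "s2"), rng.standard_normal((2, 2)))
        e2 = ExpressionMatrix(("B", "A"), ("s1", "s2", "s3"), rng.standard_normal((2, 3)))
        pooled = pool_expressions([e1, e2])
        assert pooled.n_samples == 5
        assert pooled.gene_ids == ("A", "B")
        np.testing.assert_array_equal(pooled.values[:, :2], e1.values)
        np.testing.assert_array_equal(pooled.values[0, 2:], e2.values[1])
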