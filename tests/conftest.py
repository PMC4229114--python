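import numpy as np
import pytest

from ena import ExpressionMatrix, TrueNetwork, WeightedNetwork


@pytest.fixture
def three_gene_net():
    """A-B strong, A-C medium, B-C weak."""
    scores = np.array([[0.0, 0.9, 0.5], [0.9, 0.0, 0.1], [0.5, 0.1, 0.0]])
    return WeightedNetwork(("A", "B", "C"), scores)


@pytest.fixture
def chain_truth():
    return TrueNetwork(("A", "B", "C"), frozenset({("A", "B"), ("B", "C")}))


def random_network(gene_ids, seed):
    rng = np.random.default_rng(seed)
    m = rng.standard_normal((len(gene_ids), len(gene_ids)))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return WeightedNetwork(tuple(gene_ids), m)


@pytest.fixture
def random_network_factory():
    return random_network


def chain_expression(weights, n, noise_sd, seed):
    """Markov chain of genes: X_0 ~ N(0,1); X_k = w_k X_{k-1} + N(0,1);
    observed with additive noise of sd ``noise_sd``."""
    rng = np.random.default_rng(seed)
    p = len(weights) + 1
    x = np.empty((p, n))
    x[0] = rng.standard_normal(n)
    for k, w in enumerate(weights, start=1):
        x[k] = w * x[k - 1] + rng.standard_normal(n)
    x += noise_sd * rng.standard_normal((p, n))
    names = tuple(chr(ord("A") + k) for k in range(p))
    return ExpressionMatrix(names, tuple(f"s{j}" for j in range(n)), x)


@pytest.fixture
def chain_expression_factory():
    return chain_expression
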