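"""Synthetic gold-standard topologies and expression data.

``generate_scale_free`` grows an approximately scale-free undirected
network with an *exact* node and edge count: a preferential-attachment
tree guarantees connectivity (each new node attaches to an existing node
with probability proportional to degree), and the remaining edges are
added one at a time between degree-weighted endpoint draws.  Hubs emerge
exactly as in the usual preferential-attachment construction; the
default study sizes (17/20, 44/57, 83/114, 231/311, 612/911
genes/edges) mimic protein-interaction subnetworks of increasing span.

``simulate_expression`` draws expression from a linear Gaussian model on
the generated topology.  Edges are oriented from the earlier-generated
node to the later one (a DAG by construction) and given weights drawn
uniformly from ``edge_weight_range`` with random sign.  Each node's
latent value is the weighted sum of its parents plus a unit-variance
Gaussian innovation (roots are standard normal), i.e. a conditional
normal distribution given the parents; the observed expression adds
measurement noise with standard deviation ``noise_sd`` to every value.
Keeping the regulatory signal on a fixed unit scale and varying the
observation-noise sd makes the noise level a genuine difficulty dial:
for a two-gene network with weight w the population correlation is
``w / sqrt((1 + sd^2) (w^2 + 1 + sd^2))``, decreasing in the noise.

``generate_grid`` enumerates the full factorial study grid (network
size x sample size x noise level) with seeds derived from one master
seed, 120 datasets at the default factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .netio import ExpressionMatrix, TrueNetwork, ValidationError

__all__ = [
    "SimulationConfig",
    "DEFAULT_SIZES",
    "DEFAULT_SAMPLE_SIZES",
    "DEFAULT_NOISE_LEVELS",
    "generate_scale_free",
    "assign_edge_weights",
    "simulate_expression",
    "generate_grid",
]

#: (genes, edges) pairs of the default study networks
DEFAULT_SIZES = ((17, 20), (44, 57), (83, 114), (231, 311), (612, 911))
DEFAULT_SAMPLE_SIZES = (20, 50, 100, 200, 500, 1000)
DEFAULT_NOISE_LEVELS = (0.25, 0.5, 1.0, 1.5)


@dataclass(frozen=True)
class SimulationConfig:
    n_genes: int
    n_edges: int
    n_samples: int = 100
    noise_sd: float = 0.25
    edge_weight_range: tuple[float, float] = (0.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        max_edges = self.n_genes * (self.n_genes - 1) // 2
        if not (0 <= self.n_edges <= max_edges):
            raise ValidationError(
                f"n_edges={self.n_edges} out of range [0, {max_edges}] for {self.n_genes} genes"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        lo, hi = self.edge_weight_range
        if not (0 < lo <= hi):
            raise ValidationError("edge_weight_range must satisfy 0 < low <= high")


def _gene_names(p: int) -> tuple[str, ...]:
    width = max(3, len(str(p)))
    return tuple(f"G{k + 1:0{width}d}" for k in range(p))


def generate_scale_free(config: SimulationConfig) -> TrueNetwork:
    """Seeded preferential-attachment network with exactly
    ``config.n_genes`` nodes and ``config.n_edges`` edges (connected
    whenever ``n_edges >= n_genes - 1``)."""
    p, m = config.n_genes, config.n_edges
    if p > 1 and m < p - 1:
        raise ValidationError(f"n_edges={m} cannot connect {p} genes (need >= {p - 1})")
    rng = np.random.default_rng(config.seed)
    degree = np.zeros(p, dtype=float)
    edges: set[tuple[int, int]] = set()

    def add(u: int, v: int) -> None:
        edges.add((min(u, v), max(u, v)))
        degree[u] += 1
        degree[v] += 1

    if p >= 2:
        add(0, 1)
    # preferential-attachment tree: connectivity + heavy-tailed degrees
    for k in range(2, p):
        probs = degree[:k] / degree[:k].sum()
        add(k, int(rng.choice(k, p=probs)))
    # remaining edges between degree-weighted endpoints
    guard = 0
    while len(edges) < m:
        probs = degree / degree.sum()
        u, v = rng.choice(p, size=2, p=probs)
        if u != v and (min(u, v), max(u, v)) not in edges:
            add(int(u), int(v))
        guard += 1
        if guard > 1000 * max(m, 1):  # dense corner: fall back to uniform pairs
            i, j = np.tril_indices(p, k=-1)
            free = [(a, b) for a, b in zip(j, i) if (a, b) not in edges]
            for idx in rng.choice(len(free), size=m - len(edges), replace=False):
                add(*free[idx])
            break
    names = _gene_names(p)
    return TrueNetwork(names, frozenset((names[a], names[b]) for a, b in edges))


def assign_edge_weights(truth: TrueNetwork, config: SimulationConfig) -> dict:
    """Signed regulatory weight per edge, drawn uniformly from
    ``config.edge_weight_range`` with a random sign (seeded).

    Weights belong to the *system*, not to a measurement of it: to
    emulate several datasets observing the same network, draw the
    weights once and pass them to each :func:`simulate_expression` call.
    """
    return _draw_weights(truth, config, np.random.default_rng(config.seed))


def _draw_weights(truth: TrueNetwork, config: SimulationConfig, rng) -> dict:
    lo, hi = config.edge_weight_range
    weights = {}
    for a, b in sorted(truth.edges):
        weights[(a, b)] = rng.uniform(lo, hi) * (1.0 if rng.random() < 0.5 else -1.0)
    return weights


def _dag_parents(truth: TrueNetwork, weights: dict) -> list[list[tuple[int, float]]]:
    """Parents (earlier-indexed neighbours) and signed weights per node."""
    index = {g: i for i, g in enumerate(truth.gene_ids)}
    parents: list[list[tuple[int, float]]] = [[] for _ in truth.gene_ids]
    for (a, b), w in sorted(weights.items()):
        i, j = index[a], index[b]
        child, parent = (i, j) if i > j else (j, i)
        parents[child].append((parent, w))
    return parents


def simulate_expression(
    truth: TrueNetwork, config: SimulationConfig, weights: dict | None = None
) -> ExpressionMatrix:
    """Conditional-normal expression on ``truth`` (see module docstring).

    Deterministic for a fixed ``config.seed``.  ``weights`` (from
    :func:`assign_edge_weights`) may be supplied to share one regulatory
    parameterisation across several simulated datasets; by default they
    are drawn from the same seeded stream as the noise.
    """
    if truth.n_genes == 0:
        raise ValidationError("truth has no genes")
    if config.n_samples < 2:
        raise ValidationError("need n_samples >= 2")
    rng = np.random.default_rng(config.seed)
    if weights is None:
        weights = _draw_weights(truth, config, rng)
    missing = truth.edges - set(weights)
    if missing:
        raise ValidationError(f"weights missing for edges: {sorted(missing)[:5]}")
    parents = _dag_parents(truth, weights)
    p, n = truth.n_genes, config.n_samples
    latent = np.empty((p, n))
    innovations = rng.standard_normal((p, n))
    for i in range(p):
        latent[i] = innovations[i]
        for j, w in parents[i]:
            latent[i] += w * latent[j]
    observed = latent + config.noise_sd * rng.standard_normal((p, n))
    width = max(3, len(str(n)))
    samples = tuple(f"S{k + 1:0{width}d}" for k in range(n))
    return ExpressionMatrix(truth.gene_ids, samples, observed)


def grid_seeds(master_seed: int, count: int) -> np.ndarray:
    """Derive ``count`` independent 31-bit seeds from one master seed."""
    return np.random.default_rng(master_seed).integers(0, 2**31 - 1, size=count)


def generate_grid(
    sizes=DEFAULT_SIZES,
    sample_sizes=DEFAULT_SAMPLE_SIZES,
    noise_levels=DEFAULT_NOISE_LEVELS,
    seed: int = 0,
) -> Iterator[tuple[SimulationConfig, TrueNetwork, ExpressionMatrix]]:
    """Yield one ``(config, truth, expression)`` dataset per factor
    combination of the study grid (5 x 6 x 4 = 120 at the defaults)."""
    sizes = list(sizes)
    sample_sizes = list(sample_sizes)
    noise_levels = list(noise_levels)
    if not sizes or not sample_sizes or not noise_levels:
        raise ValidationError("all factor lists must be non-empty")
    n_cells = len(sizes) * len(sample_sizes) * len(noise_levels)
    seeds = grid_seeds(seed, n_cells)
    k = 0
    for genes, edges in sizes:
        for n in sample_sizes:
            for sd in noise_levels:
                cfg = SimulationConfig(
                    n_genes=genes, n_edges=edges, n_samples=n,
                    noise_sd=sd, seed=int(seeds[k]),
                )
                truth = generate_scale_free(cfg)
                expr = simulate_expression(truth, cfg)
                yield cfg, truth, expr
                k += 1
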