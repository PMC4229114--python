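"""End-to-end simulation-study drivers.

Each driver simulates a gold standard and expression data, runs one of
the ensemble pipelines, scores everything against the truth and returns
a flat dict of named AUC/AUPR values.  They are the programmatic form of
the package's three headline experiments:

``fig1_bootstrap``   one dataset, single SPACE vs bootstrapped SPACE;
``fig4_methods``     one dataset, each method vs the cross-method ensemble;
``fig5_datasets``    three datasets of increasing noise, per-dataset
                     ensembles vs naive sample pooling vs cross-dataset
                     aggregation.

All randomness derives from the single ``seed`` argument.
"""

from __future__ import annotations

import numpy as np

from .ensemble import EnsembleConfig, bootstrap_ena, multidataset_ena, multimethod_ena, pool_expressions
from .evaluation import evaluate
from .reconstruction import reconstruct
from .simulation import (
    SimulationConfig,
    assign_edge_weights,
    generate_scale_free,
    simulate_expression,
)

__all__ = ["fig1_bootstrap", "fig4_methods", "fig5_datasets", "TEMPLATES", "run_experiment"]


def _derive(seed: int, k: int) -> list[int]:
    return [int(s) for s in np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)]


def fig1_bootstrap(
    seed: int = 0,
    n_genes: int = 231,
    n_edges: int = 311,
    n_samples: int = 20,
    noise_sd: float = 0.25,
    B: int = 100,
    sample_fraction: float = 0.70,
    workers: int = 1,
) -> dict:
    """Single-method bootstrap experiment: plain SPACE vs bootstrap-ENA
    SPACE on one simulated dataset."""
    topo_seed, data_seed, boot_seed = _derive(seed, 3)
    cfg = SimulationConfig(n_genes, n_edges, n_samples, noise_sd, seed=topo_seed)
    truth = generate_scale_free(cfg)
    expr = simulate_expression(truth, SimulationConfig(
        n_genes, n_edges, n_samples, noise_sd, seed=data_seed))

    single = reconstruct(expr, "space")
    ens_cfg = EnsembleConfig(B=B, sample_fraction=sample_fraction, seed=boot_seed, workers=workers)
    boosted = bootstrap_ena(expr, "space", ens_cfg)

    ev_single = evaluate(single, truth)
    ev_boot = evaluate(boosted, truth)
    return {
        "auc_single": ev_single.auc,
        "auc_bootstrap": ev_boot.auc,
        "aupr_single": ev_single.aupr,
        "aupr_bootstrap": ev_boot.aupr,
        "n_genes": n_genes,
        "n_samples": n_samples,
    }


def fig4_methods(
    seed: int = 0,
    n_genes: int = 83,
    n_edges: int = 114,
    n_samples: int = 200,
    noise_sd: float = 0.25,
    B: int = 1,
    workers: int = 1,
) -> dict:
    """Cross-method experiment: each reconstruction method alone vs the
    three-method ensemble on one simulated dataset."""
    topo_seed, data_seed, ens_seed = _derive(seed, 3)
    cfg = SimulationConfig(n_genes, n_edges, n_samples, noise_sd, seed=topo_seed)
    truth = generate_scale_free(cfg)
    expr = simulate_expression(truth, SimulationConfig(
        n_genes, n_edges, n_samples, noise_sd, seed=data_seed))

    ens_cfg = EnsembleConfig(B=B, seed=ens_seed, workers=workers)
    out: dict = {"n_genes": n_genes, "n_samples": n_samples}
    for method in ens_cfg.methods:
        out[f"auc_{method}"] = evaluate(reconstruct(expr, method), truth).auc
    ensemble = multimethod_ena(expr, ens_cfg)
    out["auc_ensemble"] = evaluate(ensemble, truth).auc
    return out


def fig5_datasets(
    seed: int = 0,
    n_genes: int = 231,
    n_edges: int = 311,
    n_samples: int = 200,
    noise_levels: tuple = (0.25, 1.0, 2.0),
    B: int = 20,
    workers: int = 1,
) -> dict:
    """Cross-dataset experiment: three datasets of one truth at
    increasing noise; per-dataset ensembles, naive pooling, and
    cross-dataset aggregation."""
    seeds = _derive(seed, 2 + len(noise_levels))
    topo_seed, ens_seed, data_seeds = seeds[0], seeds[1], seeds[2:]
    cfg = SimulationConfig(n_genes, n_edges, n_samples, noise_levels[0], seed=topo_seed)
    truth = generate_scale_free(cfg)
    weights = assign_edge_weights(truth, cfg)  # one system, three noisy studies
    exprs = [
        simulate_expression(truth, SimulationConfig(
            n_genes, n_edges, n_samples, sd, seed=ds), weights=weights)
        for sd, ds in zip(noise_levels, data_seeds)
    ]

    ens_cfg = EnsembleConfig(B=B, seed=ens_seed, workers=workers)
    out: dict = {"n_genes": n_genes, "n_samples": n_samples}
    per_dataset = []
    for di, (sd, expr) in enumerate(zip(noise_levels, exprs)):
        net = multimethod_ena(expr, ens_cfg, _stream=(di,))
        per_dataset.append(net)
        out[f"auc_dataset_noise_{sd:g}"] = evaluate(net, truth).auc
    pooled_net = multimethod_ena(pool_expressions(exprs), ens_cfg, _stream=(len(exprs),))
    out["auc_pooled"] = evaluate(pooled_net, truth).auc
    ena_net = multidataset_ena(exprs, ens_cfg)
    out["auc_ena"] = evaluate(ena_net, truth).auc
    return out


TEMPLATES = {
    "fig1_bootstrap": fig1_bootstrap,
    "fig4_methods": fig4_methods,
    "fig5_datasets": fig5_datasets,
}


def run_experiment(template: str, seed: int = 0, **overrides) -> dict:
    """Run one experiment template with factor overrides."""
    if template not in TEMPLATES:
        raise ValueError(f"unknown template {template!r}; choose from {sorted(TEMPLATES)}")
    return TEMPLATES[template](seed=seed, **overrides)
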