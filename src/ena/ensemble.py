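"""Ensemble drivers: bootstrap, cross-method and cross-dataset
aggregation.

Three ways to build a consensus network with the rank-product
aggregator:

1. ``bootstrap_ena`` — reconstruct a network on each of B random 70%
   subsamples of one dataset (one method) and aggregate the B networks.
   Consistently recovered edges rise to the top; edges driven by a few
   influential samples sink.
2. ``multimethod_ena`` — run several reconstruction methods (each
   optionally bootstrapped) on one dataset and aggregate across methods,
   rewarding edges that rank highly under different modelling
   assumptions.
3. ``multidataset_ena`` — build a per-dataset ensemble network for each
   of several datasets sharing (part of) a gene set, then aggregate
   across datasets.  Because only ranks cross dataset boundaries, the
   datasets may live on entirely different scales or platforms.

Replicates draw their randomness from streams keyed by (master seed,
replicate index), so results are bit-identical for any ``workers``
setting and any completion order.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from joblib import Parallel, delayed

from .aggregation import AggregatedNetwork, rank_product_aggregate
from .netio import ExpressionMatrix, ValidationError, WeightedNetwork
from .reconstruction import METHODS, ReconstructionConfig, reconstruct

__all__ = ["EnsembleConfig", "bootstrap_ena", "multimethod_ena", "multidataset_ena", "pool_expressions"]

logger = logging.getLogger("ena.ensemble")

#: hard-error threshold on the fraction of failed bootstrap replicates
MAX_FAILURE_FRACTION = 0.20


@dataclass(frozen=True)
class EnsembleConfig:
    """Settings shared by the ensemble drivers.

    ``B`` bootstrap replicates of ``sample_fraction`` of the samples
    (drawn without replacement by default — set ``replace=True`` for
    textbook with-replacement resampling); ``methods`` for the
    cross-method ensemble; ``workers`` bounds process parallelism
    without affecting results.
    """

    B: int = 100
    sample_fraction: float = 0.70
    methods: tuple[str, ...] = ("space", "shrinkage_pcor", "softcor")
    seed: int = 0
    workers: int = 1
    replace: bool = False
    flat: bool = False  # cross-dataset: aggregate all D*M networks in one step
    recon: ReconstructionConfig | None = None

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValidationError("B must be >= 1")
        if not (0 < self.sample_fraction <= 1):
            raise ValidationError("sample_fraction must be in (0, 1]")
        if not self.methods:
            raise ValidationError("methods must be non-empty")
        unknown = [m for m in self.methods if m not in METHODS]
        if unknown:
            raise ValidationError(f"unknown methods: {unknown}")
        if self.workers < 1:
            raise ValidationError("workers must be >= 1")


def _replicate_indices(n: int, config: EnsembleConfig, stream_key) -> np.ndarray:
    rng = np.random.default_rng(stream_key)
    size = int(np.ceil(config.sample_fraction * n))
    return np.sort(rng.choice(n, size=size, replace=config.replace))


def _one_replicate(expr, method, recon, n, config, stream_key):
    idx = _replicate_indices(n, config, stream_key)
    try:
        return reconstruct(expr.subset_samples(idx), method, recon)
    except Exception as exc:  # noqa: BLE001 - replicate failures are survivable
        return exc


def bootstrap_ena(
    expr: ExpressionMatrix,
    method: str,
    config: EnsembleConfig | None = None,
    _stream: tuple = (),
) -> AggregatedNetwork:
    """Aggregate ``config.B`` subsample reconstructions of one dataset.

    Each replicate b reconstructs on ceil(sample_fraction * n) samples
    drawn without replacement from a stream keyed by
    (seed, *extra, b).  With ``B=1, sample_fraction=1.0`` the ranking
    reduces to that of a single plain reconstruction.
    """
    config = config or EnsembleConfig()
    n = expr.n_samples
    if int(np.ceil(config.sample_fraction * n)) < 3:
        raise ValidationError("each replicate needs at least 3 samples")
    keys = [(config.seed, *_stream, b) for b in range(config.B)]
    run = delayed(_one_replicate)
    if config.workers == 1 or config.B == 1:
        results = [_one_replicate(expr, method, config.recon, n, config, k) for k in keys]
    else:
        results = Parallel(n_jobs=config.workers)(
            run(expr, method, config.recon, n, config, k) for k in keys
        )
    nets, names = [], []
    for b, res in enumerate(results):
        if isinstance(res, Exception):
            warnings.warn(
                f"bootstrap replicate {b} ({method}) failed: {res}", RuntimeWarning, stacklevel=2
            )
            continue
        nets.append(res)
        names.append(f"{method}/boot{b}")
    failed = config.B - len(nets)
    if failed > MAX_FAILURE_FRACTION * config.B:
        raise ValidationError(
            f"{failed}/{config.B} bootstrap replicates failed (> {MAX_FAILURE_FRACTION:.0%})"
        )
    logger.info("bootstrap_ena: method=%s B=%d failed=%d", method, config.B, failed)
    return rank_product_aggregate(nets, names=names)


def multimethod_ena(
    expr: ExpressionMatrix,
    config: EnsembleConfig | None = None,
    _stream: tuple = (),
) -> AggregatedNetwork:
    """Cross-method ensemble on one dataset.

    Each configured method contributes one network — its bootstrap
    ensemble when ``B > 1``, a plain full-sample reconstruction when
    ``B == 1``.  A failing method is an error: a cross-method ensemble
    is not silently reduced to fewer members.
    """
    config = config or EnsembleConfig()
    nets = []
    for mi, method in enumerate(config.methods):
        if config.B > 1:
            net = bootstrap_ena(expr, method, config, _stream=(*_stream, mi))
        else:
            net = reconstruct(expr, method, config.recon)
        nets.append(net)
    return rank_product_aggregate(nets, names=config.methods)


def _intersect_genes(exprs) -> list[str]:
    common = set(exprs[0].gene_ids)
    for e in exprs[1:]:
        common &= set(e.gene_ids)
    return [g for g in exprs[0].gene_ids if g in common]


def multidataset_ena(
    exprs: list[ExpressionMatrix],
    config: EnsembleConfig | None = None,
) -> AggregatedNetwork:
    """Cross-dataset ensemble over the common gene set.

    Restricts every dataset to the ordered intersection of gene sets
    (warning when genes are dropped), builds a per-dataset
    :func:`multimethod_ena` network, and aggregates the per-dataset
    networks.  ``config.flat=True`` instead pools every method network
    of every dataset into a single aggregation step.
    """
    config = config or EnsembleConfig()
    if len(exprs) < 2:
        raise ValidationError("need at least 2 datasets")
    common = _intersect_genes(exprs)
    if len(common) < 2:
        raise ValidationError("datasets share fewer than 2 genes")
    dropped = {g for e in exprs for g in e.gene_ids} - set(common)
    if dropped:
        warnings.warn(
            f"restricting to {len(common)} shared genes; dropped {sorted(dropped)}",
            RuntimeWarning,
            stacklevel=2,
        )
    exprs = [e.subset_genes(common) for e in exprs]
    if config.flat:
        nets, names = [], []
        for di, e in enumerate(exprs):
            for mi, method in enumerate(config.methods):
                if config.B > 1:
                    net = bootstrap_ena(e, method, config, _stream=(di, mi))
                else:
                    net = reconstruct(e, method, config.recon)
                nets.append(net)
                names.append(f"dataset{di}/{method}")
        return rank_product_aggregate(nets, names=names)
    per_dataset = [
        multimethod_ena(e, config, _stream=(di,)) for di, e in enumerate(exprs)
    ]
    return rank_product_aggregate(
        per_dataset, names=tuple(f"dataset{di}" for di in range(len(exprs)))
    )


def pool_expressions(exprs: list[ExpressionMatrix]) -> ExpressionMatrix:
    """Column-concatenate datasets over their common genes (the naive
    alternative to cross-dataset aggregation)."""
    if len(exprs) < 2:
        raise ValidationError("need at least 2 datasets to pool")
    common = _intersect_genes(exprs)
    if len(common) < 2:
        raise ValidationError("datasets share fewer than 2 genes")
    exprs = [e.subset_genes(common) for e in exprs]
    values = np.concatenate([e.values for e in exprs], axis=1)
    samples = tuple(
        f"d{di}:{s}" for di, e in enumerate(exprs) for s in e.sample_ids
    )
    return ExpressionMatrix(tuple(common), samples, values)
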