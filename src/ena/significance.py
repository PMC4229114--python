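"""Permutation significance of aggregated edges.

The rank-product aggregate is a complete weighted graph; this module
reduces it to the edges whose consistency across input networks is
unlikely under a null of no shared structure.  The null preserves each
input network's rank distribution exactly: each network's lower-triangle
rank assignment is permuted independently (equivalently, its edge labels
are shuffled) and the rank products recomputed.  Because all pairs are
exchangeable under this null, the K pairs of every permutation are
pooled into one null sample of size K * n_perm, and each observed rank
product RP gets

    p = (1 + #{null RP <= observed RP}) / (1 + K * n_perm),

followed by Benjamini-Hochberg adjustment at level ``alpha``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .aggregation import tri_ranks
from .netio import ValidationError, WeightedNetwork

__all__ = ["EdgeSignificance", "permutation_significance"]


@dataclass(frozen=True)
class EdgeSignificance:
    """Per-pair rank products, permutation p-values and BH decisions."""

    gene_ids: tuple[str, ...]
    pairs: list  # (gene_a, gene_b) in lower-triangle order
    log_rank_product: np.ndarray
    p_value: np.ndarray
    p_adjusted: np.ndarray
    significant: np.ndarray
    alpha: float
    n_perm: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_a": [a for a, _ in self.pairs],
                "gene_b": [b for _, b in self.pairs],
                "rank_product": np.exp(self.log_rank_product),
                "p_value": self.p_value,
                "p_adjusted": self.p_adjusted,
                "significant": self.significant,
            }
        )


def permutation_significance(
    nets: list[WeightedNetwork],
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    chunk: int = 64,
) -> EdgeSignificance:
    """Permutation p-values for every pair's rank product across ``nets``.

    ``n_perm`` independent label permutations per network build a pooled
    null of K * n_perm rank products (K = number of pairs).  Determinism
    is guaranteed by ``seed``.
    """
    if len(nets) < 2:
        raise ValidationError("need at least 2 networks")
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100 for usable resolution")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    ref = nets[0]
    for k, net in enumerate(nets[1:], start=1):
        if net.gene_ids != ref.gene_ids:
            raise ValidationError(f"network {k} is not on the common ordered gene set")

    log_ranks = [np.log(tri_ranks(net.tri_values())) for net in nets]
    observed = np.sum(log_ranks, axis=0)
    K = observed.size

    rng = np.random.default_rng(seed)
    null_sorted = np.empty(K * n_perm)
    pos = 0
    for start in range(0, n_perm, chunk):
        b = min(chunk, n_perm - start)
        acc = np.zeros((b, K))
        for lr in log_ranks:
            perms = rng.permuted(np.broadcast_to(lr, (b, K)), axis=1)
            acc += perms
        flat = acc.ravel()
        null_sorted[pos : pos + flat.size] = flat
        pos += flat.size
    null_sorted.sort()

    # right=True counts null values <= observed (log is monotone)
    counts = np.searchsorted(null_sorted, observed + 1e-12, side="right")
    p = (1.0 + counts) / (1.0 + K * n_perm)
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    p_adj = np.minimum(np.maximum(p_adj, p), 1.0)

    i, j = np.tril_indices(ref.n_genes, k=-1)
    pairs = [(ref.gene_ids[b_], ref.gene_ids[a_]) for a_, b_ in zip(i, j)]
    return EdgeSignificance(
        gene_ids=ref.gene_ids,
        pairs=pairs,
        log_rank_product=observed,
        p_value=p,
        p_adjusted=p_adj,
        significant=reject,
        alpha=alpha,
        n_perm=n_perm,
    )
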