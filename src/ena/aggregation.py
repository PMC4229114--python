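"""Inverse-rank-product aggregation of weighted networks.

The aggregation scheme is non-parametric: each input network's edge
scores are reduced to confidence ranks over the N(N-1)/2 unordered gene
pairs (rank 1 = most confident, i.e. largest |score|; ties get the
midrank so the rank sum is preserved exactly), and an edge's aggregated
statistic is the product of its ranks across the G input networks.  A
pair that ranks highly in every network gets a small rank product; a
pair that ranks highly in only one network does not.  Because only ranks
enter, networks whose scores live on wildly different scales — different
reconstruction algorithms, different datasets, different platforms —
can be merged without any calibration.

The aggregated network's score is the inverse rank product on the
geometric-mean scale, ``s_ij = (prod_g r_g(i,j)) ** (-1/G)``: monotone
decreasing in the rank product, bounded in (0, 1], equal to 1 exactly
when the pair ranked first everywhere, and comparable across ensembles
of different sizes G.  Products are accumulated in log space so large
ensembles cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .netio import ValidationError, WeightedNetwork

__all__ = ["RankMatrix", "AggregatedNetwork", "edge_ranks", "rank_product_aggregate"]


@dataclass(frozen=True)
class RankMatrix:
    """Symmetric matrix of per-pair confidence ranks (diagonal unused)."""

    gene_ids: tuple[str, ...]
    ranks: np.ndarray

    def tri_values(self) -> np.ndarray:
        i, j = np.tril_indices(len(self.gene_ids), k=-1)
        return self.ranks[i, j]


@dataclass(frozen=True)
class AggregatedNetwork(WeightedNetwork):
    """A :class:`WeightedNetwork` produced by rank-product aggregation,
    carrying the identifiers of the networks it was built from."""

    provenance: tuple[str, ...] = ()


def tri_ranks(scores_tri: np.ndarray) -> np.ndarray:
    """Midrank confidence ranks of a vector of pair scores (rank 1 =
    largest absolute score)."""
    return rankdata(-np.abs(scores_tri), method="average")


def edge_ranks(net: WeightedNetwork) -> RankMatrix:
    """Rank all unordered pairs of ``net`` by |score|, descending.

    Ties — including the block of exact zeros that sparse reconstructions
    produce — share the midrank of the positions they span, so the ranks
    always sum to K(K+1)/2 with K = N(N-1)/2.
    """
    p = net.n_genes
    if p < 2:
        raise ValidationError("need at least 2 genes to rank edges")
    r = tri_ranks(net.tri_values())
    full = np.zeros((p, p))
    i, j = np.tril_indices(p, k=-1)
    full[i, j] = r
    full[j, i] = r
    return RankMatrix(net.gene_ids, full)


def rank_product_aggregate(nets, names=None) -> AggregatedNetwork:
    """Aggregate networks over an identical gene set by the inverse rank
    product.

    Parameters
    ----------
    nets : sequence of WeightedNetwork
        Input networks.  All must share the same gene *set*; networks in
        a different gene order are re-indexed to the first network's
        order.  Callers integrating datasets with different gene sets
        must intersect them first.
    names : sequence of str, optional
        Provenance identifiers stored on the result (defaults to
        ``net0, net1, ...``).
    """
    nets = list(nets)
    if not nets:
        raise ValidationError("need at least one network to aggregate")
    ref = nets[0]
    ref_set = set(ref.gene_ids)
    aligned = [ref]
    for k, net in enumerate(nets[1:], start=1):
        if set(net.gene_ids) != ref_set:
            diff = sorted(set(net.gene_ids) ^ ref_set)
            raise ValidationError(
                f"network {k} gene set differs from network 0; symmetric difference: {diff}"
            )
        if net.gene_ids != ref.gene_ids:
            index = {g: i for i, g in enumerate(net.gene_ids)}
            perm = [index[g] for g in ref.gene_ids]
            net = WeightedNetwork(ref.gene_ids, net.scores[np.ix_(perm, perm)])
        aligned.append(net)
    if names is None:
        names = tuple(f"net{k}" for k in range(len(aligned)))
    else:
        names = tuple(names)
        if len(names) != len(aligned):
            raise ValidationError("names must match the number of networks")

    log_rp = np.zeros(ref.n_pairs)
    for net in aligned:
        log_rp += np.log(tri_ranks(net.tri_values()))
    s_tri = np.exp(-log_rp / len(aligned))

    p = ref.n_genes
    scores = np.zeros((p, p))
    i, j = np.tril_indices(p, k=-1)
    scores[i, j] = s_tri
    scores[j, i] = s_tri
    return AggregatedNetwork(ref.gene_ids, scores, provenance=names)
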