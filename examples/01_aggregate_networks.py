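"""Rank-product aggregation of two hand-made networks.

Two 3-gene networks agree that A-B is the strongest pair but disagree on
the rest.  The aggregate scores each pair by the inverse rank product
s = (r1 * r2)^(-1/2): 1.0 means "ranked first everywhere"; ties in the
product show up as equal scores.
"""

import numpy as np

from ena import WeightedNetwork, rank_product_aggregate

net1 = WeightedNetwork(("A", "B", "C"),
                       [[0.0, 0.9, 0.5], [0.9, 0.0, 0.1], [0.5, 0.1, 0.0]])
net2 = WeightedNetwork(("A", "B", "C"),
                       [[0.0, 8.0, 1.0], [8.0, 0.0, 5.0], [1.0, 5.0, 0.0]])

agg = rank_product_aggregate([net1, net2], names=("corr-method", "pcor-method"))
print("inputs:", ", ".join(agg.provenance))
i, j = np.tril_indices(3, k=-1)
for a, b in zip(i, j):
    pair = f"{agg.gene_ids[b]}-{agg.gene_ids[a]}"
    print(f"  {pair}: aggregated score {agg.scores[a, b]:.4f}")
# A-B ranks 1 in both networks -> score 1.0; A-C and B-C each rank
# 2 in one network and 3 in the other -> equal scores (6)^(-1/2) = 0.4082.
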