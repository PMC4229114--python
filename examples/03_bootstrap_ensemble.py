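"""Bootstrap aggregation of a sparse partial-correlation network.

With few samples a single SPACE fit is unstable; reconstructing on
B random 70% subsamples and aggregating by rank product rewards the
edges recovered consistently.  Printed: AUC of the single fit vs the
bootstrap ensemble on the same data.
"""

from ena import (
    EnsembleConfig,
    SimulationConfig,
    bootstrap_ena,
    evaluate,
    generate_scale_free,
    reconstruct,
    simulate_expression,
)

cfg = SimulationConfig(n_genes=83, n_edges=114, n_samples=30, noise_sd=0.25, seed=5)
truth = generate_scale_free(cfg)
expr = simulate_expression(truth, cfg)

single = reconstruct(expr, "space")
boot = bootstrap_ena(expr, "space", EnsembleConfig(B=50, sample_fraction=0.7, seed=1))

print(f"{expr.n_genes} genes, {expr.n_samples} samples, B=50 bootstrap replicates")
print(f"  single SPACE fit  AUC {evaluate(single, truth).auc:.3f}")
print(f"  bootstrap ENA     AUC {evaluate(boot, truth).auc:.3f}")
# The ensemble AUC is usually several points higher: subsample-stable
# edges dominate the top of the aggregated ranking.
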