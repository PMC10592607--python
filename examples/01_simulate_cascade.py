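"""Simulate a three-layer molecular cascade with known ground truth.

Builds a genotype panel with block LD, lays 30 genes on it with a 25%
translational and 20% post-translational attenuation of their eQTL
effects, emits read counts (mRNA, ribosome occupancy) and log2 protein
abundances, and prints what the ground truth looks like.
"""
import numpy as np

from cascadeqtl import simulate

g = simulate.simulate_genotypes(
    n_samples=185, n_variants=300, ld_block_size=10, ld_rho=0.4, seed=1
)
truth = simulate.make_cascade_truth(
    g, n_genes=30, seed=2, eqtl_effect=0.6, lambda_r=0.75, lambda_p=0.8,
    factor_sd=0.3, n_causal_outcome=2,
)
layers = simulate.simulate_cascade(g, truth, seed=3)
gwas = simulate.simulate_gwas(g, truth, outcome_h2=0.3, n_gwas=5000, seed=4)

print(f"genotypes: {g.n_samples} samples x {g.n_variants} variants, "
      f"mean MAF {g.maf.mean():.2f}")
for lay, m in layers.items():
    print(f"{lay:8s} {m.stage:12s} matrix {m.values.shape}")
print("\nfirst genes of the ground truth:")
cols = ["gene_id", "causal_variant", "eqtl_effect", "lambda_r", "lambda_p",
        "causal_for_outcome"]
print(truth.genes[cols].head(5).to_string(index=False))
print(f"\nGWAS: {len(gwas.table)} variants, "
      f"{int((gwas.table['pvalue'] < 5e-8).sum())} genome-wide-significant hits")
# The per-allele effect on ribosome occupancy is lambda_r * beta and on
# protein lambda_p * lambda_r * beta: the printed lambdas are what the
# attenuation analysis should recover from data.
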