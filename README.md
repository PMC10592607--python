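# cascadeqtl

Genetic regulation of gene expression across the central-dogma cascade —
from transcript to ribosome occupancy to protein — and its connection to
complex-trait risk.

Bulk multi-omics cohorts (RNA-seq, ribo-seq, quantitative mass spec on
the same individuals, plus genotypes) make it possible to ask not just
*whether* a common variant regulates a gene, but *how far down* the
cascade its effect travels: many eQTL effects are attenuated
translationally or post-translationally and never reach the proteome,
while other genes carry genetic regulation that exists only at one layer.
`cascadeqtl` implements the full analysis tool-chain for this question,
exercised end to end on a synthetic cascade generator with complete
ground truth:

* **Cis-QTL mapping** per layer: permutation-calibrated empirical
  p-values via the beta approximation of the minimum-p null, Storey
  q-value FDR.
* **Attenuation analyses**: the π1 replication matrix between QTL types
  (with its directional asymmetry), direction-aware replication curves,
  and per-allele |log2 effect| profiles of an external eQTL panel whose
  layer-mean ratios estimate the attenuation parameters λ_r and λ_p.
* **Omics-specificity**: per-gene elastic-net prediction models, a
  conditional model after regressing out the other layers' imputed
  expression, and the R_c² statistic — the squared correlation between
  the two models' imputed expression — calibrated by a permutation null;
  genes classify as shared (FDR < 0.1, R_c² < 0.5) or omics-specific
  (FDR > 0.1, R_c² > 0.9).
* **Colocalization** of QTL and GWAS signals: Wakefield ABFs under the
  five-hypothesis enumeration, PP4 ≥ 0.7 reporting.
* **TWAS**: summary-statistic gene association
  z = Σ w_i (σ_i/σ_g) z_i, Cauchy omnibus over protein isoforms,
  Bonferroni FWER.
* **Mendelian randomization**: two-sample IVW with MR-Egger pleiotropy
  screening (LD-clumped instruments, allele harmonization), and
  one-sample 2SLS between adjacent layers combined into
  both-/single-/none-passed cascade verdicts for risk genes.

The generative model, every estimator's assumptions and all numerical
choices are documented in [`docs/methods.md`](docs/methods.md).

## Worked example

Recover the attenuation parameters of a simulated cascade
(`examples/03_attenuation.py`; all examples in `examples/` run in under
a few minutes):

```python
from cascadeqtl import attenuation, preprocess, simulate

g, truth, raw, panel = simulate.attenuation_study(n_genes=200, seed=7)
log2 = {lay: (preprocess.counts_to_log_cpm(m) if m.stage == "raw_counts" else m)
        for lay, m in raw.items()}
profile = attenuation.external_effect_profile(panel, log2, g)
print(profile.table)
print(profile.ratio("ribo", "mrna"), profile.ratio("protein", "ribo"))
```

Output (from `python examples/03_attenuation.py`):

```
effect-size profile (external panel of strong eQTLs):
  layer  mean_abs_effect  ci_low  ci_high  n_snps
   mrna           0.7648  0.7127   0.8169      73
   ribo           0.5721  0.5238   0.6204      73
protein           0.4875  0.4357   0.5393      73

ribo/mRNA ratio  0.748  (simulated lambda_r = 0.75)
protein/ribo ratio 0.852  (simulated lambda_p = 0.80)

pi1 replication matrix (rows discover, columns replicate):
          mrna   ribo  protein
mrna     1.000  0.439    0.285
ribo     0.940  1.000    0.829
protein  0.975  0.975    1.000
```

The mean |per-allele log2 effect| of the same external eQTL panel falls
monotonically down the cascade, and the layer-mean ratios recover the
simulated translational (λ_r = 0.75) and post-translational (λ_p = 0.8)
attenuation (this 200-gene run estimates λ_p with ±0.05-ish noise; the
500-gene acceptance run is tighter). The replication matrix shows the
second, cutoff-free signature of attenuation: mRNA discoveries replicate
poorly downstream (π1 0.44 at ribo, 0.29 at protein) while downstream
discoveries replicate almost fully at the transcript level (π1 ≥ 0.94).

A full synthetic pipeline run (simulate → preprocess → QTL map →
attenuation → specificity → coloc → TWAS → MR, with a checksummed
manifest) is one call or one command:

```bash
cascadeqtl run-all --seed 7 --out-dir run/
cascadeqtl simulate --n-genes 50 --out-dir sim/       # inputs as VCF/TSV
cascadeqtl map-qtl --layer mrna --vcf sim/genotypes.vcf ...
```

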