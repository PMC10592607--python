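"""Synthetic genotype / multi-omics cascade / GWAS generator with ground truth.

The generative model is a three-layer molecular cascade.  For gene g with
cis dosage G (alt-allele count), hidden confounders F (n x K) and
independent noise eps:

    mRNA latent     M = beta * G            + F @ l_m + eps_m
    ribo latent     R = (lambda_r*beta + gamma_r) * G + F @ l_r + eps_r
    protein latent  P = (lambda_p*(lambda_r*beta + gamma_r) + gamma_p) * G
                                            + F @ l_p + eps_p

lambda_r and lambda_p in [0, 1] are the translational and
post-translational attenuation of the transcriptional effect; gamma_r and
gamma_p are genetic effects arising only at the downstream layer
(omics-specific QTLs).  mRNA and ribo are emitted as negative-binomial
counts whose log-mean equals the latent predictor plus a gene baseline, so
log-CPM recovers the linear signal; protein is emitted directly on the log
scale.  A GWAS outcome is simulated on an independent cohort as a
continuous liability driven by the protein-layer genetic components of
causal genes plus optional horizontal-pleiotropy effects.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CascadeTruth, GWASSummary, OmicsMatrix, VariantTable

_BASES = np.array(["A", "C", "G", "T"])


def _draw_dosages(rng, n_samples, maf, ld_block_size, ld_rho):
    """Latent Gaussian copula, block-equicorrelated, thresholded to HWE."""
    n_variants = maf.size
    z = rng.standard_normal((n_samples, n_variants))
    if ld_rho > 0 and ld_block_size > 1:
        n_blocks = int(np.ceil(n_variants / ld_block_size))
        shared = rng.standard_normal((n_samples, n_blocks))
        block_of = np.arange(n_variants) // ld_block_size
        z = np.sqrt(ld_rho) * shared[:, block_of] + np.sqrt(1.0 - ld_rho) * z
    # Hardy-Weinberg genotype frequencies for alt frequency p = maf
    p = maf
    c0 = stats.norm.ppf((1 - p) ** 2)
    c1 = stats.norm.ppf((1 - p) ** 2 + 2 * p * (1 - p))
    return (z > c0[None, :]).astype(np.int8) + (z > c1[None, :]).astype(np.int8)


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    maf_low: float = 0.05,
    maf_high: float = 0.5,
    ld_block_size: int = 10,
    ld_rho: float = 0.0,
    seed: int = 0,
    chrom: str = "1",
    spacing_bp: int = 2000,
    block_gap_bp: int = 3_000_000,
) -> VariantTable:
    """Simulate biallelic common-variant dosages with block LD.

    Each LD block shares a latent Gaussian factor with pairwise correlation
    ``ld_rho``; latent values are thresholded at the Hardy-Weinberg genotype
    frequencies of each variant's declared MAF.  Positions are strictly
    increasing: variants within a block sit ``spacing_bp`` apart and
    consecutive blocks start ``block_gap_bp`` apart, so a gene laid out on
    one block has a +/- 1 Mb cis window that cannot reach a neighbouring
    block.
    """
    if n_samples < 30:
        raise ValueError("n_samples < 30: downstream regressions are unidentifiable")
    if not (0.05 <= maf_low <= maf_high <= 0.5):
        raise ValueError("require 0.05 <= maf_low <= maf_high <= 0.5")
    if not (0.0 <= ld_rho < 1.0):
        raise ValueError("ld_rho must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(maf_low, maf_high, size=n_variants)
    dosage = _draw_dosages(rng, n_samples, maf, ld_block_size, ld_rho)
    # resample the rare monomorphic column (possible at small n)
    for _ in range(20):
        mono = np.flatnonzero(dosage.min(axis=0) == dosage.max(axis=0))
        if mono.size == 0:
            break
        dosage[:, mono] = _draw_dosages(rng, n_samples, maf[mono], 1, 0.0)
    ref_idx = rng.integers(0, 4, size=n_variants)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_variants)) % 4
    idx = np.arange(n_variants)
    block_of = idx // ld_block_size
    pos = block_of * block_gap_bp + (idx - block_of * ld_block_size) * spacing_bp + 1
    return VariantTable(
        variant_id=np.array([f"rs{i + 1}" for i in range(n_variants)]),
        chrom=np.full(n_variants, chrom, dtype=object),
        pos=pos,
        ref_allele=_BASES[ref_idx],
        alt_allele=_BASES[alt_idx],
        maf=maf,
        dosage=dosage.astype(float),
        sample_ids=[f"S{i + 1}" for i in range(n_samples)],
        ld_block_size=ld_block_size,
        ld_rho=ld_rho,
    )


def make_cascade_truth(
    genotypes: VariantTable,
    n_genes: int,
    seed: int = 0,
    eqtl_effect: float | np.ndarray = 0.5,
    eqtl_fraction: float = 1.0,
    lambda_r: float | np.ndarray = 1.0,
    lambda_p: float | np.ndarray = 1.0,
    gamma_r: float | np.ndarray = 0.0,
    gamma_p: float | np.ndarray = 0.0,
    noise_sd: float | dict = 1.0,
    factor_sd: float = 0.0,
    n_hidden_factors: int = 5,
    n_causal_outcome: int = 0,
    pleiotropy: dict | None = None,
    random_sign: bool = True,
    separate_specific_variant: bool = False,
) -> CascadeTruth:
    """Lay out genes along the genotype panel and fix their cascade parameters.

    Genes are assigned contiguous runs of whole LD blocks (so each gene has
    >= 1 cis variant by construction and no gene's +/- 1 Mb cis window
    reaches another gene's variants); one variant per gene is the causal
    cis variant.  Scalar parameters are broadcast to all genes; arrays give
    per-gene values.  ``eqtl_fraction`` randomly zeroes the transcriptional
    effect of the remaining genes (null genes).

    Layer-specific effects gamma_r / gamma_p act at the gene's
    ``specific_variant``: the eQTL variant itself by default, or — with
    ``separate_specific_variant`` — a variant in a different LD block of
    the gene's window, modelling an omics-specific QTL that is genetically
    independent of the gene's eQTL.
    """
    rng = np.random.default_rng(seed)
    bs = genotypes.ld_block_size
    n_blocks = genotypes.n_variants // bs
    if n_blocks < n_genes:
        raise ValueError("need at least one whole LD block per gene")
    blocks_per_gene = n_blocks // n_genes
    per_gene = blocks_per_gene * bs
    starts = np.arange(n_genes) * per_gene
    causal = starts + rng.integers(0, per_gene, size=n_genes)
    if separate_specific_variant:
        if blocks_per_gene < 2:
            raise ValueError("separate specific variants need >= 2 LD blocks per gene")
        causal_block = (causal - starts) // bs
        other_block = (causal_block + 1 + rng.integers(0, blocks_per_gene - 1, n_genes)) % blocks_per_gene
        specific = starts + other_block * bs + rng.integers(0, bs, size=n_genes)
    else:
        specific = causal

    def bcast(x):
        return np.broadcast_to(np.asarray(x, float), (n_genes,)).copy()

    beta = bcast(eqtl_effect)
    if eqtl_fraction < 1.0:
        null = rng.random(n_genes) >= eqtl_fraction
        beta[null] = 0.0
    if random_sign:
        beta = beta * rng.choice([-1.0, 1.0], size=n_genes)

    pos = genotypes.pos
    # gene body spans its variant run; +/- 1 Mb window stays inside it
    g_start = pos[starts]
    g_end = pos[starts + per_gene - 1]
    genes = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1}" for i in range(n_genes)],
            "chrom": genotypes.chrom[starts],
            "start": g_start,
            "end": g_end,
            "strand": "+",
            "causal_variant": genotypes.variant_id[causal],
            "specific_variant": genotypes.variant_id[specific],
            "eqtl_effect": beta,
            "lambda_r": bcast(lambda_r),
            "lambda_p": bcast(lambda_p),
            "gamma_r": bcast(gamma_r),
            "gamma_p": bcast(gamma_p),
            "noise_sd_mrna": noise_sd.get("mrna", 1.0) if isinstance(noise_sd, dict) else noise_sd,
            "noise_sd_ribo": noise_sd.get("ribo", 1.0) if isinstance(noise_sd, dict) else noise_sd,
            "noise_sd_protein": noise_sd.get("protein", 1.0) if isinstance(noise_sd, dict) else noise_sd,
            "causal_for_outcome": False,
        }
    )
    if n_causal_outcome > 0:
        chosen = rng.choice(n_genes, size=n_causal_outcome, replace=False)
        genes.loc[chosen, "causal_for_outcome"] = True
    loadings = {
        layer: rng.normal(0.0, factor_sd, size=(n_hidden_factors, n_genes))
        for layer in ("mrna", "ribo", "protein")
    }
    return CascadeTruth(
        genes=genes,
        pleiotropy=dict(pleiotropy or {}),
        factor_loadings=loadings,
        n_hidden_factors=n_hidden_factors,
    )


def _latent_layers(genotypes, truth, rng):
    """Per-layer latent (log-scale) signal matrices, samples x genes."""
    g = truth.genes
    Gc = genotypes.dosage[:, genotypes.index_of(g["causal_variant"])]
    Gs = genotypes.dosage[:, genotypes.index_of(truth.specific_variants())]
    F = rng.standard_normal((genotypes.n_samples, truth.n_hidden_factors))
    out = {}
    for layer in ("mrna", "ribo", "protein"):
        a, b = truth.layer_effect_components(layer)
        noise = rng.standard_normal(Gc.shape) * g[f"noise_sd_{layer}"].to_numpy(float)
        out[layer] = Gc * a + Gs * b + F @ truth.factor_loadings[layer] + noise
    return out, F


def simulate_cascade(
    genotypes: VariantTable,
    truth: CascadeTruth,
    seed: int = 0,
    nb_dispersion: float = 0.1,
    count_baseline_log2: float = 7.0,
    protein_baseline: float = 6.0,
) -> dict[str, OmicsMatrix]:
    """Emit the three omics layers from the cascade latent model.

    All layers share a log2 convention: mRNA and ribo are
    negative-binomial counts with log2-mean equal to
    ``count_baseline_log2`` plus the latent predictor (so the per-allele
    slope on log2-CPM equals the latent genetic effect; dispersion
    ``nb_dispersion``), and protein is the latent predictor as a log2
    abundance plus ``protein_baseline``.
    """
    rng = np.random.default_rng(seed)
    latent, _ = _latent_layers(genotypes, truth, rng)
    gene_ids = truth.gene_ids
    samples = genotypes.sample_ids
    layers = {}
    for layer in ("mrna", "ribo"):
        mu = np.exp2(count_baseline_log2 + latent[layer])
        if nb_dispersion > 0:
            # NB as gamma-Poisson: shape 1/dispersion
            shape = 1.0 / nb_dispersion
            mu = mu * rng.gamma(shape, 1.0 / shape, size=mu.shape)
        counts = rng.poisson(mu).astype(float)
        layers[layer] = OmicsMatrix(
            layer=layer,
            stage="raw_counts",
            values=pd.DataFrame(counts, index=samples, columns=gene_ids),
        )
    layers["protein"] = OmicsMatrix(
        layer="protein",
        stage="log_cpm",  # already log-scale abundances
        values=pd.DataFrame(
            protein_baseline + latent["protein"], index=samples, columns=gene_ids
        ),
    )
    return layers


def _outcome_genetic_component(truth, genotypes, dosage, n):
    """Liability genetic part: causal genes' protein-layer genetic
    components (at both their eQTL and specific variants) plus direct
    pleiotropy effects."""
    g = truth.genes
    genetic = np.zeros(n)
    a, b = truth.layer_effect_components("protein")
    spec = truth.specific_variants()
    for i in g.index[g["causal_for_outcome"]]:
        jc = genotypes.index_of([g.loc[i, "causal_variant"]])[0]
        js = genotypes.index_of([spec.loc[i]])[0]
        genetic += a[i] * dosage[:, jc] + b[i] * dosage[:, js]
    for vid, eff in truth.pleiotropy.items():
        genetic += eff * dosage[:, genotypes.index_of([vid])[0]]
    return genetic


def simulate_gwas(
    genotypes: VariantTable,
    truth: CascadeTruth,
    outcome_h2: float = 0.3,
    n_gwas: int = 5000,
    seed: int = 0,
) -> GWASSummary:
    """Marginal GWAS summary statistics from an independent cohort.

    The outcome is a continuous liability: the sum over causal genes of
    their protein-layer genetic component, plus direct variant effects
    (horizontal pleiotropy), scaled so the genetic part explains
    ``outcome_h2`` of the liability variance, plus Gaussian noise.  The
    GWAS cohort is redrawn with the QTL cohort's MAF and LD parameters so
    two-sample MR assumptions hold by construction.
    """
    if not (0.0 < outcome_h2 < 1.0):
        raise ValueError("outcome_h2 must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    dosage = _draw_dosages(
        rng, n_gwas, genotypes.maf, genotypes.ld_block_size, genotypes.ld_rho
    ).astype(float)

    genetic = _outcome_genetic_component(truth, genotypes, dosage, n_gwas)

    var_g = genetic.var()
    if var_g > 0:
        noise_sd = np.sqrt(var_g * (1.0 - outcome_h2) / outcome_h2)
    else:  # fully null outcome: pure noise
        noise_sd = 1.0
    y = genetic + rng.normal(0.0, noise_sd, size=n_gwas)

    # marginal simple regression per variant, vectorized
    yc = y - y.mean()
    xc = dosage - dosage.mean(axis=0)
    sxx = (xc**2).sum(axis=0)
    beta = (xc * yc[:, None]).sum(axis=0) / sxx
    resid_var = ((yc**2).sum() - beta**2 * sxx) / (n_gwas - 2)
    se = np.sqrt(resid_var / sxx)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {
            "variant_id": genotypes.variant_id,
            "effect_allele": genotypes.alt_allele,
            "other_allele": genotypes.ref_allele,
            "beta": beta,
            "se": se,
            "zscore": z,
            "pvalue": p,
            "n": n_gwas,
        }
    )
    return GWASSummary(table=table)


def attenuation_study(
    n_samples: int = 200,
    n_genes: int = 500,
    seed: int = 0,
    lambda_r: float = 0.75,
    lambda_p: float = 0.8,
):
    """Standard attenuation-study conditions: genotypes + cascade layers.

    Three gene classes mirror the structure of a real eQTL replication
    design: ~35% strong eQTL genes (effect 0.5 + half-normal(0.3), random
    sign) that stand in for an externally ascertained eQTL panel — strong
    ascertained effects keep the per-gene |slope| means free of
    folded-normal noise inflation, so the panel's layer-mean ratios
    recover the attenuation parameters; ~45% weak eQTL genes (effect
    uniform on 0.15-0.35) that sit near the detection limit, where
    downstream attenuation and noise genuinely erase replication — the
    regime that creates the asymmetric pi1 matrix; and ~20% null genes so
    FDR control is exercised.  Measurement noise increases down the
    cascade (protein 1.8x, ribo 1.3x the mRNA residual sd, on top of the
    count layers' negative-binomial sampling noise), reflecting ribo-seq
    and mass-spec being technically noisier than RNA-seq.  Variants are
    common (MAF 0.2-0.5).

    Returns (genotypes, truth, raw layers, external_panel) where
    ``external_panel`` is the (gene_id, variant_id) frame of the strong
    ascertained class.
    """
    g = simulate_genotypes(
        n_samples, n_genes * 3, maf_low=0.2, maf_high=0.5,
        ld_block_size=3, ld_rho=0.3, seed=seed,
    )
    rng = np.random.default_rng(seed + 1)
    u = rng.random(n_genes)
    beta = np.where(
        u < 0.35,
        0.5 + np.abs(rng.normal(0.0, 0.3, size=n_genes)),
        np.where(u < 0.80, rng.uniform(0.15, 0.35, size=n_genes), 0.0),
    )
    truth = make_cascade_truth(
        g, n_genes, seed=seed + 2, eqtl_effect=beta,
        lambda_r=lambda_r, lambda_p=lambda_p,
        noise_sd={"mrna": 1.0, "ribo": 1.3, "protein": 1.8},
    )
    layers = simulate_cascade(g, truth, seed=seed + 3)
    strong = truth.genes[np.abs(truth.genes["eqtl_effect"]) >= 0.5]
    panel = pd.DataFrame(
        {"gene_id": strong["gene_id"], "variant_id": strong["causal_variant"]}
    )
    return g, truth, layers, panel


def specificity_study(
    kind: str = "shared",
    n_samples: int = 185,
    n_genes: int = 50,
    seed: int = 0,
    variants_per_gene: int = 200,
):
    """Standard conditions for the shared/omics-specific classifier study.

    Genes get rich cis panels (200 variants in 40 LD blocks of 5,
    pairwise r ~ 0.5 within a block): the permutation null of R_c^2 is
    honest only when the cis genotype space spans the sample space, as it
    does in a real +/- 1 Mb window with hundreds of common SNPs — with
    only a handful of cis variants, a shuffled imputation vector cannot
    be absorbed by the conditional model while the observed one can,
    which deflates the null systematically.  Effects give a cis heritability
    near 0.2 (effect 0.8 per allele, residual sd 1.2).

    kind="shared": the genetic effect propagates through all layers
    unattenuated (the false-specificity control).  kind="protein_specific":
    the mRNA eQTL propagates to ribosome occupancy but not protein, and
    protein carries its own genetic effect at a different LD block.
    Returns (genotypes, truth).
    """
    g = simulate_genotypes(
        n_samples, n_genes * variants_per_gene, ld_block_size=5, ld_rho=0.5,
        seed=seed,
    )
    if kind == "shared":
        truth = make_cascade_truth(g, n_genes, seed=seed + 1, eqtl_effect=0.8,
                                   noise_sd=1.2)
    elif kind == "protein_specific":
        truth = make_cascade_truth(
            g, n_genes, seed=seed + 1, eqtl_effect=0.8, lambda_r=1.0,
            lambda_p=0.0, gamma_p=0.8, separate_specific_variant=True,
            noise_sd=1.2,
        )
    else:
        raise ValueError(f"unknown study kind {kind!r}")
    return g, truth


def twas_null_study(seed: int = 0, n_qtl: int = 1000):
    """Genotypes, truth and trained prediction models for the TWAS
    family-wise-control study.

    40 genes laid out two per LD block (overlapping cis architecture, as
    in gene-dense loci) with models trained by the package's elastic net
    on a large QTL cohort — trained weights are aligned with the LD they
    will be normalized by, and the large cohort keeps the reference LD
    estimate accurate, both of which a calibrated summary-statistic test
    requires.  Returns (genotypes, truth, models dict).
    """
    from .specificity import train_prediction_model

    g = simulate_genotypes(n_qtl, 100, ld_block_size=5, ld_rho=0.4, seed=seed)
    truth = make_cascade_truth(g, 20, seed=seed, eqtl_effect=0.6)
    rng = np.random.default_rng(seed + 1)
    models = {}
    for i in range(40):
        b = i // 2
        cols = slice(5 * b, 5 * b + 5)
        y = 0.6 * g.dosage[:, 5 * b + (i % 2)] + rng.normal(size=n_qtl)
        y = (y - y.mean()) / y.std()
        m = train_prediction_model(
            f"gene{i + 1}", "mrna", g.dosage[:, cols], y,
            g.variant_id[cols], seed=i,
        )
        if m.retained:
            models[(f"gene{i + 1}", "mrna")] = m
    return g, truth, models


def cascade_mr_study(
    n_per_class: int = 50,
    n_samples: int = 185,
    seed: int = 0,
):
    """Three constructed gene classes for the one-sample cascade MR study.

    both-passed: full cascade (lambda_r = lambda_p = 1);
    single-passed: translated but post-translationally erased
    (lambda_r = 1, lambda_p = 0); none-passed: no transcriptional signal,
    protein-specific genetic effect only (beta = 0, gamma_p > 0).
    Effects are strong (0.9 per allele, residual sd 1) so instruments are
    informative at n = 185.  Returns (genotypes, truth, expected_classes).
    """
    n_genes = 3 * n_per_class
    g = simulate_genotypes(
        n_samples, n_genes * 10, ld_block_size=5, ld_rho=0.5, seed=seed
    )
    cls = np.repeat(["both-passed", "single-passed", "none-passed"], n_per_class)
    rng = np.random.default_rng(seed + 1)
    cls = rng.permutation(cls)
    beta = np.where(cls == "none-passed", 0.0, 0.9)
    lam_p = np.where(cls == "both-passed", 1.0, 0.0)
    gam_p = np.where(cls == "none-passed", 0.9, 0.0)
    truth = make_cascade_truth(
        g, n_genes, seed=seed + 2, eqtl_effect=beta, lambda_r=1.0,
        lambda_p=lam_p, gamma_p=gam_p, noise_sd=1.0,
        separate_specific_variant=True,
    )
    expected = pd.Series(cls, index=truth.gene_ids, name="expected_class")
    return g, truth, expected


def coloc_study_region(
    seed: int = 0,
    shared: bool = True,
    qtl_r2: float = 0.15,
    gwas_locus_h2: float = 0.01,
    n_qtl: int = 185,
    n_gwas: int = 5000,
):
    """One cis region for the colocalization study.

    Three 10-variant LD blocks (within-block r ~ 0.6).  The QTL trait is
    driven by one causal variant explaining ``qtl_r2`` of its variance —
    0.15 by default, the effect size of a typical *discovered* lead eQTL
    at n=185, since colocalization is only ever attempted for mapped QTL
    genes.  The GWAS outcome (independent cohort of ``n_gwas``) is driven
    by the same variant when ``shared``, else by a variant in a different
    LD block, with the locus explaining ``gwas_locus_h2`` of outcome
    variance.  Returns (gene_row, genotypes, qtl_expression, gwas).
    """
    g = simulate_genotypes(n_qtl, 30, ld_block_size=10, ld_rho=0.6, seed=seed)
    rng = np.random.default_rng(seed + 1000)
    causal = 5
    x = g.dosage[:, causal]
    # exact realized R^2: orthogonalize the noise against the causal dosage
    xc = x - x.mean()
    e = rng.normal(size=n_qtl)
    e = e - (e @ xc) / (xc @ xc) * xc
    y = np.sqrt(qtl_r2) * xc / xc.std() + np.sqrt(1 - qtl_r2) * e / e.std()
    truth = make_cascade_truth(g, 1, seed=seed, eqtl_effect=0.0, random_sign=False)
    gene_row = truth.annotation().iloc[0]
    truth.genes.loc[0, "causal_variant"] = g.variant_id[causal if shared else 25]
    truth.genes.loc[0, "eqtl_effect"] = 1.0
    truth.genes.loc[0, "causal_for_outcome"] = True
    gwas = simulate_gwas(g, truth, outcome_h2=gwas_locus_h2, n_gwas=n_gwas, seed=seed + 2)
    return gene_row, g, y, gwas


def residualized_latent_layers(genotypes, truth, seed: int = 0):
    """Latent cascade layers standardized per gene, as residualized
    OmicsMatrix objects — the direct route to the post-preprocessing state
    when a study does not exercise the preprocessing stack itself."""
    rng = np.random.default_rng(seed)
    latent, _ = _latent_layers(genotypes, truth, rng)
    out = {}
    for lay, v in latent.items():
        v = (v - v.mean(axis=0)) / v.std(axis=0)
        out[lay] = OmicsMatrix(
            layer=lay, stage="residualized",
            values=pd.DataFrame(v, index=genotypes.sample_ids,
                                columns=truth.gene_ids),
        )
    return out


def gwas_individual_level(
    genotypes: VariantTable,
    truth: CascadeTruth,
    outcome_h2: float,
    n_gwas: int,
    seed: int = 0,
):
    """Individual-level GWAS cohort (dosages + outcome), for equivalence tests."""
    rng = np.random.default_rng(seed)
    dosage = _draw_dosages(
        rng, n_gwas, genotypes.maf, genotypes.ld_block_size, genotypes.ld_rho
    ).astype(float)
    genetic = _outcome_genetic_component(truth, genotypes, dosage, n_gwas)
    var_g = genetic.var()
    noise_sd = np.sqrt(var_g * (1 - outcome_h2) / outcome_h2) if var_g > 0 else 1.0
    y = genetic + rng.normal(0.0, noise_sd, size=n_gwas)
    return dosage, y
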