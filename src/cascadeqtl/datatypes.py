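"""Core containers shared across the pipeline.

Conventions: sample x feature orientation for all in-memory matrices;
genomic coordinates are 1-based inclusive; dosages count alternate alleles
in [0, 2].
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

LAYERS = ("mrna", "ribo", "protein")

STAGES = ("raw_counts", "log_cpm", "filtered", "quantile_normalized", "residualized")


@dataclass
class VariantTable:
    """Variant metadata plus per-sample alt-allele dosages.

    ``dosage`` is samples x variants.  ``maf`` is the declared minor-allele
    frequency used at simulation time (equal to the alt-allele frequency,
    which is kept <= 0.5).  ``ld_block_size``/``ld_rho`` record the
    block-equicorrelation structure so that an independent cohort with the
    same variants can be redrawn.
    """

    variant_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    maf: np.ndarray
    dosage: np.ndarray
    sample_ids: list[str]
    ld_block_size: int = 1
    ld_rho: float = 0.0

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosage.shape[1]

    def index_of(self, variant_ids) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variant_id)}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"variant not in table: {e.args[0]}") from None

    def subset_variants(self, idx) -> "VariantTable":
        idx = np.asarray(idx)
        return replace(
            self,
            variant_id=self.variant_id[idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            ref_allele=self.ref_allele[idx],
            alt_allele=self.alt_allele[idx],
            maf=self.maf[idx],
            dosage=self.dosage[:, idx],
        )

    def empirical_maf(self) -> np.ndarray:
        af = self.dosage.mean(axis=0) / 2.0
        return np.minimum(af, 1.0 - af)


@dataclass
class OmicsMatrix:
    """One sample x gene quantification layer with a processing-stage tag."""

    layer: str
    stage: str
    values: pd.DataFrame  # index = sample ids, columns = gene ids

    def __post_init__(self):
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}; expected one of {LAYERS}")
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {STAGES}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    def advance(self, new_stage: str, new_values: pd.DataFrame) -> "OmicsMatrix":
        """Return a copy at a later processing stage; transitions only move forward."""
        if STAGES.index(new_stage) <= STAGES.index(self.stage) and not (
            new_stage == self.stage == "filtered"
        ):
            raise ValueError(
                f"stage transition {self.stage} -> {new_stage} moves backward"
            )
        return OmicsMatrix(layer=self.layer, stage=new_stage, values=new_values)


@dataclass
class FactorSet:
    """Nuisance covariates: sample x factor scores, mutually orthogonal."""

    factors: pd.DataFrame  # index = sample ids, columns = factor names
    variance_explained: np.ndarray

    @property
    def n_factors(self) -> int:
        return self.factors.shape[1]


@dataclass
class CascadeTruth:
    """Ground truth of the generative cascade.

    ``genes`` has one row per gene: gene_id, chrom, start, end, strand,
    causal_variant (id), eqtl_effect (beta, per-allele effect on the
    standardized mRNA scale), lambda_r / lambda_p (translational and
    post-translational attenuation in [0, 1]), gamma_r / gamma_p
    (layer-specific genetic effects arising only at the ribo / protein
    layer), causal_for_outcome flag and per-layer noise_sd columns.

    ``pleiotropy`` maps variant_id -> direct variant->outcome effect that
    bypasses expression.  ``factor_loadings`` maps layer -> (n_factors x
    n_genes) loading matrix of the shared hidden confounders.
    """

    genes: pd.DataFrame
    pleiotropy: dict = field(default_factory=dict)
    factor_loadings: dict = field(default_factory=dict)
    n_hidden_factors: int = 5

    def __post_init__(self):
        lam = self.genes[["lambda_r", "lambda_p"]].to_numpy(float)
        if ((lam < 0) | (lam > 1)).any():
            raise ValueError("attenuation parameters lambda_r/lambda_p must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.genes["gene_id"])

    def specific_variants(self) -> pd.Series:
        """Variant carrying the layer-specific gamma effects (the eQTL
        variant itself unless laid out separately)."""
        if "specific_variant" in self.genes.columns:
            return self.genes["specific_variant"]
        return self.genes["causal_variant"]

    def layer_effect_components(self, layer: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-allele effects at (causal_variant, specific_variant).

        mrna: (beta, 0); ribo: (lambda_r*beta, gamma_r);
        protein: (lambda_p*lambda_r*beta, lambda_p*gamma_r + gamma_p).
        """
        g = self.genes
        beta = g["eqtl_effect"].to_numpy(float)
        zero = np.zeros_like(beta)
        lam_r = g["lambda_r"].to_numpy(float)
        lam_p = g["lambda_p"].to_numpy(float)
        gam_r = g["gamma_r"].to_numpy(float)
        gam_p = g["gamma_p"].to_numpy(float)
        if layer == "mrna":
            return beta, zero
        if layer == "ribo":
            return lam_r * beta, gam_r
        if layer == "protein":
            return lam_p * lam_r * beta, lam_p * gam_r + gam_p
        raise ValueError(f"unknown layer {layer!r}")

    def layer_effect(self, layer: str) -> np.ndarray:
        """Total per-allele genetic effect at a layer when the gamma
        effects act at the eQTL variant itself (the default layout):
        mrna beta; ribo lambda_r*beta + gamma_r;
        protein lambda_p*(lambda_r*beta + gamma_r) + gamma_p."""
        a, b = self.layer_effect_components(layer)
        return a + b

    def annotation(self) -> pd.DataFrame:
        return self.genes[["gene_id", "chrom", "start", "end", "strand"]].copy()


@dataclass
class GWASSummary:
    """Per-variant marginal summary statistics for the outcome trait."""

    table: pd.DataFrame  # variant_id, effect_allele, other_allele, beta, se, zscore, pvalue, n

    def __post_init__(self):
        t = self.table
        need = {"variant_id", "effect_allele", "other_allele", "beta", "se", "zscore", "pvalue", "n"}
        missing = need - set(t.columns)
        if missing:
            raise ValueError(f"GWAS summary missing columns: {sorted(missing)}")

    def subset(self, variant_ids) -> pd.DataFrame:
        return self.table.set_index("variant_id").loc[list(variant_ids)].reset_index()


@dataclass
class QTLResult:
    """Per-gene lead-variant cis association for one omics layer."""

    gene_id: str
    layer: str
    lead_variant_id: str
    slope: float
    slope_se: float
    nominal_p: float
    beta_shape1: float
    beta_shape2: float
    empirical_p: float
    n_variants_tested: int
    qvalue: float = np.nan


@dataclass
class PredictionModel:
    """Sparse cis-variant weight model for one gene x layer."""

    gene_id: str
    layer: str
    weights: dict  # variant_id -> weight (nonzero entries only)
    intercept: float
    r_cv: float
    r_cv_p: float
    conditional: bool = False
    alpha: float = np.nan  # elastic-net penalty actually used

    @property
    def retained(self) -> bool:
        return bool(self.r_cv > 0.1 and self.r_cv_p < 0.05 and len(self.weights) > 0)


@dataclass
class MRResult:
    """One causal test (IVW, Egger or two-stage least squares)."""

    gene_id: str
    exposure: str
    outcome: str
    method: str  # IVW | Egger | TSLS
    estimate: float
    se: float
    pvalue: float
    n_instruments: int
    intercept: float = np.nan
    intercept_p: float = np.nan
    f_statistic: float = np.nan
    fdr: float = np.nan
    verdict: str = "untested"
    weak_instruments: bool = False
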