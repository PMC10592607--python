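"""Bayesian colocalization between a cis-QTL signal and GWAS.

Single-causal-variant enumeration over five hypotheses: H0 no signal, H1
QTL-only, H2 GWAS-only, H3 two distinct causal variants, H4 one shared
causal variant.  Per-variant evidence is the Wakefield approximate Bayes
factor; hypothesis sums are accumulated in log space.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .datatypes import GWASSummary, VariantTable
from .qtl import cis_window, nominal_scan

# default priors of the referenced colocalization framework
P1_DEFAULT = 1e-4
P2_DEFAULT = 1e-4
P12_DEFAULT = 1e-5
PRIOR_SD_QUANT = 0.15  # effect-scale prior for a standardized quantitative trait


@dataclass
class ColocResult:
    gene_id: str
    layer: str
    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_snps: int
    lead_shared_variant: str

    @property
    def posteriors(self) -> np.ndarray:
        return np.array([self.pp0, self.pp1, self.pp2, self.pp3, self.pp4])


def wakefield_abf(beta, se, prior_sd: float = PRIOR_SD_QUANT) -> np.ndarray:
    """Log approximate Bayes factor for association of one variant.

    z = beta/se, shrinkage r = prior_sd^2/(prior_sd^2 + se^2),
    logABF = 0.5*(log(1-r) + r*z^2).
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    z = beta / se
    r = prior_sd**2 / (prior_sd**2 + se**2)
    return 0.5 * (np.log1p(-r) + r * z**2)


def coloc_posteriors(
    logabf_qtl: np.ndarray,
    logabf_gwas: np.ndarray,
    p1: float = P1_DEFAULT,
    p2: float = P2_DEFAULT,
    p12: float = P12_DEFAULT,
) -> np.ndarray:
    """Posterior probabilities (pp0..pp4) from per-variant log ABFs.

    H1 ~ p1 * sum BF1_i; H2 ~ p2 * sum BF2_j;
    H3 ~ p1*p2 * (sum BF1 * sum BF2 - sum BF1_i*BF2_i); H4 ~ p12 * sum BF1_i*BF2_i;
    H0 ~ 1.  All sums in log space; a single-variant region has pp3 = 0
    exactly (the distinct-pair sum is empty).
    """
    l1 = np.asarray(logabf_qtl, float)
    l2 = np.asarray(logabf_gwas, float)
    if l1.shape != l2.shape:
        raise ValueError("mismatched variant sets")
    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    lh = np.full(5, -np.inf)
    lh[0] = 0.0
    lh[1] = np.log(p1) + ls1
    lh[2] = np.log(p2) + ls2
    if l1.size > 1:
        # log(sum_{i != j} BF1_i BF2_j) = log(exp(ls1+ls2) - exp(ls12))
        both = ls1 + ls2
        if both > ls12:
            lh[3] = np.log(p1) + np.log(p2) + both + np.log1p(-np.exp(ls12 - both))
    lh[4] = np.log(p12) + ls12
    pp = np.exp(lh - logsumexp(lh))
    return pp / pp.sum()


def gwas_logabf(gwas_rows: pd.DataFrame, prior_sd: float = PRIOR_SD_QUANT) -> np.ndarray:
    """Log ABFs for GWAS variants; falls back to z and se = 1/sqrt(n) when
    beta/se are unavailable (unknown trait scale)."""
    if {"beta", "se"}.issubset(gwas_rows.columns) and gwas_rows["se"].notna().all():
        return wakefield_abf(gwas_rows["beta"].to_numpy(), gwas_rows["se"].to_numpy(), prior_sd)
    se = 1.0 / np.sqrt(gwas_rows["n"].to_numpy(float))
    beta = gwas_rows["zscore"].to_numpy(float) * se
    return wakefield_abf(beta, se, prior_sd)


def colocalize_gene(
    gene_row,
    layer: str,
    genotypes: VariantTable,
    expression: np.ndarray,
    gwas: GWASSummary,
    pph4_cutoff: float = 0.7,
    maf_min: float = 0.05,
    prior_sd: float = PRIOR_SD_QUANT,
) -> tuple[ColocResult, bool]:
    """Colocalize one gene's cis-QTL signal with the GWAS.

    QTL slopes/ses come from the nominal cis scan; the flag is
    pp4 >= ``pph4_cutoff``.
    """
    scan = nominal_scan(cis_window(gene_row), genotypes, expression, maf_min)
    if scan is None:
        raise ValueError(f"gene {gene_row['gene_id']}: no cis variants overlap")
    gtab = gwas.table.set_index("variant_id")
    overlap = scan["variant_id"].isin(gtab.index)
    scan = scan[overlap]
    if len(scan) == 0:
        raise ValueError(f"gene {gene_row['gene_id']}: zero overlapping variants")
    if len(scan) < 10:
        warnings.warn(f"gene {gene_row['gene_id']}: only {len(scan)} overlapping variants")
    grows = gtab.loc[scan["variant_id"]].reset_index()
    l1 = wakefield_abf(scan["slope"].to_numpy(), scan["se"].to_numpy(), prior_sd)
    l2 = gwas_logabf(grows, prior_sd)
    pp = coloc_posteriors(l1, l2)
    lead = str(scan["variant_id"].iloc[int(np.argmax(l1 + l2))])
    res = ColocResult(
        gene_id=str(gene_row["gene_id"]), layer=layer,
        pp0=pp[0], pp1=pp[1], pp2=pp[2], pp3=pp[3], pp4=pp[4],
        n_snps=len(scan), lead_shared_variant=lead,
    )
    return res, bool(pp[4] >= pph4_cutoff)
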