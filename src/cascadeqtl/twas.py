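"""Summary-statistic transcriptome/proteome-wide association.

The gene-level z-score combines prediction-model weights with per-variant
GWAS z-scores, normalized by the imputed-expression variance under the
reference LD:

    z_gene = sum_i w_i * (sigma_i / sigma_g) * z_i,   sigma_g = sqrt(w' Sigma w)

where sigma_i is the dosage standard deviation of variant i and Sigma the
dosage covariance over the model's variants (from the QTL cohort, the
models' training data).  Protein isoforms are combined by the Cauchy
combination test; family-wise error uses Bonferroni.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .datatypes import GWASSummary, PredictionModel, VariantTable


@dataclass
class TwasResult:
    gene_id: str
    layer: str
    zscore: float
    pvalue: float
    n_model_snps_used: int
    fwer: float = np.nan
    testable: bool = True


def spredixcan_zscore(
    model: PredictionModel, gwas: GWASSummary, genotypes: VariantTable
) -> TwasResult:
    """Gene-level association z from model weights and GWAS z-scores.

    Alleles are assumed harmonized (the synthetic GWAS reports effects on
    the same alt allele as the dosage coding).  sigma_g = 0 (no weight
    variance under LD) marks the gene untestable.
    """
    gtab = gwas.table.set_index("variant_id")
    vids = [v for v in model.weights if v in gtab.index]
    if not vids:
        raise ValueError(f"gene {model.gene_id}: no model variant has GWAS statistics")
    idx = genotypes.index_of(vids)
    w = np.array([model.weights[v] for v in vids])
    X = genotypes.dosage[:, idx]
    sigma = np.cov(X, rowvar=False, ddof=1).reshape(len(vids), len(vids))
    sigma_i = np.sqrt(np.diag(sigma))
    var_g = float(w @ sigma @ w)
    if var_g <= 0:
        return TwasResult(model.gene_id, model.layer, np.nan, np.nan, len(vids), testable=False)
    z_i = gtab.loc[vids, "zscore"].to_numpy(float)
    z = float(np.sum(w * sigma_i * z_i) / np.sqrt(var_g))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return TwasResult(model.gene_id, model.layer, z, p, len(vids))


def omnibus_combine(pvalues) -> float:
    """Cauchy combination of per-isoform p-values.

    T = mean(tan((0.5 - p_i) * pi)); combined p = 0.5 - arctan(T)/pi.
    Robust to dependence between isoforms; exact for a single p.  Zeros are
    clipped to 1e-300 with a warning.
    """
    p = np.asarray(pvalues, float)
    if np.any(p > 1) or np.any(p < 0):
        raise ValueError("p-values outside [0, 1]")
    if np.any(p == 0):
        warnings.warn("p = 0 clipped to 1e-300")
        p = np.clip(p, 1e-300, 1.0)
    t = np.mean(np.tan((0.5 - p) * np.pi))
    return float(0.5 - np.arctan(t) / np.pi)


def fwer_adjust(pvalues, n_tests: int | None = None) -> np.ndarray:
    """Bonferroni family-wise error rates: min(1, p * n_tests)."""
    p = np.asarray(pvalues, float)
    if n_tests is None:
        n_tests = p.size
    if n_tests < p.size:
        raise ValueError("n_tests smaller than the number of p-values")
    return np.minimum(1.0, p * n_tests)


def twas_scan(
    models: dict[tuple[str, str], PredictionModel],
    gwas: GWASSummary,
    genotypes: VariantTable,
    alpha: float = 0.05,
) -> "pd.DataFrame":
    """TWAS over all retained models, Bonferroni within each layer.

    Significance uses fwer <= ``alpha`` (boundary inclusive)."""
    import pandas as pd

    rows = []
    for (gid, layer), model in models.items():
        if not model.retained:
            continue
        try:
            res = spredixcan_zscore(model, gwas, genotypes)
        except ValueError:
            continue
        if res.testable:
            rows.append(res)
    df = pd.DataFrame([vars(r) for r in rows])
    if len(df) == 0:
        df = pd.DataFrame(columns=[
            "gene_id", "layer", "zscore", "pvalue", "n_model_snps_used",
            "fwer", "testable", "is_significant",
        ])
        return df
    for layer in df["layer"].unique():
        mask = df["layer"] == layer
        df.loc[mask, "fwer"] = fwer_adjust(df.loc[mask, "pvalue"].to_numpy())
    df["is_significant"] = df["fwer"] <= alpha
    return df
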