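"""Cross-omics sharing and effect attenuation.

Three complementary views of how genetic effects propagate down the
cascade: the Storey pi1 replication matrix between QTL layers, a
direction-aware cutoff-based replication rate, and aggregate per-allele
effect-size profiles for an externally ascertained eQTL list (which avoids
winner's-curse bias when comparing layers).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import OmicsMatrix, VariantTable
from .qtl import _regress, storey_pi0

LAYER_ORDER = ("mrna", "ribo", "protein")


def _lead_nominal(
    leads: pd.DataFrame, expression: OmicsMatrix, genotypes: VariantTable
) -> pd.DataFrame:
    """Nominal slope/se/p of each (gene, lead variant) pair in one layer."""
    rows = []
    vidx = genotypes.index_of(leads["lead_variant_id"])
    for (gid, vi) in zip(leads["gene_id"], vidx):
        if gid not in expression.values.columns:
            continue
        y = expression.values[gid].to_numpy(float)
        slope, se, p = _regress(genotypes.dosage[:, [vi]], y)
        rows.append((gid, slope[0], se[0], p[0]))
    return pd.DataFrame(rows, columns=["gene_id", "slope", "se", "pvalue"])


def replication_pi1(
    discovery: pd.DataFrame,
    replication_layer: OmicsMatrix,
    genotypes: VariantTable,
) -> float:
    """pi1 = 1 - pi0 of replication-layer nominal p-values at the
    discovery leads.  ``discovery`` needs gene_id and lead_variant_id
    columns (the significant set of a QTL scan)."""
    if len(discovery) == 0:
        raise ValueError("empty discovery set")
    if len(discovery) < 20:
        warnings.warn("fewer than 20 discovery genes: pi0 smoothing is unstable")
    rep = _lead_nominal(discovery, replication_layer, genotypes)
    return float(1.0 - storey_pi0(rep["pvalue"].to_numpy()))


def replication_matrix(
    qtl_results: pd.DataFrame,
    layers: dict[str, OmicsMatrix],
    genotypes: VariantTable,
) -> pd.DataFrame:
    """Full 3x3 pi1 matrix (rows discover, columns replicate; diagonal 1)."""
    mat = pd.DataFrame(
        np.ones((3, 3)), index=list(LAYER_ORDER), columns=list(LAYER_ORDER)
    )
    for disc in LAYER_ORDER:
        sig = qtl_results[(qtl_results["layer"] == disc) & qtl_results["is_significant"]]
        for rep in LAYER_ORDER:
            if rep == disc or len(sig) == 0:
                continue
            mat.loc[disc, rep] = replication_pi1(sig, layers[rep], genotypes)
    return mat


def asymmetry_statistics(matrix: pd.DataFrame) -> pd.DataFrame:
    """pi1(downstream->upstream) - pi1(upstream->downstream) per layer pair.

    Positive values mean downstream discoveries replicate upstream better
    than the reverse — the signature of effect attenuation.
    """
    rows = []
    for i, up in enumerate(LAYER_ORDER):
        for down in LAYER_ORDER[i + 1:]:
            rows.append(
                {
                    "upstream": up,
                    "downstream": down,
                    "asymmetry": float(matrix.loc[down, up] - matrix.loc[up, down]),
                }
            )
    return pd.DataFrame(rows)


def directional_replication_rate(
    discovery: pd.DataFrame,
    replication_stats: pd.DataFrame,
    p_cutoffs,
) -> pd.DataFrame:
    """Fraction of discovery leads replicating with matching effect sign.

    ``discovery`` and ``replication_stats`` both need gene_id and slope
    columns; replication additionally pvalue.  rate(c) = fraction with
    replication p < c and sign agreement.
    """
    merged = discovery.merge(
        replication_stats, on="gene_id", suffixes=("_disc", "_rep")
    )
    sign_ok = np.sign(merged["slope_disc"]) == np.sign(merged["slope_rep"])
    rows = []
    for c in np.atleast_1d(p_cutoffs):
        hit = (merged["pvalue"] < c) if c < 1 else np.ones(len(merged), bool)
        rows.append({"cutoff": float(c), "rate": float((sign_ok & hit).mean())})
    return pd.DataFrame(rows)


@dataclass
class EffectProfile:
    """Per-layer mean |per-allele effect| (log2 units) with 95% CI."""

    table: pd.DataFrame          # layer, mean_abs_effect, ci_low, ci_high, n_snps
    pairwise_p: pd.DataFrame     # layer x layer t-test p-values

    def ratio(self, num_layer: str, den_layer: str) -> float:
        t = self.table.set_index("layer")["mean_abs_effect"]
        return float(t[num_layer] / t[den_layer])


def external_effect_profile(
    external_pairs: pd.DataFrame,
    layers_log2: dict[str, OmicsMatrix],
    genotypes: VariantTable,
) -> EffectProfile:
    """Aggregate per-allele |effect| of an external (gene, variant) list.

    Slopes are computed on log2-scale quantifications (not standardized
    residuals) so the three layers are compared in the same interpretable
    units.  Variants absent from the genotype table are dropped with a
    logged count; the same (gene, variant) set is evaluated in all layers.
    """
    if len(external_pairs) == 0:
        raise ValueError("empty external eQTL list")
    known = set(genotypes.variant_id)
    keep = external_pairs["variant_id"].isin(known)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} external variants absent from genotypes, dropped")
    pairs = external_pairs[keep]
    pairs = pairs[
        pairs["gene_id"].isin(
            set.intersection(*(set(m.gene_ids) for m in layers_log2.values()))
        )
    ]
    if len(pairs) == 0:
        raise ValueError("no external pairs overlap the quantified gene set")
    vidx = genotypes.index_of(pairs["variant_id"])
    effects = {}
    for layer, mx in layers_log2.items():
        Y = mx.values[list(pairs["gene_id"])].to_numpy(float)
        X = genotypes.dosage[:, vidx]
        # per-pair simple regression, vectorized across pairs
        xc = X - X.mean(axis=0)
        yc = Y - Y.mean(axis=0)
        slope = (xc * yc).sum(axis=0) / (xc**2).sum(axis=0)
        effects[layer] = np.abs(slope)
    rows = []
    for layer in LAYER_ORDER:
        if layer not in effects:
            continue
        e = effects[layer]
        m, sem = e.mean(), e.std(ddof=1) / np.sqrt(e.size)
        rows.append(
            {
                "layer": layer,
                "mean_abs_effect": m,
                "ci_low": m - 1.96 * sem,
                "ci_high": m + 1.96 * sem,
                "n_snps": int(e.size),
            }
        )
    names = [r["layer"] for r in rows]
    pw = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            p = stats.ttest_ind(effects[a], effects[b]).pvalue
            pw.loc[a, b] = pw.loc[b, a] = p
    return EffectProfile(table=pd.DataFrame(rows), pairwise_p=pw)
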