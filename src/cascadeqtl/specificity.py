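"""Shared vs omics-specific QTL gene classification via conditional
prediction models.

For each gene and focal omics layer an elastic-net model predicts the
residualized expression from cis genotypes (the "original" model, weights
w_i).  The genetic signal of the other layers is then removed by
regressing the focal expression on the other layers' *imputed* expression;
a second elastic net on the residual gives the "conditional" model
(weights m_i).  The squared correlation R_c^2 between the two models'
imputed expression measures how much of the gene's genetic regulation
survives conditioning: low R_c^2 means the signal is shared with other
layers, R_c^2 near 1 means it is specific to the focal layer.  A
permutation null (shuffling the sample labels of the other layers' imputed
expression) calibrates R_c^2; Benjamini-Hochberg FDR over the empirical
p-values plus R_c^2 cutoffs yields the shared / specific / unclassified
call:

    shared    iff FDR < 0.1 and R_c^2 < 0.5
    specific  iff FDR > 0.1 and R_c^2 > 0.9
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .datatypes import OmicsMatrix, PredictionModel, VariantTable
from .qtl import cis_variant_indices, cis_window

logger = logging.getLogger(__name__)

L1_RATIO = 0.5  # elastic-net mixing; the prediction-model convention


@dataclass
class ConditionalExpression:
    """Focal-layer expression conditioned on other layers' genetic signal."""

    gene_id: str
    layer: str
    residual: np.ndarray          # e_k, orthogonal to every regressor
    slopes: np.ndarray            # beta_l on the other layers' imputed expression
    center_offset: float          # per-gene mean of the focal expression
    conditioned: np.ndarray       # R_k = center_offset + e_k

    def __post_init__(self):
        self.conditioned = self.center_offset + self.residual


def _fit_enet(X, y, alpha):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = ElasticNet(alpha=alpha, l1_ratio=L1_RATIO, max_iter=2000, tol=1e-3)
        model.fit(X, y)
    return model


def train_prediction_model(
    gene_id: str,
    layer: str,
    X: np.ndarray,
    y: np.ndarray,
    variant_ids: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    conditional: bool = False,
    alpha: float | None = None,
) -> PredictionModel:
    """Elastic-net cis prediction model with cross-validated accuracy.

    The penalty is chosen by ``n_folds``-fold CV along the elastic-net path
    (mixing parameter 0.5) unless ``alpha`` is given; r_cv is the Pearson
    correlation between out-of-fold predictions and observations, with its
    correlation-test p-value.  An all-zero-weight solution is returned
    unretained (no genetic signal).
    """
    if X.shape[1] < 1:
        raise ValueError("no cis variants")
    y = np.asarray(y, float)
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if alpha is None:
            cvm = ElasticNetCV(
                l1_ratio=L1_RATIO, alphas=15, cv=cv, max_iter=2000, tol=1e-3
            )
            cvm.fit(X, y)
            alpha = float(cvm.alpha_)
    # out-of-fold predictions at the chosen penalty
    oof = np.empty_like(y)
    for tr, te in cv.split(X):
        m = _fit_enet(X[tr], y[tr], alpha)
        oof[te] = m.predict(X[te])
    if np.std(oof) < 1e-12 or np.std(y) < 1e-12:
        r_cv, r_cv_p = 0.0, 1.0
    else:
        r_cv, r_cv_p = stats.pearsonr(oof, y)
    final = _fit_enet(X, y, alpha)
    nz = np.flatnonzero(final.coef_)
    weights = {str(variant_ids[j]): float(final.coef_[j]) for j in nz}
    return PredictionModel(
        gene_id=gene_id,
        layer=layer,
        weights=weights,
        intercept=float(final.intercept_),
        r_cv=float(r_cv),
        r_cv_p=float(r_cv_p),
        conditional=conditional,
        alpha=alpha,
    )


def impute_expression(model: PredictionModel, genotypes: VariantTable) -> np.ndarray:
    """Imputed expression: intercept + sum_i w_i * dosage_i."""
    if not model.weights:
        return np.full(genotypes.n_samples, model.intercept)
    vids = list(model.weights)
    missing = [v for v in vids if v not in set(genotypes.variant_id)]
    if missing:
        raise KeyError(f"model variants missing from genotypes: {missing}")
    idx = genotypes.index_of(vids)
    w = np.array([model.weights[v] for v in vids])
    return model.intercept + genotypes.dosage[:, idx] @ w


def conditional_residualize(
    gene_id: str,
    layer: str,
    expression: np.ndarray,
    imputed_others: list[np.ndarray],
) -> ConditionalExpression:
    """Regress the focal expression on other layers' imputed expression.

    Collinear regressors are dropped (later ones) with a warning.  Near-
    collinearity counts: when two layers share most of their genetic
    signal (e.g. no translational attenuation), their imputations are
    almost identical and jointly fitting both amplifies a noise direction
    by the inverse of their tiny angle — so a candidate whose R^2 on the
    already-included regressors exceeds 0.95 is dropped too.  The residual
    e_k is exactly orthogonal to every retained regressor; the conditioned
    expression R_k adds back the per-gene mean.
    """
    if not imputed_others:
        raise ValueError("need at least one other-layer imputed expression vector")
    y = np.asarray(expression, float)
    cols = [np.ones_like(y)]
    for v in imputed_others:
        v = np.asarray(v, float)
        Z0 = np.column_stack(cols)
        coef0, *_ = np.linalg.lstsq(Z0, v, rcond=None)
        resid0 = v - Z0 @ coef0
        denom = ((v - v.mean()) ** 2).sum()
        r2_on_included = 1.0 - (resid0 @ resid0) / denom if denom > 0 else 1.0
        if r2_on_included > 0.95:
            warnings.warn(f"gene {gene_id}: collinear imputed regressor dropped")
        else:
            cols.append(v)
    Z = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(Z, y, rcond=None)
    resid = y - Z @ coef
    return ConditionalExpression(
        gene_id=gene_id,
        layer=layer,
        residual=resid,
        slopes=coef[1:],
        center_offset=float(y.mean()),
        conditioned=None,  # set in __post_init__
    )


def compute_rc2(
    original: PredictionModel, conditional: PredictionModel, genotypes: VariantTable
) -> float:
    """R_c^2: squared correlation of the two models' imputed expression.

    A constant imputation on either side (all genetic signal removed by
    conditioning, or none to begin with) gives R_c^2 = 0.
    """
    a = impute_expression(original, genotypes)
    b = impute_expression(conditional, genotypes)
    if np.std(a) < 1e-12 or np.std(b) < 1e-12:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1] ** 2)


def permutation_null_rc2(
    original: PredictionModel,
    expression: np.ndarray,
    imputed_others: list[np.ndarray],
    X: np.ndarray,
    variant_ids: np.ndarray,
    cond_alpha: float,
    observed_rc2: float,
    n_perm: int = 50,
    seed: int = 0,
) -> float:
    """Empirical p of the observed R_c^2 against a permutation null.

    Each permutation applies one shared shuffle of sample labels to all
    other layers' imputed vectors (preserving their mutual correlation),
    rebuilds the conditional model at the penalty chosen for the observed
    conditional fit, and recomputes R_c^2.  p = (#{perm <= obs} + 1) /
    (n_perm + 1): small observed R_c^2 relative to the null is evidence of
    cross-layer sharing.
    """
    rng = np.random.default_rng(seed)
    n = len(expression)
    imp_orig = original.intercept + X @ np.array(
        [original.weights.get(str(v), 0.0) for v in variant_ids]
    )
    if np.std(imp_orig) < 1e-12:
        raise ValueError("original model imputation is constant")
    null = np.empty(n_perm)
    failures = 0
    for b in range(n_perm):
        perm = rng.permutation(n)
        shuffled = [v[perm] for v in imputed_others]
        try:
            ce = conditional_residualize(original.gene_id, original.layer, expression, shuffled)
            m = _fit_enet(X, ce.conditioned, cond_alpha)
            imp_cond = m.intercept_ + X @ m.coef_
            if np.std(imp_cond) < 1e-12:
                null[b] = 0.0
            else:
                null[b] = np.corrcoef(imp_orig, imp_cond)[0, 1] ** 2
        except Exception:  # pragma: no cover - degenerate permutation
            null[b] = np.nan
            failures += 1
    if failures > n_perm / 2:
        raise RuntimeError(
            f"gene {original.gene_id}: conditional model failed in {failures}/{n_perm} permutations"
        )
    valid = null[~np.isnan(null)]
    return float((np.sum(valid <= observed_rc2) + 1.0) / (valid.size + 1.0))


def classify_gene(fdr: float, rc2: float, fdr_cut: float = 0.1,
                  shared_rc2: float = 0.5, specific_rc2: float = 0.9) -> str:
    """shared iff FDR < cut and R_c^2 < 0.5; specific iff FDR > cut and
    R_c^2 > 0.9; otherwise unclassified."""
    if fdr < fdr_cut and rc2 < shared_rc2:
        return "shared"
    if fdr > fdr_cut and rc2 > specific_rc2:
        return "specific"
    return "unclassified"


def bh_fdr(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(pvalues, float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(adj, 0, 1)
    return out


def specificity_scan(
    layers: dict[str, OmicsMatrix],
    genotypes: VariantTable,
    annotation: pd.DataFrame,
    n_perm: int = 50,
    seed: int = 0,
    n_folds: int = 10,
    maf_min: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Full shared/specific classification over genes x focal layers.

    Entry criteria per gene x layer: a retained original model in the
    focal layer and at least one retained original model in another layer
    (otherwise conditioning is undefined; such pairs are skipped).
    Returns (calls table, dict of original models keyed by (gene, layer)).
    """
    rng = np.random.default_rng(seed)
    originals: dict[tuple[str, str], PredictionModel] = {}
    cis_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for _, grow in annotation.iterrows():
        gid = grow["gene_id"]
        idx = cis_variant_indices(cis_window(grow), genotypes, maf_min)
        if idx.size == 0:
            continue
        cis_cache[gid] = (genotypes.dosage[:, idx], genotypes.variant_id[idx])
        for layer, mx in layers.items():
            if gid not in mx.values.columns:
                continue
            originals[(gid, layer)] = train_prediction_model(
                gid, layer, cis_cache[gid][0], mx.values[gid].to_numpy(),
                cis_cache[gid][1], n_folds=n_folds,
                seed=int(rng.integers(2**31 - 1)),
            )
    rows = []
    for (gid, layer), orig in originals.items():
        if not orig.retained:
            continue
        others = [
            originals[(gid, lay)]
            for lay in layers
            if lay != layer and (gid, lay) in originals and originals[(gid, lay)].retained
        ]
        if not others:
            continue
        X, vids = cis_cache[gid]
        y = layers[layer].values[gid].to_numpy(float)
        imputed_others = [impute_expression(m, genotypes) for m in others]
        ce = conditional_residualize(gid, layer, y, imputed_others)
        # the conditional model refits the same predictor class at the
        # original model's penalty, so R_c^2 compares before/after
        # conditioning without re-tuning noise
        cond = train_prediction_model(
            gid, layer, X, ce.conditioned, vids, n_folds=n_folds,
            seed=int(rng.integers(2**31 - 1)), conditional=True,
            alpha=orig.alpha,
        )
        rc2 = compute_rc2(orig, cond, genotypes)
        try:
            emp_p = permutation_null_rc2(
                orig, y, imputed_others, X, vids, cond.alpha, rc2,
                n_perm=n_perm, seed=int(rng.integers(2**31 - 1)),
            )
        except (RuntimeError, ValueError) as e:
            logger.warning("gene %s/%s unclassifiable: %s", gid, layer, e)
            continue
        rows.append({"gene_id": gid, "layer": layer, "rc2": rc2, "empirical_p": emp_p})
    calls = pd.DataFrame(rows, columns=["gene_id", "layer", "rc2", "empirical_p"])
    if len(calls):
        calls["fdr"] = bh_fdr(calls["empirical_p"].to_numpy())
        calls["label"] = [
            classify_gene(f, r) for f, r in zip(calls["fdr"], calls["rc2"])
        ]
    else:
        calls["fdr"] = []
        calls["label"] = []
    return calls, originals
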