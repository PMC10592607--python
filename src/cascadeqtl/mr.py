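"""Mendelian randomization between molecular layers and the outcome trait.

Two-sample MR (summary statistics): LD clumping selects approximately
independent instrument SNPs per gene; the inverse-variance-weighted (IVW)
estimator gives the causal effect and the Egger intercept screens for
directional horizontal pleiotropy.  A gene passes when the IVW effect
survives FDR < 0.1 and the Egger intercept p > 0.05.

One-sample MR (individual level): two-stage least squares between adjacent
omics layers (mRNA -> ribosome occupancy, ribosome occupancy -> protein),
with the first-stage F statistic as an instrument-strength check; the two
pathway verdicts combine into a cascade class (both- / single- /
none-passed).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import MRResult, VariantTable
from .specificity import bh_fdr

logger = logging.getLogger(__name__)

PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class InstrumentSet:
    gene_id: str
    layer: str
    variant_ids: list[str]
    exposure_beta: np.ndarray
    exposure_se: np.ndarray
    outcome_beta: np.ndarray
    outcome_se: np.ndarray
    clump_r2: float = 0.5
    clump_kb: float = 1000.0

    @property
    def n(self) -> int:
        return len(self.variant_ids)


def ld_clump(
    stats_df: pd.DataFrame,
    genotypes: VariantTable,
    r2_max: float = 0.5,
    window_kb: float = 1000.0,
    p_threshold: float = 0.05,
) -> list[str]:
    """Greedy LD clumping: repeatedly take the smallest-p variant below the
    threshold and discard all variants within the window whose dosage r^2
    with it exceeds ``r2_max``.  ``stats_df`` needs variant_id, pos, pvalue
    columns sorted by position.  Returns the retained index-variant ids."""
    df = stats_df[stats_df["pvalue"] < p_threshold]
    if len(df) == 0:
        return []
    idx = genotypes.index_of(df["variant_id"])
    pos = df["pos"].to_numpy(float)
    pvals = df["pvalue"].to_numpy(float)
    X = genotypes.dosage[:, idx]
    Xs = (X - X.mean(axis=0)) / X.std(axis=0)
    n = X.shape[0]
    alive = np.ones(len(df), bool)
    keep = []
    order = np.argsort(pvals, kind="stable")
    for j in order:
        if not alive[j]:
            continue
        keep.append(j)
        near = alive & (np.abs(pos - pos[j]) <= window_kb * 1000.0)
        r2 = (Xs[:, near].T @ Xs[:, j] / n) ** 2
        drop = np.flatnonzero(near)[r2 > r2_max]
        alive[drop] = False
        alive[j] = False
    keep.sort()
    return [str(v) for v in df["variant_id"].to_numpy()[keep]]


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Flips the outcome beta when effect/other alleles are swapped; drops
    strand-ambiguous palindromic (A/T, C/G) variants and allele-incompatible
    variants (drops are logged).  Both frames need variant_id,
    effect_allele, other_allele, beta, se.
    """
    merged = exposure.merge(outcome, on="variant_id", suffixes=("_exp", "_out"))
    rows = []
    for _, r in merged.iterrows():
        ea, oa = r["effect_allele_exp"], r["other_allele_exp"]
        eb, ob = r["effect_allele_out"], r["other_allele_out"]
        if (ea, oa) in PALINDROMIC:
            logger.info("dropping palindromic variant %s", r["variant_id"])
            continue
        if (ea, oa) == (eb, ob):
            flip = 1.0
        elif (ea, oa) == (ob, eb):
            flip = -1.0
        else:
            logger.info("dropping allele-incompatible variant %s", r["variant_id"])
            continue
        rows.append(
            {
                "variant_id": r["variant_id"],
                "effect_allele": ea,
                "other_allele": oa,
                "beta_exp": r["beta_exp"],
                "se_exp": r["se_exp"],
                "beta_out": flip * r["beta_out"],
                "se_out": r["se_out"],
            }
        )
    return pd.DataFrame(
        rows,
        columns=["variant_id", "effect_allele", "other_allele",
                 "beta_exp", "se_exp", "beta_out", "se_out"],
    )


def ivw(inst: InstrumentSet, outcome: str = "outcome") -> MRResult:
    """Fixed-effect inverse-variance-weighted estimate.

    Weighted regression of outcome betas on exposure betas through the
    origin with weights 1/se_out^2: estimate = sum(w x y)/sum(w x^2),
    se = sqrt(1/sum(w x^2)).  A single instrument reduces to the Wald
    ratio with first-order delta-method se.
    """
    x, y, so = inst.exposure_beta, inst.outcome_beta, inst.outcome_se
    if inst.n == 0:
        raise ValueError("no instruments")
    w = 1.0 / so**2
    denom = np.sum(w * x**2)
    est = float(np.sum(w * x * y) / denom)
    se = float(np.sqrt(1.0 / denom))
    z = est / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MRResult(
        gene_id=inst.gene_id, exposure=inst.layer, outcome=outcome,
        method="IVW", estimate=est, se=se, pvalue=p, n_instruments=inst.n,
    )


def egger(inst: InstrumentSet, outcome: str = "outcome") -> MRResult:
    """MR-Egger: weighted regression with a free intercept.

    Exposure betas are oriented positive first (the standard Egger
    convention); the intercept and its p-value diagnose directional
    horizontal pleiotropy.  Requires >= 3 instruments.
    """
    if inst.n < 3:
        raise ValueError("Egger regression needs >= 3 instruments")
    sign = np.sign(inst.exposure_beta)
    sign[sign == 0] = 1.0
    x = inst.exposure_beta * sign
    y = inst.outcome_beta * sign
    w = 1.0 / inst.outcome_se**2
    W = np.diag(w)
    Z = np.column_stack([np.ones_like(x), x])
    XtWX = Z.T @ W @ Z
    coef = np.linalg.solve(XtWX, Z.T @ W @ y)
    dof = inst.n - 2
    # model-based (fixed-effect) covariance: the reported outcome standard
    # errors are taken at face value rather than rescaled by residual
    # heterogeneity, which keeps the intercept test powered against
    # directional pleiotropy instead of absorbing it into the error term
    cov = np.linalg.inv(XtWX)
    ses = np.sqrt(np.diag(cov))
    t_int = coef[0] / ses[0]
    t_slope = coef[1] / ses[1]
    return MRResult(
        gene_id=inst.gene_id, exposure=inst.layer, outcome=outcome,
        method="Egger", estimate=float(coef[1]), se=float(ses[1]),
        pvalue=float(2 * stats.t.sf(abs(t_slope), dof)),
        intercept=float(coef[0]), intercept_p=float(2 * stats.t.sf(abs(t_int), dof)),
        n_instruments=inst.n,
    )


def two_sample_verdict(ivw_res: MRResult, egger_res: MRResult | None) -> str:
    """pass iff FDR < 0.1 and Egger intercept p > 0.05.

    ``ivw_res.fdr`` must be filled in (BH across the analysis family)
    before calling.  With no Egger fit (< 3 instruments) pleiotropy is
    untestable and the effect criterion alone decides.
    """
    if np.isnan(ivw_res.fdr):
        raise ValueError("fdr not computed; run BH across all tested genes first")
    effect_ok = ivw_res.fdr < 0.1
    if egger_res is not None and not np.isnan(egger_res.intercept_p):
        if effect_ok and egger_res.intercept_p > 0.05:
            return "pass"
        if effect_ok:
            return "fail_pleiotropy"
        return "fail_effect"
    return "pass" if effect_ok else "fail_effect"


def tsls(
    exposure: np.ndarray,
    outcome: np.ndarray,
    instruments: np.ndarray,
    gene_id: str = "",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> MRResult:
    """Two-stage least squares with correct (observed-exposure) standard errors.

    Stage 1 regresses the exposure on the instruments; stage 2 regresses
    the outcome on the fitted exposure.  Standard errors use residuals
    from the *observed* exposure at the 2SLS coefficients.  The
    first-stage F statistic is reported; F < 10 sets the weak-instrument
    flag.  Rank-deficient instrument columns are dropped.
    """
    y = np.asarray(outcome, float)
    x = np.asarray(exposure, float)
    Z = np.atleast_2d(np.asarray(instruments, float))
    if Z.shape[0] != x.size:
        Z = Z.T
    n = x.size
    # drop collinear instrument columns
    keep = []
    for j in range(Z.shape[1]):
        cand = np.column_stack([np.ones(n)] + [Z[:, k] for k in keep] + [Z[:, j]])
        if np.linalg.matrix_rank(cand) == cand.shape[1]:
            keep.append(j)
        else:
            logger.warning("dropping collinear instrument column %d", j)
    Z = Z[:, keep]
    k = Z.shape[1]
    if k < 1:
        raise ValueError("no usable instruments")
    if n <= k + 2:
        raise ValueError("need n > n_instruments + 2")
    Z1 = np.column_stack([np.ones(n), Z])
    # stage 1
    c1, *_ = np.linalg.lstsq(Z1, x, rcond=None)
    xhat = Z1 @ c1
    rss1 = np.sum((x - xhat) ** 2)
    tss1 = np.sum((x - x.mean()) ** 2)
    f_stat = ((tss1 - rss1) / k) / (rss1 / (n - k - 1))
    # stage 2
    X2 = np.column_stack([np.ones(n), xhat])
    c2, *_ = np.linalg.lstsq(X2, y, rcond=None)
    # correct 2SLS se: residuals at observed exposure
    Xobs = np.column_stack([np.ones(n), x])
    resid = y - Xobs @ c2
    sigma2 = float(resid @ resid) / (n - 2)
    cov = sigma2 * np.linalg.inv(X2.T @ X2)
    ses = np.sqrt(np.diag(cov))
    t_slope = c2[1] / ses[1]
    t_int = c2[0] / ses[0]
    return MRResult(
        gene_id=gene_id, exposure=exposure_name, outcome=outcome_name,
        method="TSLS", estimate=float(c2[1]), se=float(ses[1]),
        pvalue=float(2 * stats.t.sf(abs(t_slope), n - 2)),
        intercept=float(c2[0]), intercept_p=float(2 * stats.t.sf(abs(t_int), n - 2)),
        f_statistic=float(f_stat), n_instruments=k,
        weak_instruments=bool(f_stat < 10),
    )


def one_sample_verdict(res: MRResult) -> str:
    """pass iff FDR < 0.1 and stage-2 intercept p > 0.05 (pleiotropy proxy)."""
    if np.isnan(res.fdr):
        raise ValueError("fdr not computed")
    if res.fdr < 0.1 and res.intercept_p > 0.05:
        return "pass"
    if res.fdr < 0.1:
        return "fail_pleiotropy"
    return "fail_effect"


@dataclass
class CascadeVerdict:
    gene_id: str
    upstream_pass: bool   # mRNA -> ribosome occupancy
    downstream_pass: bool  # ribosome occupancy -> protein

    @property
    def cascade_class(self) -> str:
        if self.upstream_pass and self.downstream_pass:
            return "both-passed"
        if self.upstream_pass or self.downstream_pass:
            return "single-passed"
        return "none-passed"


def cascade_classify(
    gene_id: str, upstream: MRResult | None, downstream: MRResult | None
) -> CascadeVerdict:
    """Combine the two adjacent-layer verdicts; an untested pathway counts
    as not passed."""
    up = upstream is not None and upstream.verdict == "pass"
    down = downstream is not None and downstream.verdict == "pass"
    return CascadeVerdict(gene_id=gene_id, upstream_pass=up, downstream_pass=down)


def one_sample_mr_gene(
    gene_row,
    upstream_expr: np.ndarray,
    downstream_expr: np.ndarray,
    genotypes: VariantTable,
    nominal_stats: pd.DataFrame,
    gene_id: str = "",
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    r2_max: float = 0.5,
    window_kb: float = 1000.0,
    p_threshold: float = 0.05,
) -> MRResult | None:
    """One-sample 2SLS for one adjacent-layer pathway.

    Instruments are the exposure layer's clumped cis SNPs with nominal
    p < 0.05; returns None (untested) when none survive."""
    ids = ld_clump(nominal_stats, genotypes, r2_max, window_kb, p_threshold)
    if not ids:
        return None
    Z = genotypes.dosage[:, genotypes.index_of(ids)]
    return tsls(upstream_expr, downstream_expr, Z, gene_id=gene_id,
                exposure_name=exposure_name, outcome_name=outcome_name)


def one_sample_cascade(
    layers: dict,
    genotypes: VariantTable,
    annotation: pd.DataFrame,
    r2_max: float = 0.5,
    window_kb: float = 1000.0,
    p_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[MRResult]]:
    """One-sample MR along the cascade for every gene.

    Tests mRNA -> ribosome occupancy and ribosome occupancy -> protein per
    gene (instruments: the exposure layer's clumped cis SNPs with nominal
    p < ``p_threshold``), applies BH-FDR across the whole family and
    returns (cascade verdict table, MR results).
    """
    from .qtl import cis_window, nominal_scan

    pathways = [("mrna", "ribo"), ("ribo", "protein")]
    results: list[MRResult] = []
    per_gene: dict[str, dict[str, MRResult]] = {}
    for _, grow in annotation.iterrows():
        gid = grow["gene_id"]
        for up, down in pathways:
            if (gid not in layers[up].values.columns
                    or gid not in layers[down].values.columns):
                continue
            up_expr = layers[up].values[gid].to_numpy()
            down_expr = layers[down].values[gid].to_numpy()
            scan = nominal_scan(cis_window(grow), genotypes, up_expr)
            if scan is None:
                continue
            res = one_sample_mr_gene(
                grow, up_expr, down_expr, genotypes, scan, gene_id=gid,
                exposure_name=up, outcome_name=down,
                r2_max=r2_max, window_kb=window_kb, p_threshold=p_threshold,
            )
            if res is not None:
                results.append(res)
                per_gene.setdefault(gid, {})[f"{up}->{down}"] = res
    apply_family_fdr(results)
    for r in results:
        r.verdict = one_sample_verdict(r)
    rows = []
    for gid in annotation["gene_id"]:
        path_res = per_gene.get(gid, {})
        v = cascade_classify(gid, path_res.get("mrna->ribo"), path_res.get("ribo->protein"))
        rows.append({
            "gene_id": gid, "upstream_pass": v.upstream_pass,
            "downstream_pass": v.downstream_pass, "cascade_class": v.cascade_class,
        })
    return pd.DataFrame(rows), results


def apply_family_fdr(results: list[MRResult]) -> None:
    """BH-FDR in place across one analysis family of MR results."""
    if not results:
        return
    fdrs = bh_fdr(np.array([r.pvalue for r in results]))
    for r, f in zip(results, fdrs):
        r.fdr = float(f)
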