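"""Quantification-matrix preprocessing: log-CPM, expression filtering,
outlier-sample flagging, quantile normalization, hidden-factor estimation
(PCA surrogate) and residualization.

All operations take and return :class:`~cascadeqtl.datatypes.OmicsMatrix`
objects and advance the processing-stage tag; residualized output is
standardized per gene (mean 0, sd 1)."""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import FactorSet, OmicsMatrix


def counts_to_log_cpm(counts: OmicsMatrix) -> OmicsMatrix:
    """log2 counts-per-million with a +0.5 count / +1 library pseudocount.

    value = log2((count + 0.5) / (library_size + 1) * 1e6), the documented
    behaviour of the standard cpm implementation, which avoids log(0) and is
    invariant to doubling every count of a sample up to the pseudocount.
    """
    if counts.stage != "raw_counts":
        raise ValueError(f"expected raw_counts stage, got {counts.stage}")
    v = counts.values.to_numpy(float)
    if (v < 0).any():
        raise ValueError("negative counts")
    lib = v.sum(axis=1)
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        bad = [counts.sample_ids[i] for i in zero]
        raise ValueError(f"zero-total samples: {bad}")
    logcpm = np.log2((v + 0.5) / (lib[:, None] + 1.0) * 1e6)
    return counts.advance(
        "log_cpm", pd.DataFrame(logcpm, index=counts.values.index, columns=counts.values.columns)
    )


def filter_low_expression(
    matrix: OmicsMatrix, threshold: float = 0.0, max_fraction: float = 0.75
) -> OmicsMatrix:
    """Drop genes low in *more than* ``max_fraction`` of samples.

    For count layers the conventional threshold is CPM < 1, i.e. 0 on the
    log2-CPM scale; for protein it is applied to the log abundance
    directly.  A gene is kept iff the fraction of samples strictly below
    ``threshold`` is <= ``max_fraction`` (strict "more than" semantics).
    Gene order of survivors is preserved.
    """
    frac_low = (matrix.values < threshold).mean(axis=0)
    keep = frac_low <= max_fraction
    return matrix.advance("filtered", matrix.values.loc[:, keep.to_numpy()])


def flag_outlier_samples(matrix: OmicsMatrix, z_cutoff: float = -5.0) -> list[str]:
    """Flag samples with anomalously low network connectivity.

    Connectivity of sample j = sum over i != j of cor(sample_i, sample_j)
    across genes (unsigned correlations are not folded: the raw Pearson r
    is summed).  Connectivities are z-scored across samples; a sample is
    flagged iff z < z_cutoff.  Constant samples are flagged unconditionally.
    """
    v = matrix.values.to_numpy(float)
    n = v.shape[0]
    if n < 10:
        raise ValueError("need >= 10 samples for connectivity z-scores")
    sds = v.std(axis=1)
    const = np.flatnonzero(sds == 0)
    if const.size:
        warnings.warn(f"constant samples flagged unconditionally: {const.tolist()}")
    ok = sds > 0
    vz = np.zeros_like(v)
    vz[ok] = (v[ok] - v[ok].mean(axis=1, keepdims=True)) / sds[ok, None]
    corr = vz @ vz.T / v.shape[1]
    connectivity = corr.sum(axis=1) - np.diag(corr)
    z = (connectivity - connectivity.mean()) / connectivity.std(ddof=1)
    flagged = set(np.flatnonzero(z < z_cutoff).tolist()) | set(const.tolist())
    return [matrix.sample_ids[i] for i in sorted(flagged)]


def quantile_normalize(matrix: OmicsMatrix) -> OmicsMatrix:
    """Force every sample onto the common distribution of order-statistic means.

    Each sample's sorted values are replaced by the across-sample mean of
    the order statistics; ties within a sample receive the mean of the
    reference values they would have occupied.  Idempotent within 1e-9.
    """
    v = matrix.values.to_numpy(float)
    if np.isnan(v).any():
        raise ValueError("missing values: impute before quantile normalization")
    order = np.argsort(v, axis=1, kind="stable")
    sorted_v = np.take_along_axis(v, order, axis=1)
    reference = sorted_v.mean(axis=0)
    out = np.empty_like(v)
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(v.shape[1])[None, :], axis=1)
    out = reference[ranks]
    # ties: average the reference values mapped to tied positions
    for i in range(v.shape[0]):
        row = v[i]
        uniq, inv, cnt = np.unique(row, return_inverse=True, return_counts=True)
        if uniq.size < row.size:
            sums = np.bincount(inv, weights=out[i])
            out[i] = (sums / cnt)[inv]
    return matrix.advance(
        "quantile_normalized",
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
    )


def estimate_hidden_factors(matrix: OmicsMatrix, n_factors: int) -> FactorSet:
    """Top principal components of the gene-standardized matrix.

    Serves as the deterministic surrogate for latent nuisance-factor
    estimation: factors are the left singular vectors (sample scores),
    mutually orthogonal, with per-factor fraction of variance explained.
    """
    v = matrix.values.to_numpy(float)
    n, m = v.shape
    if n_factors >= min(n, m):
        raise ValueError(f"n_factors={n_factors} must be < min(samples, genes)={min(n, m)}")
    sd = v.std(axis=0)
    sd[sd == 0] = 1.0
    x = (v - v.mean(axis=0)) / sd
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    ve = s**2 / (s**2).sum()
    scores = u[:, :n_factors] * s[:n_factors]
    return FactorSet(
        factors=pd.DataFrame(
            scores, index=matrix.values.index, columns=[f"PC{i + 1}" for i in range(n_factors)]
        ),
        variance_explained=ve[:n_factors],
    )


def select_n_factors(matrix: OmicsMatrix, max_factors: int = 30, tol: float = 0.01) -> int:
    """Elbow rule: number of leading factors clearly above noise.

    A factor counts while its variance explained exceeds both ``tol`` (1%
    by default) and the Marchenko-Pastur upper bulk edge for an iid matrix
    of the same shape — without the second term, every PC of a small
    matrix trivially clears a fixed 1%.  Returns the smallest k at which
    the next factor falls below that threshold (0 for pure noise at
    balanced shapes).
    """
    v = matrix.values.to_numpy(float)
    n, m = v.shape
    cap = min(max_factors, min(n, m) - 1)
    fs = estimate_hidden_factors(matrix, cap)
    mp_edge = (1.0 + np.sqrt(min(n, m) / max(n, m))) ** 2 / min(n, m)
    threshold = max(tol, mp_edge)
    below = np.flatnonzero(fs.variance_explained < threshold)
    return int(below[0]) if below.size else cap


def residualize(matrix: OmicsMatrix, factors: FactorSet) -> OmicsMatrix:
    """OLS out the factors per gene, then center and scale to sd 1.

    Genes whose residuals are constant (e.g. a gene exactly equal to a
    factor) cannot be scaled and are dropped with a warning.
    """
    if list(factors.factors.index) != matrix.sample_ids:
        raise ValueError("factor and matrix sample ids are not aligned")
    F = np.column_stack(
        [np.ones(len(matrix.sample_ids)), factors.factors.to_numpy(float)]
    )
    if np.linalg.matrix_rank(F) < F.shape[1]:
        raise ValueError("collinear factors")
    v = matrix.values.to_numpy(float)
    coef, *_ = np.linalg.lstsq(F, v, rcond=None)
    resid = v - F @ coef
    sd = resid.std(axis=0)
    dead = sd < 1e-12
    if dead.any():
        dropped = [matrix.gene_ids[i] for i in np.flatnonzero(dead)]
        warnings.warn(f"dropping genes with zero residual variance: {dropped}")
    resid = resid[:, ~dead]
    resid = (resid - resid.mean(axis=0)) / resid.std(axis=0)
    cols = [g for g, d in zip(matrix.gene_ids, dead) if not d]
    return matrix.advance(
        "residualized", pd.DataFrame(resid, index=matrix.values.index, columns=cols)
    )


def select_representative_isoform(
    protein: OmicsMatrix, isoform_to_gene: dict[str, str]
) -> OmicsMatrix:
    """Collapse protein isoforms to one row per gene by highest median
    abundance; median ties broken by lexicographically smallest isoform id.
    Unmapped isoforms are dropped with a warning."""
    unmapped = [iso for iso in protein.gene_ids if iso not in isoform_to_gene]
    if unmapped:
        warnings.warn(f"dropping unmapped isoforms: {unmapped}")
    chosen: dict[str, str] = {}
    best: dict[str, float] = {}
    for iso in sorted(set(protein.gene_ids) - set(unmapped)):
        gene = isoform_to_gene[iso]
        med = float(protein.values[iso].median())
        if gene not in chosen or med > best[gene]:
            chosen[gene], best[gene] = iso, med
    genes = sorted(chosen)
    out = protein.values[[chosen[g] for g in genes]].copy()
    out.columns = genes
    return OmicsMatrix(layer=protein.layer, stage=protein.stage, values=out)


def impute_missing_min(matrix: OmicsMatrix) -> OmicsMatrix:
    """Replace missing protein abundances by the per-gene observed minimum."""
    v = matrix.values.copy()
    v = v.fillna(v.min(axis=0))
    return OmicsMatrix(layer=matrix.layer, stage=matrix.stage, values=v)


def preprocess_layer(
    matrix: OmicsMatrix,
    n_factors: int,
    cpm_threshold: float = 1.0,
    max_low_fraction: float = 0.75,
    z_cutoff: float = -5.0,
    elbow: bool = False,
) -> OmicsMatrix:
    """Full per-layer pipeline: (counts -> log-CPM ->) filter -> outlier
    removal -> quantile normalize -> PCA factors -> residualize.

    With ``elbow=True``, ``n_factors`` acts as a cap and the count actually
    removed is chosen by the 1%-marginal-variance elbow rule — appropriate
    when the matrix is small enough that a fixed large count would absorb
    genetic signal along with the nuisance structure.
    """
    if matrix.stage == "raw_counts":
        matrix = counts_to_log_cpm(matrix)
        threshold = np.log2(cpm_threshold) if cpm_threshold > 0 else -np.inf
    else:
        threshold = cpm_threshold
    matrix = filter_low_expression(matrix, threshold, max_low_fraction)
    bad = flag_outlier_samples(matrix, z_cutoff)
    if bad:
        matrix = OmicsMatrix(
            layer=matrix.layer, stage=matrix.stage, values=matrix.values.drop(index=bad)
        )
    matrix = quantile_normalize(matrix)
    n_factors = min(n_factors, min(matrix.values.shape) - 2)
    if elbow and n_factors > 0:
        n_factors = min(n_factors, select_n_factors(matrix, max_factors=n_factors))
    if n_factors > 0:
        factors = estimate_hidden_factors(matrix, n_factors)
        return residualize(matrix, factors)
    empty = FactorSet(
        factors=pd.DataFrame(index=matrix.values.index), variance_explained=np.array([])
    )
    return residualize(matrix, empty)
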