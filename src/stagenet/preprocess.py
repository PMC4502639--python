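"""Batch adjustment and gene filtering for merged expression matrices.

``batch_adjust`` implements the parametric empirical-Bayes location/scale
batch-correction model widely used for merging microarray cohorts: per gene,
additive batch effects are shrunk toward a normal prior and multiplicative
effects toward an inverse-gamma prior, with prior hyperparameters estimated
by method of moments across genes, while the tumor/normal group effect is
protected as a covariate in the standardization model.

``svd_filter`` removes a dominant "steady-state" eigenfeature (a rank-1
component absorbing near-constant overall expression), reporting the
eigen-fraction spectrum and its normalized Shannon entropy.
``variance_filter`` is the usual nonspecific filter on gene variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simdata import ExpressionDataset

__all__ = ["batch_adjust", "svd_filter", "variance_filter", "SvdFilterReport"]


@dataclass
class SvdFilterReport:
    eigen_fractions: np.ndarray   # s_l^2 / sum s^2, length min(genes, samples)
    entropy: float                # normalized Shannon entropy in [0, 1]
    removed_indices: list[int]    # 1-based indices of subtracted eigenfeatures

    def to_dict(self) -> dict:
        return {
            "eigen_fractions": [float(x) for x in self.eigen_fractions],
            "entropy": float(self.entropy),
            "removed_indices": list(self.removed_indices),
        }


# ---------------------------------------------------------------------------
# Empirical-Bayes batch adjustment
# ---------------------------------------------------------------------------

def _postmean(g_hat, g_bar, n, d_star, t2):
    return (t2 * n * g_hat + d_star * g_bar) / (t2 * n + d_star)


def _postvar(sum2, n, a, b):
    return (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)


def _it_solve(s_data, g_hat, d_hat, g_bar, t2, a, b, conv=1e-4, max_iter=500):
    """Iterative joint posterior solution for one batch (vectors over genes)."""
    n = s_data.shape[1]
    g_old, d_old = g_hat.copy(), d_hat.copy()
    for _ in range(max_iter):
        g_new = _postmean(g_hat, g_bar, n, d_old, t2)
        sum2 = ((s_data - g_new[:, None]) ** 2).sum(axis=1)
        d_new = _postvar(sum2, n, a, b)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old


def batch_adjust(ds: ExpressionDataset) -> ExpressionDataset:
    """Remove additive and multiplicative batch effects, gene by gene.

    Single-batch input is returned unchanged.  Genes with zero pooled or
    within-batch variance cannot be scale-adjusted and are passed through
    unmodified (with a warning).  Matrix dimensions and the gene/sample
    ordering are preserved, and the gene-wise mean/variance scale of the
    input is restored after adjustment.
    """
    batches = ds.phenotype.loc[ds.sample_ids, "batch"].astype(str)
    batch_names = sorted(batches.unique())
    if len(batch_names) < 2:
        return ExpressionDataset(ds.expr.copy(), ds.phenotype.copy(), ds.truth)
    counts = batches.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"batch {small.index[0]!r} has fewer than 2 samples")

    Y = ds.expr.to_numpy(dtype=float)
    n_genes, n_arr = Y.shape
    groups = ds.phenotype.loc[ds.sample_ids, "group"].to_numpy()
    batch_arr = batches.to_numpy()

    # Design: one indicator per batch plus protected group covariates
    # (reference level dropped).
    batch_ind = np.stack([(batch_arr == b).astype(float) for b in batch_names], axis=1)
    group_levels = sorted(pd.unique(groups))
    if len(group_levels) > 1:
        cov = np.stack([(groups == g).astype(float) for g in group_levels[1:]], axis=1)
    else:
        cov = np.empty((n_arr, 0))
    design = np.hstack([batch_ind, cov])

    B_hat, *_ = np.linalg.lstsq(design, Y.T, rcond=None)  # (p, genes)
    n_per_batch = batch_ind.sum(axis=0)
    grand_mean = (n_per_batch / n_arr) @ B_hat[: len(batch_names)]
    resid = Y - (design @ B_hat).T
    var_pooled = (resid**2).mean(axis=1)
    stand_mean = grand_mean[:, None] + (cov @ B_hat[len(batch_names):]).T

    batch_cols = {b: np.flatnonzero(batch_arr == b) for b in batch_names}
    skip = var_pooled <= 0
    sd = np.sqrt(np.where(skip, 1.0, var_pooled))[:, None]
    Z = (Y - stand_mean) / sd

    for b in batch_names:
        if skip.all():
            break
        cols = batch_cols[b]
        skip |= Z[:, cols].var(axis=1, ddof=1) <= 0

    ok = ~skip
    Z_adj = Z.copy()
    if ok.any():
        for b in batch_names:
            cols = batch_cols[b]
            Zb = Z[np.ix_(ok, cols)]
            g_hat = Zb.mean(axis=1)
            d_hat = Zb.var(axis=1, ddof=1)
            # Method-of-moments priors across genes.
            g_bar = g_hat.mean()
            t2 = g_hat.var(ddof=1) if ok.sum() > 1 else 0.0
            m = d_hat.mean()
            s2 = d_hat.var(ddof=1) if ok.sum() > 1 else 0.0
            if s2 <= 0 or t2 <= 0:
                g_star, d_star = g_hat, np.maximum(d_hat, 1e-12)
            else:
                a = (2.0 * s2 + m**2) / s2
                bb = (m * s2 + m**3) / s2
                g_star, d_star = _it_solve(Zb, g_hat, d_hat, g_bar, t2, a, bb)
            Z_adj[np.ix_(ok, cols)] = (Zb - g_star[:, None]) / np.sqrt(
                np.maximum(d_star, 1e-12)
            )[:, None]

    out = Y.copy()
    out[ok] = (Z_adj * sd + stand_mean)[ok]
    if skip.any():
        warnings.warn(
            f"{int(skip.sum())} gene(s) with zero pooled or within-batch "
            "variance passed through unadjusted"
        )
    expr = pd.DataFrame(out, index=ds.expr.index, columns=ds.expr.columns)
    return ExpressionDataset(expr, ds.phenotype.copy(), ds.truth)


# ---------------------------------------------------------------------------
# SVD steady-state eigenfeature filter
# ---------------------------------------------------------------------------

def svd_filter(
    matrix: pd.DataFrame, steady_state_threshold: float = 0.90
) -> tuple[pd.DataFrame, SvdFilterReport]:
    """Subtract the first eigenfeature if it dominates the spectrum.

    The SVD is taken of the matrix as-is (no gene centering), so a large
    shared offset -- steady-state expression -- loads on the first
    eigenfeature.  If its eigen-fraction ``s_1^2 / sum s^2`` reaches
    ``steady_state_threshold`` the rank-1 component is subtracted and index 1
    recorded; otherwise the matrix passes through unchanged.  The report
    always carries the eigen-fraction spectrum and its normalized entropy
    ``-(1/log L) * sum p_l log p_l``.
    """
    X = matrix.to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("svd_filter needs at least 2 genes and 2 samples")
    if not np.any(X):
        raise ValueError("svd_filter: matrix is identically zero")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    frac = s**2 / (s**2).sum()
    L = len(frac)
    nz = frac[frac > 0]
    entropy = float(-(nz * np.log(nz)).sum() / np.log(L)) if L > 1 else 0.0
    removed: list[int] = []
    out = X
    if frac[0] >= steady_state_threshold:
        out = X - s[0] * np.outer(U[:, 0], Vt[0])
        removed.append(1)
    report = SvdFilterReport(frac, entropy, removed)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), report


def variance_filter(matrix: pd.DataFrame, drop_quantile: float = 0.5) -> pd.DataFrame:
    """Drop genes whose variance is strictly below the given quantile.

    Ties at the threshold are kept.  ``drop_quantile = 0`` retains all genes.
    """
    if not 0.0 <= drop_quantile < 1.0:
        raise ValueError("drop_quantile must lie in [0, 1)")
    variances = matrix.var(axis=1, ddof=1)
    threshold = float(np.quantile(variances.to_numpy(), drop_quantile))
    keep = variances.to_numpy() >= threshold
    if not keep.any():
        warnings.warn("variance_filter removed every gene")
    return matrix.loc[keep]
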