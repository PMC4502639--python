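"""Moderated-t differential expression with fold-change and FDR gating.

The two-group moderated t-statistic shrinks per-gene residual variances
toward a common prior: hyperparameters ``(d0, s0^2)`` are estimated by the
method of moments on log sample variances (digamma/trigamma matching), the
posterior variance is ``(d0 s0^2 + d s^2) / (d0 + d)``, and p-values come
from a t distribution with ``d0 + d`` degrees of freedom.  Genes are called
differentially expressed when they pass a fold-change and an FDR cut
simultaneously (the default |log2 FC| >= 1 is "twofold", FDR < 0.05).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import special, stats

from .simdata import ExpressionDataset

__all__ = ["moderated_t", "moderated_t_matrix", "bh_adjust", "select_degs"]


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        return math.inf
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled-F model to sample variances.

    Returns ``(d0, s0sq)``: the prior degrees of freedom (may be inf) and the
    prior variance.  Genes with zero variance are excluded from estimation.
    """
    ok = s2 > 0
    if not ok.any():
        return math.inf, 0.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + math.log(df / 2.0)
    emean = float(e.mean())
    n = len(e)
    if n > 1:
        evar = float(((e - emean) ** 2).sum() / (n - 1)) - float(
            special.polygamma(1, df / 2.0)
        )
    else:
        evar = 0.0
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0sq = math.exp(emean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0))
    else:
        d0 = math.inf
        s0sq = math.exp(emean)
    return d0, s0sq


def moderated_t_matrix(
    X_a: np.ndarray, X_b: np.ndarray, prior_df: float | None = None
) -> pd.DataFrame:
    """Moderated two-sample t-tests on raw group matrices (genes x samples).

    ``prior_df`` overrides the estimated d0 (0 gives the ordinary pooled t);
    by default d0 is estimated from the data.  Returns one row per gene with
    logFC = mean(b) - mean(a).
    """
    X_a = np.asarray(X_a, dtype=float)
    X_b = np.asarray(X_b, dtype=float)
    n_a, n_b = X_a.shape[1], X_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs at least 2 samples")
    df_resid = n_a + n_b - 2
    mean_a, mean_b = X_a.mean(axis=1), X_b.mean(axis=1)
    logfc = mean_b - mean_a
    ss = ((X_a - mean_a[:, None]) ** 2).sum(axis=1) + (
        (X_b - mean_b[:, None]) ** 2
    ).sum(axis=1)
    s2 = ss / df_resid
    c = math.sqrt(1.0 / n_a + 1.0 / n_b)

    with np.errstate(divide="ignore", invalid="ignore"):
        t_ord = np.where(s2 > 0, logfc / (np.sqrt(s2) * c), 0.0)

    d0, s0sq = _fit_f_dist(s2, df_resid) if prior_df is None else (prior_df, 0.0)
    if prior_df is not None and prior_df > 0:
        # With an explicit finite prior df, still moment-match the scale.
        _, s0sq = _fit_f_dist(s2, df_resid)
    df_pooled = float(df_resid * len(s2))  # cap: total residual df
    if math.isinf(d0):
        s2_post = np.full_like(s2, s0sq)
        df_total = np.full_like(s2, df_pooled)
    else:
        s2_post = (d0 * s0sq + df_resid * s2) / (d0 + df_resid)
        df_total = np.full_like(s2, min(d0 + df_resid, df_pooled))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_mod = np.where(s2_post > 0, logfc / (np.sqrt(s2_post) * c), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t_mod), df_total)
    p = np.clip(p, 0.0, 1.0)
    q = bh_adjust(p)
    return pd.DataFrame(
        {
            "logFC": logfc,
            "t_ordinary": t_ord,
            "s2": s2,
            "t_moderated": t_mod,
            "df_total": df_total,
            "p_value": p,
            "q_value": q,
            "selected": False,
            "direction": "none",
        }
    )


def moderated_t(
    ds: ExpressionDataset,
    group_a: str = "normal",
    group_b: str = "tumor",
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Moderated t-table for ``group_b`` versus ``group_a`` samples of ``ds``."""
    a_cols = ds.samples_in_group(group_a)
    b_cols = ds.samples_in_group(group_b)
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError(
            f"need >=2 samples per group, got {len(a_cols)} {group_a!r} and "
            f"{len(b_cols)} {group_b!r}"
        )
    table = moderated_t_matrix(
        ds.expr[a_cols].to_numpy(), ds.expr[b_cols].to_numpy(), prior_df=prior_df
    )
    table.index = ds.expr.index
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_degs(
    table: pd.DataFrame, lfc_min: float = 1.0, fdr_max: float = 0.05
) -> pd.DataFrame:
    """Flag genes passing both the fold-change and FDR gates.

    Returns a copy of the table with ``selected`` and ``direction`` filled
    in; ``direction`` is "up"/"down" for selected genes, "none" otherwise.
    """
    out = table.copy()
    sel = (out["logFC"].abs() >= lfc_min) & (out["q_value"] < fdr_max)
    out["selected"] = sel
    out["direction"] = np.where(
        sel, np.where(out["logFC"] > 0, "up", "down"), "none"
    )
    return out
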