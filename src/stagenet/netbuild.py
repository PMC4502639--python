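"""Signed weighted coexpression networks, modules and trait statistics.

The signed soft-thresholded adjacency is ``a_ij = ((1 + cor_ij) / 2)^beta``
(anticorrelated genes map near zero, so module membership respects the sign
of coexpression); the topological overlap measure (TOM) augments direct
adjacency with shared-neighborhood strength.  Modules are branches of an
average-linkage dendrogram of ``1 - TOM`` cut at a fixed fraction of the
maximal merge height, with small branches collected into the reserved
"grey" label.  Per-module eigengenes, gene significance (GS), module
significance (MS), module-trait correlations and intramodular scaled
connectivity (K) follow the standard weighted-network definitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import minimize_scalar
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust

__all__ = [
    "signed_adjacency",
    "scale_free_fit",
    "pick_soft_power",
    "tom_similarity",
    "detect_modules",
    "module_eigengene",
    "gene_significance",
    "module_significance",
    "module_trait_correlation",
    "scaled_connectivity",
    "power_law_test",
    "ModuleProfile",
    "profile_modules",
    "module_color_aliases",
    "GREY",
]

GREY = "grey"

# Cosmetic color aliases in the conventional largest-first order.
_COLOR_ORDER = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan", "midnightblue",
    "lightcyan", "grey60", "lightgreen", "lightyellow", "royalblue",
]


def module_color_aliases(assignment: pd.Series) -> dict[str, str]:
    """Map size-ranked module labels to conventional color names (cosmetic)."""
    labels = [l for l in assignment.unique() if l != GREY]
    sizes = assignment.value_counts()
    labels.sort(key=lambda l: (-sizes[l], l))
    return {
        lab: (_COLOR_ORDER[i] if i < len(_COLOR_ORDER) else f"color_{i + 1}")
        for i, lab in enumerate(labels)
    }


def _pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Gene-gene Pearson correlations; zero-variance genes correlate 0."""
    sd = X.std(axis=1)
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance gene(s): correlations set to 0"
        )
    Xc = X - X.mean(axis=1, keepdims=True)
    denom = np.where(zero, 1.0, sd * np.sqrt(X.shape[1]))
    Z = Xc / denom[:, None]
    cor = Z @ Z.T
    cor[zero, :] = 0.0
    cor[:, zero] = 0.0
    np.fill_diagonal(cor, 1.0)
    return np.clip(cor, -1.0, 1.0)


def signed_adjacency(X: pd.DataFrame, beta: int = 18) -> pd.DataFrame:
    """Signed soft-thresholded adjacency of a genes x samples matrix.

    ``a_ij = ((1 + cor_ij)/2)^beta`` with a zero diagonal.
    """
    if int(beta) != beta or beta < 1:
        raise ValueError("beta must be a positive integer")
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples to build a network")
    cor = _pearson_matrix(X.to_numpy(dtype=float))
    adj = ((1.0 + cor) / 2.0) ** beta
    np.fill_diagonal(adj, 0.0)
    return pd.DataFrame(adj, index=X.index, columns=X.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> dict:
    """Signed R^2 of the log-log degree-distribution fit.

    Connectivities are discretized into ``n_bins`` equal-width bins (the
    usual scale-free-topology convention: equal-count bins would flatten the
    frequency axis by construction); the log10 bin frequency is regressed on
    the log10 bin-mean connectivity and the R^2 is signed by the negated
    slope sign, since scale-free topology demands a decreasing fit.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if len(k) < 2 or np.allclose(k, k[0]):
        raise ValueError("scale-free fit undefined for all-equal connectivities")
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    idx = np.clip(np.searchsorted(edges, k, side="right") - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        sel = idx == b
        if sel.sum() == 0:
            continue
        xs.append(np.log10(k[sel].mean()))
        ys.append(np.log10(sel.sum() / len(k)))
    xs, ys = np.array(xs), np.array(ys)
    if len(xs) < 3:
        raise ValueError("too few occupied bins for a log-log fit")
    slope, intercept, r, *_ = stats.linregress(xs, ys)
    if not np.isfinite(r):  # degenerate near-constant connectivities
        return {"r2": 0.0, "signed_r2": 0.0, "slope": float(slope),
                "intercept": float(intercept)}
    return {
        "r2": float(r**2),
        "signed_r2": float(r**2 * -np.sign(slope)),
        "slope": float(slope),
        "intercept": float(intercept),
    }


def pick_soft_power(
    X: pd.DataFrame,
    betas=range(1, 21),
    r2_target: float = 0.90,
    n_bins: int = 10,
) -> tuple[int, pd.DataFrame]:
    """Choose the smallest beta whose signed scale-free fit reaches the target.

    Falls back to the argmax of the signed R^2 (flagged in the fit table)
    when no power reaches the target.
    """
    if X.shape[0] < 50:
        warnings.warn("fewer than 50 genes: soft-power fit may be unstable")
    cor = _pearson_matrix(X.to_numpy(dtype=float))
    base = (1.0 + cor) / 2.0
    np.fill_diagonal(base, 0.0)
    rows = []
    for beta in betas:
        k = (base**beta).sum(axis=1)
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append(
            {"beta": int(beta), "signed_r2": fit["signed_r2"],
             "slope": fit["slope"], "mean_k": float(k.mean())}
        )
    table = pd.DataFrame(rows)
    reached = table[table["signed_r2"] >= r2_target]
    if len(reached):
        beta = int(reached.iloc[0]["beta"])
        table["target_reached"] = True
    else:
        beta = int(table.loc[table["signed_r2"].idxmax(), "beta"])
        table["target_reached"] = False
    return beta, table


def tom_similarity(adjacency: pd.DataFrame) -> pd.DataFrame:
    """Topological overlap: ``(sum_u a_iu a_uj + a_ij) / (min(k_i,k_j) + 1 - a_ij)``.

    The diagonal is 1 by convention.
    """
    A = adjacency.to_numpy(dtype=float)
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    k = A.sum(axis=1)
    numer = A @ A + A
    denom = np.minimum.outer(k, k) + 1.0 - A
    tom = numer / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=adjacency.index, columns=adjacency.columns)


def detect_modules(
    tom: pd.DataFrame,
    min_size: int = 30,
    cut_height_quantile: float = 0.99,
) -> pd.Series:
    """Cluster genes on ``1 - TOM`` and label branches as modules.

    Average-linkage hierarchical clustering is cut at ``cut_height_quantile``
    times the maximal merge height; branches with at least ``min_size`` genes
    become modules named "module_1" (largest) downward, everything else is
    "grey".
    """
    genes = list(tom.index)
    n = len(genes)
    if n < min_size:
        warnings.warn("fewer genes than min_size: all genes labeled grey")
        return pd.Series(GREY, index=tom.index, name="module")
    D = 1.0 - tom.to_numpy(dtype=float)
    D = (D + D.T) / 2.0
    np.fill_diagonal(D, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    heights = Z[:, 2]
    t = cut_height_quantile * float(heights.max())
    labels = fcluster(Z, t=t, criterion="distance")
    counts = pd.Series(labels).value_counts()
    big = counts[counts >= min_size]
    # Deterministic naming: by decreasing size, ties by first gene position.
    first_pos = {c: int(np.flatnonzero(labels == c)[0]) for c in big.index}
    ordered = sorted(big.index, key=lambda c: (-big[c], first_pos[c]))
    name = {c: f"module_{i + 1}" for i, c in enumerate(ordered)}
    out = pd.Series(
        [name.get(c, GREY) for c in labels], index=tom.index, name="module"
    )
    return out


def module_eigengene(
    X: pd.DataFrame, assignment: pd.Series
) -> tuple[pd.DataFrame, dict[str, float]]:
    """First-principal-component eigengenes per module.

    Each module submatrix is gene-standardized; the eigengene is the leading
    right-singular vector (unit norm over samples), sign-fixed so that it
    correlates nonnegatively with the module's mean expression profile.
    Returns (samples x modules eigengene frame, var_explained per module).
    """
    modules = [m for m in assignment.unique() if m != GREY]
    modules.sort(key=_module_sort_key)
    if not modules:
        raise ValueError("no non-grey modules to summarize")
    me = {}
    var_explained = {}
    for m in modules:
        genes = assignment.index[assignment == m]
        sub = X.loc[genes].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=0)
        sd[sd == 0] = 1.0
        Zm = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        U, s, Vt = np.linalg.svd(Zm, full_matrices=False)
        v = Vt[0]
        var_explained[m] = float(s[0] ** 2 / (s**2).sum()) if (s**2).sum() > 0 else 0.0
        mean_profile = Zm.mean(axis=0)
        if np.dot(v, mean_profile - mean_profile.mean()) < 0:
            v = -v
        me[m] = v
    return pd.DataFrame(me, index=X.columns), var_explained


def _module_sort_key(label: str):
    if label.startswith("module_"):
        try:
            return (0, int(label.split("_", 1)[1]))
        except ValueError:
            pass
    return (1, label)


def gene_significance(X: pd.DataFrame, trait: pd.Series | np.ndarray) -> pd.Series:
    """GS_i = |Pearson cor(gene i, trait)| across the network samples."""
    t = np.asarray(trait, dtype=float)
    if t.std() == 0:
        raise ValueError("trait is constant; gene significance undefined")
    Xv = X.to_numpy(dtype=float)
    tz = (t - t.mean()) / t.std()
    sd = Xv.std(axis=1)
    zero = sd == 0
    Xc = Xv - Xv.mean(axis=1, keepdims=True)
    denom = np.where(zero, 1.0, sd)
    r = (Xc / denom[:, None]) @ tz / Xv.shape[1]
    r[zero] = 0.0
    return pd.Series(np.abs(np.clip(r, -1, 1)), index=X.index, name="GS")


def module_significance(GS: pd.Series, assignment: pd.Series) -> pd.Series:
    """MS(module) = mean GS over the module's genes (grey included for
    reference but excluded from candidate ranking downstream)."""
    ms = GS.groupby(assignment).mean()
    ms.name = "MS"
    return ms


def module_trait_correlation(
    eigengenes: pd.DataFrame,
    trait: pd.Series | np.ndarray,
    r_min: float = 0.3,
) -> pd.DataFrame:
    """Module-trait Pearson correlations with Student-t p-values and BH q.

    A module is a candidate when ``|r| >= r_min``.
    """
    t = np.asarray(trait, dtype=float)
    n = len(t)
    if n < 3:
        raise ValueError("need at least 3 samples for module-trait correlation")
    if t.std() == 0:
        raise ValueError("trait is constant")
    rows = []
    for m in eigengenes.columns:
        me = eigengenes[m].to_numpy(dtype=float)
        r = float(np.corrcoef(me, t)[0, 1])
        if abs(r) >= 1.0:
            p = 0.0
        else:
            tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
            p = float(2.0 * stats.t.sf(abs(tstat), n - 2))
        rows.append({"module": m, "r": r, "p": p})
    out = pd.DataFrame(rows).set_index("module")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["candidate"] = out["r"].abs() >= r_min
    return out


def scaled_connectivity(adjacency: pd.DataFrame, assignment: pd.Series) -> pd.Series:
    """K_i = intramodular connectivity / max intramodular connectivity.

    Grey genes and single-gene modules get K = 0.
    """
    K = pd.Series(0.0, index=adjacency.index, name="K")
    for m in assignment.unique():
        if m == GREY:
            continue
        genes = assignment.index[assignment == m]
        sub = adjacency.loc[genes, genes].to_numpy(dtype=float)
        k = sub.sum(axis=1)
        kmax = k.max() if len(k) else 0.0
        if kmax > 0:
            K.loc[genes] = k / kmax
    return K


def power_law_test(degrees) -> tuple[float, int, float]:
    """Discrete power-law fit with KS-optimal lower cutoff.

    ``xmin`` minimizes the Kolmogorov-Smirnov distance between the empirical
    tail and the discrete maximum-likelihood power law; ``alpha_hat`` is the
    discrete MLE at that cutoff (zeta-function likelihood).  Returns
    ``(alpha_hat, xmin, ks_stat)``.
    """
    x = np.asarray(degrees)
    x = np.round(x).astype(int)
    x = x[x > 0]
    if len(x) < 20:
        raise ValueError("need at least 20 positive degree values")
    if np.all(x == x[0]):
        raise ValueError("power-law fit undefined for all-equal degrees")

    def mle_alpha(tail, xmin):
        logsum = float(np.log(tail).sum())
        n = len(tail)
        res = minimize_scalar(
            lambda a: n * np.log(special.zeta(a, xmin)) + a * logsum,
            bounds=(1.01, 8.0),
            method="bounded",
        )
        return float(res.x)

    def ks_distance(tail, xmin, alpha):
        support = np.arange(xmin, tail.max() + 1)
        z0 = special.zeta(alpha, xmin)
        pmf = support**(-alpha) / z0
        cdf_model = np.cumsum(pmf)
        cdf_emp = np.searchsorted(np.sort(tail), support, side="right") / len(tail)
        return float(np.max(np.abs(cdf_emp - cdf_model)))

    best = None
    for xmin in np.unique(x)[:-1]:
        tail = x[x >= xmin]
        if len(tail) < 10:
            break
        alpha = mle_alpha(tail, int(xmin))
        ks = ks_distance(tail, int(xmin), alpha)
        if best is None or ks < best[2]:
            best = (alpha, int(xmin), ks)
    if best is None:
        raise ValueError("no viable lower cutoff for the power-law fit")
    return best


@dataclass
class ModuleProfile:
    """Bundle of module structure and trait statistics for one network."""

    assignment: pd.Series                 # gene -> module label ("grey" = none)
    eigengenes: pd.DataFrame              # samples x modules
    var_explained: dict[str, float]
    module_trait: pd.DataFrame            # per module: r, p, q, candidate
    GS: pd.Series                         # per gene
    MS: pd.Series                         # per module
    K: pd.Series                          # per gene, scaled connectivity
    candidate_modules: list[str] = field(default_factory=list)

    def module_genes(self, module: str) -> list[str]:
        return list(self.assignment.index[self.assignment == module])


def profile_modules(
    X: pd.DataFrame,
    assignment: pd.Series,
    trait: pd.Series | np.ndarray,
    adjacency: pd.DataFrame,
    r_min: float = 0.3,
) -> ModuleProfile:
    """Compute eigengenes, GS/MS/K and module-trait gating in one pass."""
    eigengenes, var_explained = module_eigengene(X, assignment)
    mt = module_trait_correlation(eigengenes, trait, r_min=r_min)
    GS = gene_significance(X, trait)
    MS = module_significance(GS, assignment)
    K = scaled_connectivity(adjacency, assignment)
    candidates = list(mt.index[mt["candidate"]])
    return ModuleProfile(
        assignment=assignment,
        eigengenes=eigengenes,
        var_explained=var_explained,
        module_trait=mt,
        GS=GS,
        MS=MS,
        K=K,
        candidate_modules=candidates,
    )
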