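"""Module preservation statistics and topological attack robustness.

Preservation: for each module, a density statistic (mean within-module
adjacency in a test network) and a connectivity statistic (correlation of
intramodular connectivities between reference and test) are compared with a
permutation null of random same-size gene sets; the Z-summary is the mean of
the two Z-scores.  Z < 2 means no evidence of preservation, 2-10 moderate,
> 10 strong.

Robustness: the (binarized, unweighted) module graph is attacked by removing
nodes in decreasing order of a centrality computed once on the intact graph
(degree, betweenness, closeness, eigenvector) or uniformly at random, and the
relative size of the largest connected component sigma(rho) is tracked.  The
R-index is the average of sigma over the removal sequence and the
vulnerability index is V = 1/2 - R.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .netbuild import GREY, signed_adjacency

__all__ = [
    "zsummary",
    "resample_preservation",
    "centralities",
    "attack_curve",
    "random_attack_mean",
    "graph_from_adjacency",
    "AttackResult",
    "ATTACK_SCHEMES",
    "preservation_interpretation",
]

ATTACK_SCHEMES = ("degree", "betweenness", "closeness", "eigenvector", "random")


def preservation_interpretation(z: float) -> str:
    if z < 2:
        return "not_preserved"
    if z <= 10:
        return "moderate"
    return "strong"


def _density(A: np.ndarray, idx: np.ndarray) -> float:
    """Mean within-set adjacency (off-diagonal)."""
    m = len(idx)
    if m < 2:
        return 0.0
    return float(A[np.ix_(idx, idx)].sum() / (m * (m - 1)))


def _intramodular_k(A: np.ndarray, idx: np.ndarray) -> np.ndarray:
    return A[np.ix_(idx, idx)].sum(axis=1)


def _k_correlation(k_ref: np.ndarray, k_test: np.ndarray) -> float:
    if k_ref.std() == 0 or k_test.std() == 0:
        return 0.0
    return float(np.corrcoef(k_ref, k_test)[0, 1])


def zsummary(
    X_ref: pd.DataFrame,
    assignment: pd.Series,
    X_test: pd.DataFrame,
    n_perm: int = 200,
    seed: int | None = None,
    beta: int = 6,
) -> pd.DataFrame:
    """Permutation Z-summary of module preservation between two datasets.

    Both matrices must cover the same gene universe.  Modules smaller than 3
    genes are skipped with a warning.  A soft power of 6 is the usual default
    for preservation adjacency; it need not match the power used to detect
    the modules.
    """
    if n_perm < 50:
        raise ValueError("n_perm must be at least 50")
    if list(X_ref.index) != list(X_test.index):
        X_test = X_test.loc[X_ref.index]
    rng = np.random.default_rng(seed)
    A_ref = signed_adjacency(X_ref, beta=beta).to_numpy()
    A_test = signed_adjacency(X_test, beta=beta).to_numpy()
    n_genes = A_ref.shape[0]
    gene_pos = {g: i for i, g in enumerate(X_ref.index)}

    rows = []
    for module in [m for m in assignment.unique() if m != GREY]:
        genes = assignment.index[assignment == module]
        idx = np.array([gene_pos[g] for g in genes if g in gene_pos])
        if len(idx) < 3:
            warnings.warn(f"module {module!r} smaller than 3 genes: skipped")
            continue
        k_ref_mod = _intramodular_k(A_ref, idx)
        obs_d = _density(A_test, idx)
        obs_c = _k_correlation(k_ref_mod, _intramodular_k(A_test, idx))
        # Null: module labels permuted on the test side only -- the module
        # keeps its reference connectivity pattern, which is paired with a
        # random same-size gene set drawn from the test network.
        null_d = np.empty(n_perm)
        null_c = np.empty(n_perm)
        for p in range(n_perm):
            ridx = rng.choice(n_genes, size=len(idx), replace=False)
            null_d[p] = _density(A_test, ridx)
            null_c[p] = _k_correlation(k_ref_mod, _intramodular_k(A_test, ridx))
        z_d = _zscore(obs_d, null_d)
        z_c = _zscore(obs_c, null_c)
        # A component whose permutation null is (near-)constant carries no
        # information; the summary averages the informative components only.
        comps = [z for z in (z_d, z_c) if not np.isnan(z)]
        z_sum = float(np.mean(comps)) if comps else np.nan
        rows.append(
            {
                "module": module,
                "size": int(len(idx)),
                "z_density": z_d,
                "z_connectivity": z_c,
                "z_summary": z_sum,
                "interpretation": preservation_interpretation(z_sum),
            }
        )
    columns = ["module", "size", "z_density", "z_connectivity", "z_summary",
               "interpretation"]
    return pd.DataFrame(rows, columns=columns).set_index("module")


def _zscore(obs: float, null: np.ndarray) -> float:
    sd = null.std(ddof=1)
    if sd < 1e-8:  # degenerate null: the statistic is uninformative here
        return float("nan")
    return float((obs - null.mean()) / sd)


def resample_preservation(
    X: pd.DataFrame,
    assignment: pd.Series,
    n_samples: int = 100,
    subsample_fraction: float = 0.5,
    n_perm: int = 200,
    seed: int | None = None,
    beta: int = 6,
) -> pd.DataFrame:
    """Mean/sd of Z-summary over repeated column-subsampled test sets.

    Each repetition draws ``subsample_fraction`` of the samples (without
    replacement) as the test dataset and recomputes :func:`zsummary` against
    the full reference.
    """
    n_cols = X.shape[1]
    n_keep = int(round(subsample_fraction * n_cols))
    if n_keep < 10:
        raise ValueError("subsample leaves fewer than 10 samples")
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(n_samples)
    acc: dict[str, list[float]] = {}
    sizes: dict[str, int] = {}
    for rep in range(n_samples):
        rng = np.random.default_rng(streams[rep])
        cols = rng.choice(n_cols, size=n_keep, replace=False)
        X_test = X.iloc[:, np.sort(cols)]
        z = zsummary(
            X, assignment, X_test, n_perm=n_perm,
            seed=int(rng.integers(2**31)), beta=beta,
        )
        for module, row in z.iterrows():
            acc.setdefault(module, []).append(row["z_summary"])
            sizes[module] = int(row["size"])
    rows = []
    for module, zs in acc.items():
        zs = np.asarray(zs)
        rows.append(
            {
                "module": module,
                "size": sizes[module],
                "mean_z_summary": float(zs.mean()),
                "sd_z_summary": float(zs.std(ddof=1)) if len(zs) > 1 else 0.0,
                "interpretation": preservation_interpretation(float(zs.mean())),
            }
        )
    return pd.DataFrame(rows).set_index("module")


# ---------------------------------------------------------------------------
# Attack robustness
# ---------------------------------------------------------------------------

def graph_from_adjacency(adjacency: pd.DataFrame, edge_min: float = 0.1) -> nx.Graph:
    """Binarize a weighted adjacency: edge wherever ``a_ij >= edge_min``."""
    if not 0.0 < edge_min < 1.0:
        raise ValueError("edge_min must lie in (0, 1)")
    A = adjacency.to_numpy(dtype=float)
    nodes = list(adjacency.index)
    G = nx.Graph()
    G.add_nodes_from(nodes)
    ii, jj = np.nonzero(np.triu(A >= edge_min, k=1))
    G.add_edges_from((nodes[i], nodes[j]) for i, j in zip(ii, jj))
    if G.number_of_edges() == 0:
        warnings.warn("edge_min threshold yields an edgeless graph")
    return G


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness, closeness and eigenvector centrality per node.

    The graph is treated as simple, undirected and unweighted.  Betweenness
    counts mediated pairs (unnormalized); closeness is the classic
    within-component form; eigenvector centrality is computed by power
    iteration on the full graph (tolerance 1e-10).
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False)
    clo = nx.closeness_centrality(graph, wf_improved=False)
    if graph.number_of_edges() == 0:
        eig = {v: 0.0 for v in graph}
    else:
        eig = nx.eigenvector_centrality(graph, max_iter=10_000, tol=1e-10)
    nodes = sorted(graph.nodes())
    return pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "betweenness": [btw[v] for v in nodes],
            "closeness": [clo[v] for v in nodes],
            "eigenvector": [eig[v] for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


@dataclass
class AttackResult:
    scheme: str
    removal_order: list
    sigma: np.ndarray        # fraction of original nodes, after each removal
    r_index: float
    v_index: float

    def removal_fraction_to_zero(self) -> float:
        """Fraction of nodes removed when sigma first reaches 0."""
        hit = np.flatnonzero(self.sigma == 0)
        n = len(self.sigma)
        return float((hit[0] + 1) / n) if len(hit) else 1.0


def attack_curve(
    graph: nx.Graph, scheme: str, seed: int | None = None
) -> AttackResult:
    """Simultaneous-ordering node-removal curve for one attack scheme.

    The removal order is fixed from centralities computed once on the intact
    graph (decreasing order, ties broken by node id) or, for ``random``, a
    seeded uniform permutation.  ``sigma[q]`` is the relative size of the
    largest component after the first ``q + 1`` removals; the R-index is the
    mean of sigma and V = 1/2 - R.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if scheme not in ATTACK_SCHEMES:
        raise ValueError(f"unknown attack scheme {scheme!r}")
    nodes = sorted(graph.nodes())
    if scheme == "random":
        rng = np.random.default_rng(seed)
        order = [nodes[i] for i in rng.permutation(len(nodes))]
    else:
        cent = centralities(graph)[scheme]
        order = sorted(nodes, key=lambda v: (-cent[v], v))
    N = len(nodes)
    H = graph.copy()
    sigma = np.empty(N)
    for q, v in enumerate(order):
        H.remove_node(v)
        if H.number_of_nodes() == 0:
            sigma[q] = 0.0
        else:
            sigma[q] = max(len(c) for c in nx.connected_components(H)) / N
    r_index = float(sigma.mean())
    return AttackResult(
        scheme=scheme,
        removal_order=order,
        sigma=sigma,
        r_index=r_index,
        v_index=0.5 - r_index,
    )


def random_attack_mean(
    graph: nx.Graph, n_rep: int = 20, seed: int | None = None
) -> AttackResult:
    """Random-attack curve averaged over ``n_rep`` seeded permutations."""
    ss = np.random.SeedSequence(seed)
    curves = []
    for child in ss.spawn(n_rep):
        rep_seed = int(np.random.default_rng(child).integers(2**31))
        curves.append(attack_curve(graph, "random", seed=rep_seed).sigma)
    sigma = np.mean(curves, axis=0)
    r_index = float(sigma.mean())
    return AttackResult(
        scheme="random",
        removal_order=[],
        sigma=sigma,
        r_index=r_index,
        v_index=0.5 - r_index,
    )
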