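"""Hub-gene calling, gene-set enrichment and bootstrap elastic-net ranking.

Hubs of a trait-associated module are genes exceeding both a gene-significance
cut (GS > 0.2 by default) and a scaled-connectivity cut (K > 0.3).  Their
stability as predictors is ranked by bootstrap elastic-net feature selection:
in each of ``n_boot`` class-stratified bootstrap resamples the elastic-net
mixing and strength are tuned by inner cross-validated deviance, the model is
refit, and every gene with a nonzero coefficient has its inclusion frequency
``f`` incremented.  Key hubs are hubs with ``f`` above 0.675 x n_boot -- the
90th-percentile cut of the fourth quartile (0.9 x 0.75), i.e. f > 675 at
1000 bootstraps.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._glmnet import (
    DEFAULT_ALPHA_GRID,
    DEFAULT_LAMBDA_GRID,
    ElasticNetLogit,
    tune_elasticnet,
)
from .diffexpr import bh_adjust
from .netbuild import ModuleProfile

__all__ = [
    "select_hubs",
    "read_gmt",
    "hypergeom_enrichment",
    "bootstrap_elasticnet",
    "key_hub_genes",
    "build_selection_result",
    "SelectionResult",
]


def select_hubs(
    profile: ModuleProfile,
    module: str,
    gs_min: float = 0.2,
    k_min: float = 0.3,
) -> list[str]:
    """Genes of ``module`` with GS > gs_min and K > k_min (both strict)."""
    genes = profile.module_genes(module)
    if not genes:
        raise ValueError(f"module {module!r} not present in profile")
    gs = profile.GS.loc[genes]
    k = profile.K.loc[genes]
    return [g for g in genes if gs[g] > gs_min and k[g] > k_min]


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT: ``set_id<TAB>description<TAB>gene1...``."""
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{Path(path).name}, line {lineno}: expected at least "
                    "3 tab-separated fields"
                )
            sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def hypergeom_enrichment(
    query: list[str],
    universe: list[str],
    gene_sets: dict[str, list[str]],
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of gene sets in a query list.

    Sets are intersected with the universe; p is the probability of seeing
    at least the observed overlap when drawing ``|query|`` genes from the
    universe, and q is the BH adjustment across sets.
    """
    uni = set(universe)
    qry = set(query)
    if not uni or not qry:
        raise ValueError("query and universe must be nonempty")
    if not qry <= uni:
        raise ValueError("query genes must be contained in the universe")
    M, n_query = len(uni), len(qry)
    rows = []
    for set_id, members in gene_sets.items():
        members_in = set(members) & uni
        overlap = len(members_in & qry)
        p = float(stats.hypergeom.sf(overlap - 1, M, len(members_in), n_query))
        rows.append(
            {
                "set_id": set_id,
                "set_size": len(members_in),
                "overlap": overlap,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows).set_index("set_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p")


def bootstrap_elasticnet(
    X_hubs: pd.DataFrame,
    y_stage: pd.Series | np.ndarray,
    n_boot: int = 1000,
    alpha_grid=DEFAULT_ALPHA_GRID,
    lambda_grid=DEFAULT_LAMBDA_GRID,
    inner_folds: int = 5,
    seed: int | None = None,
    rule: str = "min",
) -> pd.Series:
    """Bootstrap inclusion frequency ``f`` per gene (0..n_boot).

    ``X_hubs`` is samples x genes.  Each bootstrap draws samples with
    replacement stratified by class (so both classes are always present),
    tunes (alpha, lambda) by ``inner_folds``-fold CV deviance on the
    bootstrap sample (``rule`` picks the deviance minimum or the
    one-standard-error point), refits at the tuned pair, and counts genes
    with nonzero coefficients.
    """
    X = X_hubs.to_numpy(dtype=float)
    y = np.asarray(y_stage, dtype=float)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("y_stage must be binary")
    idx_by_class = [np.flatnonzero(y == c) for c in classes]
    if min(len(ix) for ix in idx_by_class) < 10:
        raise ValueError("need at least 10 samples per class")
    ss = np.random.SeedSequence(seed)
    f = np.zeros(X.shape[1], dtype=int)
    for child in ss.spawn(n_boot):
        rng = np.random.default_rng(child)
        boot = np.concatenate(
            [rng.choice(ix, size=len(ix), replace=True) for ix in idx_by_class]
        )
        Xb, yb = X[boot], y[boot]
        alpha, lam = tune_elasticnet(
            Xb, yb, alpha_grid, lambda_grid,
            n_folds=inner_folds, seed=int(rng.integers(2**31)), rule=rule,
        )
        model = ElasticNetLogit(alpha=alpha, lam=lam).fit(Xb, yb)
        f += model.nonzero_mask()
    return pd.Series(f, index=X_hubs.columns, name="f")


@dataclass
class SelectionResult:
    """Per-gene hub flags, bootstrap frequencies and key-hub calls."""

    table: pd.DataFrame        # index gene: GS, K, is_hub, f, is_key_hub
    gs_min: float
    k_min: float
    f_min_fraction: float
    n_boot: int

    @property
    def hubs(self) -> list[str]:
        return list(self.table.index[self.table["is_hub"]])

    @property
    def key_hubs(self) -> list[str]:
        return list(self.table.index[self.table["is_key_hub"]])


def key_hub_genes(
    result: SelectionResult, f_min_fraction: float = 0.675
) -> list[str]:
    """Hubs whose bootstrap frequency exceeds ``f_min_fraction * n_boot``.

    The default 0.675 is 0.9 x 0.75: the 90th-percentile cut of the fourth
    quartile, giving f > 675 at 1000 bootstraps.  The comparison is strict,
    so f = 675 of 1000 does not qualify.
    """
    threshold = f_min_fraction * result.n_boot
    table = result.table
    keys = [
        g
        for g in table.index
        if table.at[g, "is_hub"] and table.at[g, "f"] > threshold
    ]
    result.table["is_key_hub"] = result.table.index.isin(keys)
    result.f_min_fraction = f_min_fraction
    return keys


def build_selection_result(
    profile: ModuleProfile,
    module: str,
    f: pd.Series,
    gs_min: float = 0.2,
    k_min: float = 0.3,
    f_min_fraction: float = 0.675,
    n_boot: int | None = None,
) -> SelectionResult:
    """Assemble the per-gene selection table for one module."""
    genes = profile.module_genes(module)
    hubs = set(select_hubs(profile, module, gs_min=gs_min, k_min=k_min))
    table = pd.DataFrame(
        {
            "GS": profile.GS.loc[genes],
            "K": profile.K.loc[genes],
            "is_hub": [g in hubs for g in genes],
            "f": [int(f.get(g, 0)) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    table["is_key_hub"] = False
    result = SelectionResult(
        table=table,
        gs_min=gs_min,
        k_min=k_min,
        f_min_fraction=f_min_fraction,
        n_boot=int(n_boot if n_boot is not None else f.max()),
    )
    key_hub_genes(result, f_min_fraction=f_min_fraction)
    return result
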