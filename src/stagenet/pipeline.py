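"""End-to-end orchestration: data to stage classifier under a single seed.

The flow mirrors the analysis the package implements: (synthetic or on-disk)
expression data -> empirical-Bayes batch adjustment -> steady-state
eigenfeature and variance filtering -> moderated-t differential expression ->
signed coexpression network on tumor samples restricted to the DEGs ->
module-trait gating (candidate = |r| >= r_min against the early/late stage
trait; the selected module prefers positive correlation, then maximal module
significance) -> module preservation and attack robustness -> GS/K hub
calling -> bootstrap elastic-net frequency ranking -> key hubs -> stratified
70/30 split with 5-fold cross-validated elastic-net logistic classification.

If no module passes the trait gate the pipeline stops after network
construction and returns a report with the downstream stages marked skipped
(this is a result, not an error).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify, diffexpr, netbuild, netstats, preprocess, selection
from .simdata import ExpressionDataset, SimConfig, read_dataset, simulate_dataset

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]

log = logging.getLogger("stagenet")

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """All thresholds and sizes of the full analysis, plus one global seed."""

    sim: SimConfig | None = None          # simulate when set ...
    data_dir: str | None = None           # ... otherwise read from disk
    lfc_min: float = 1.0                  # "twofold" on the log2 scale
    fdr_max: float = 0.05
    steady_state_threshold: float = 0.90
    variance_drop_quantile: float = 0.5
    network_on_degs: bool = True
    beta: int | str = 18                  # soft power, or "auto"
    min_size: int = 30
    cut_height_quantile: float = 0.99
    r_min: float = 0.3
    gs_min: float = 0.2
    k_min: float = 0.3
    n_boot: int = 1000
    f_min_fraction: float = 0.675
    inner_folds: int = 5
    train_fraction: float = 0.7
    cv_folds: int = 5
    edge_min: float = 0.1
    n_perm: int = 200
    n_preservation_samples: int = 100
    subsample_fraction: float = 0.5
    preservation_beta: int = 6
    n_random_attack: int = 20
    gmt: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = dataclasses.asdict(self.sim)
            d["sim"]["module_sizes"] = list(self.sim.module_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("sim") is not None:
            sim = dict(d["sim"])
            if "module_sizes" in sim:
                sim["module_sizes"] = tuple(sim["module_sizes"])
            d["sim"] = SimConfig(**sim)
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineReport:
    config: dict
    stages: dict = field(default_factory=dict)
    completed: list = field(default_factory=list)
    skipped: dict = field(default_factory=dict)   # stage -> reason
    version: str = VERSION

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "stages": self.stages,
            "completed": self.completed,
            "skipped": self.skipped,
            "version": self.version,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())


def _jaccard(a: set, b: set) -> float:
    return len(a & b) / len(a | b) if a | b else 0.0


def _derive_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(np.random.default_rng(c).integers(2**31)) for c in ss.spawn(n)]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineReport:
    """Execute the full analysis; see the module docstring for the flow."""
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config=config.to_dict())
    (sim_seed, preserve_seed, attack_seed, boot_seed, clf_seed) = _derive_seeds(
        config.seed, 5
    )

    # --- data ------------------------------------------------------------
    if config.sim is not None:
        ds = simulate_dataset(config.sim.with_(seed=sim_seed))
        source = "simulated"
    elif config.data_dir is not None:
        ds = read_dataset(config.data_dir)
        source = str(config.data_dir)
    else:
        raise ValueError("config needs either a sim block or a data_dir")
    log.info("dataset: %d genes x %d samples (%s)", *ds.expr.shape, source)
    report.stages["data"] = {
        "source": source,
        "n_genes": int(ds.expr.shape[0]),
        "n_samples": int(ds.expr.shape[1]),
        "n_tumor": len(ds.samples_in_group("tumor")),
        "n_normal": len(ds.samples_in_group("normal")),
    }
    report.completed.append("data")

    # --- preprocessing ---------------------------------------------------
    ds = preprocess.batch_adjust(ds)
    filtered, svd_report = preprocess.svd_filter(
        ds.expr, steady_state_threshold=config.steady_state_threshold
    )
    filtered = preprocess.variance_filter(
        filtered, drop_quantile=config.variance_drop_quantile
    )
    ds = ExpressionDataset(filtered, ds.phenotype, ds.truth)
    log.info("preprocessing kept %d genes", ds.expr.shape[0])
    report.stages["preprocess"] = {
        "entropy": svd_report.entropy,
        "eigen_fraction_1": float(svd_report.eigen_fractions[0]),
        "removed_eigenfeatures": svd_report.removed_indices,
        "genes_after_filtering": int(ds.expr.shape[0]),
    }
    report.completed.append("preprocess")

    # --- differential expression ----------------------------------------
    degs_table = diffexpr.select_degs(
        diffexpr.moderated_t(ds, "normal", "tumor"),
        lfc_min=config.lfc_min,
        fdr_max=config.fdr_max,
    )
    deg_genes = list(degs_table.index[degs_table["selected"]])
    n_up = int((degs_table["direction"] == "up").sum())
    n_down = int((degs_table["direction"] == "down").sum())
    log.info("DEGs: %d (%d up, %d down)", len(deg_genes), n_up, n_down)
    report.stages["degs"] = {"n_degs": len(deg_genes), "n_up": n_up, "n_down": n_down}
    report.completed.append("degs")
    if out is not None:
        degs_table.to_csv(out / "degs.tsv", sep="\t")

    remaining = [
        "network", "preservation", "robustness", "hubs", "selection", "classify",
    ]
    if len(deg_genes) < max(config.min_size, 10):
        reason = f"only {len(deg_genes)} DEGs; too few to build a network"
        for stage in remaining:
            report.skipped[stage] = reason
        _finalize(report, out)
        return report

    # --- network on tumor samples ---------------------------------------
    net_ds = ds.tumor_subset()
    if config.network_on_degs:
        net_ds = net_ds.subset_genes(deg_genes)
    X_net = net_ds.expr
    trait = net_ds.stage_trait()

    if config.beta == "auto":
        beta, beta_table = netbuild.pick_soft_power(X_net)
    else:
        beta, beta_table = int(config.beta), None
    adjacency = netbuild.signed_adjacency(X_net, beta=beta)
    tom = netbuild.tom_similarity(adjacency)
    assignment = netbuild.detect_modules(
        tom, min_size=config.min_size, cut_height_quantile=config.cut_height_quantile
    )
    module_sizes = {
        m: int((assignment == m).sum())
        for m in assignment.unique()
        if m != netbuild.GREY
    }
    if not module_sizes:
        report.stages["network"] = {"beta": beta, "modules": {}}
        report.completed.append("network")
        for stage in remaining[1:]:
            report.skipped[stage] = "no modules detected"
        _finalize(report, out)
        return report

    profile = netbuild.profile_modules(
        X_net, assignment, trait, adjacency, r_min=config.r_min
    )
    report.stages["network"] = {
        "beta": beta,
        "beta_auto": config.beta == "auto",
        "n_network_genes": int(X_net.shape[0]),
        "n_network_samples": int(X_net.shape[1]),
        "modules": dict(sorted(module_sizes.items())),
        "module_trait": {
            m: {
                "r": float(profile.module_trait.at[m, "r"]),
                "p": float(profile.module_trait.at[m, "p"]),
                "q": float(profile.module_trait.at[m, "q"]),
                "MS": float(profile.MS.get(m, np.nan)),
                "candidate": bool(profile.module_trait.at[m, "candidate"]),
            }
            for m in profile.module_trait.index
        },
        "candidate_modules": profile.candidate_modules,
    }
    report.completed.append("network")
    if out is not None:
        pd.DataFrame(
            {"module": assignment, "GS": profile.GS, "K": profile.K}
        ).to_csv(out / "modules.tsv", sep="\t")
        profile.eigengenes.to_csv(out / "eigengenes.tsv", sep="\t")
        _write_edge_list(adjacency, config.edge_min, out / "edges.tsv")

    # --- candidate-module gating -----------------------------------------
    candidates = profile.candidate_modules
    if not candidates:
        for stage in remaining[1:]:
            report.skipped[stage] = (
                f"no module reached |r| >= {config.r_min} against the stage trait"
            )
        _finalize(report, out)
        return report
    positive = [m for m in candidates if profile.module_trait.at[m, "r"] > 0]
    pool = positive if positive else candidates
    chosen = max(pool, key=lambda m: profile.MS.get(m, 0.0))
    chosen_genes = profile.module_genes(chosen)
    report.stages["network"]["selected_module"] = chosen
    report.stages["network"]["selected_module_size"] = len(chosen_genes)
    _report_truth_recovery(report, net_ds, chosen_genes)
    log.info(
        "selected module %s (%d genes, r=%.2f)",
        chosen, len(chosen_genes), profile.module_trait.at[chosen, "r"],
    )

    # --- preservation ----------------------------------------------------
    preservation = netstats.resample_preservation(
        X_net,
        assignment,
        n_samples=config.n_preservation_samples,
        subsample_fraction=config.subsample_fraction,
        n_perm=config.n_perm,
        seed=preserve_seed,
        beta=config.preservation_beta,
    )
    report.stages["preservation"] = {
        m: {
            "mean_z_summary": float(preservation.at[m, "mean_z_summary"]),
            "interpretation": str(preservation.at[m, "interpretation"]),
        }
        for m in preservation.index
    }
    report.completed.append("preservation")
    if out is not None:
        preservation.to_csv(out / "preservation.tsv", sep="\t")

    # --- robustness of the selected module -------------------------------
    module_adj = adjacency.loc[chosen_genes, chosen_genes]
    graph = netstats.graph_from_adjacency(module_adj, edge_min=config.edge_min)
    attacks = {}
    curves = []
    for scheme in ("degree", "betweenness", "closeness", "eigenvector"):
        res = netstats.attack_curve(graph, scheme)
        attacks[scheme] = res
        curves.append(res)
    attacks["random"] = netstats.random_attack_mean(
        graph, n_rep=config.n_random_attack, seed=attack_seed
    )
    report.stages["robustness"] = {
        scheme: {
            "r_index": float(res.r_index),
            "v_index": float(res.v_index),
            "removal_fraction_to_zero": res.removal_fraction_to_zero(),
        }
        for scheme, res in attacks.items()
    }
    report.completed.append("robustness")
    if out is not None:
        _write_attack_curves(attacks, out / "attack_curves.tsv")

    # --- hub calling ------------------------------------------------------
    hubs = selection.select_hubs(
        profile, chosen, gs_min=config.gs_min, k_min=config.k_min
    )
    report.stages["hubs"] = {
        "n_hubs": len(hubs),
        "hub_fraction_of_module": len(hubs) / len(chosen_genes),
        "hubs": sorted(hubs),
    }
    report.completed.append("hubs")
    log.info("hubs: %d of %d module genes", len(hubs), len(chosen_genes))

    if config.gmt is not None:
        sets = selection.read_gmt(config.gmt)
        enrichment = selection.hypergeom_enrichment(
            hubs, list(X_net.index), sets
        )
        report.stages["enrichment"] = {
            "n_sets": int(len(enrichment)),
            "n_significant_q05": int((enrichment["q"] < 0.05).sum()),
        }
        if out is not None:
            enrichment.to_csv(out / "enrichment.tsv", sep="\t")

    if not hubs:
        for stage in ("selection", "classify"):
            report.skipped[stage] = "no hub genes passed the GS/K thresholds"
        _finalize(report, out)
        return report

    # --- bootstrap elastic-net selection ---------------------------------
    X_hubs = X_net.loc[hubs].T  # samples x genes
    f = selection.bootstrap_elasticnet(
        X_hubs,
        trait,
        n_boot=config.n_boot,
        inner_folds=config.inner_folds,
        seed=boot_seed,
    )
    sel_result = selection.build_selection_result(
        profile, chosen, f,
        gs_min=config.gs_min, k_min=config.k_min,
        f_min_fraction=config.f_min_fraction, n_boot=config.n_boot,
    )
    key_hubs = sel_result.key_hubs
    report.stages["selection"] = {
        "n_boot": config.n_boot,
        "f_threshold": config.f_min_fraction * config.n_boot,
        "n_key_hubs": len(key_hubs),
        "key_hubs": sorted(key_hubs),
    }
    report.completed.append("selection")
    if out is not None:
        sel_result.table.to_csv(out / "selection.tsv", sep="\t")
    log.info("key hubs: %d of %d hubs", len(key_hubs), len(hubs))

    if len(key_hubs) < 2:
        report.skipped["classify"] = (
            f"only {len(key_hubs)} key hub(s); need at least 2 predictors"
        )
        _finalize(report, out)
        return report

    # --- classification ---------------------------------------------------
    clf_report = classify.train_and_evaluate(
        X_net.loc[key_hubs].T,
        trait,
        train_fraction=config.train_fraction,
        k=config.cv_folds,
        inner_folds=config.inner_folds,
        seed=clf_seed,
    )
    report.stages["classify"] = {
        "fold_aucs": [float(a) for a in clf_report.fold_aucs],
        "mean_auc": float(clf_report.mean_auc),
        "holdout_auc": float(clf_report.holdout_auc),
        "holdout_accuracy": float(clf_report.holdout_accuracy),
        "n_predictors": len(key_hubs),
    }
    report.completed.append("classify")
    if out is not None:
        clf_report.save(out / "model.json")
    log.info(
        "classification: mean CV AUC %.3f, holdout AUC %.3f",
        clf_report.mean_auc, clf_report.holdout_auc,
    )
    _finalize(report, out)
    return report


def _report_truth_recovery(
    report: PipelineReport, net_ds: ExpressionDataset, chosen_genes: list[str]
) -> None:
    """When planted truth is available, score recovery of the stage module."""
    if net_ds.truth is None:
        return
    truth = net_ds.truth
    planted = truth.index[truth["module"] != "none"]
    if not len(planted):
        return
    # The planted stage module is identifiable in truth via the sim config
    # convention: its genes carry the module label of the stage module; the
    # pipeline does not know which planted module is the stage one, so score
    # against the best-matching planted label and report all Jaccards.
    jaccards = {}
    chosen_set = set(chosen_genes)
    for label in sorted(truth.loc[planted, "module"].unique()):
        genes = set(truth.index[truth["module"] == label])
        jaccards[label] = _jaccard(chosen_set, genes)
    best = max(jaccards, key=jaccards.get)
    report.stages["network"]["truth_recovery"] = {
        "jaccard_by_planted_module": {k: float(v) for k, v in jaccards.items()},
        "best_match": best,
        "best_jaccard": float(jaccards[best]),
    }


def _write_edge_list(adjacency: pd.DataFrame, edge_min: float, path: Path) -> None:
    A = adjacency.to_numpy()
    genes = list(adjacency.index)
    ii, jj = np.nonzero(np.triu(A >= edge_min, k=1))
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene_a\tgene_b\tweight\n")
        for i, j in zip(ii, jj):
            fh.write(f"{genes[i]}\t{genes[j]}\t{A[i, j]:.6g}\n")


def _write_attack_curves(attacks: dict, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("scheme\tQ\trho\tsigma\n")
        for scheme, res in attacks.items():
            n = len(res.sigma)
            for q, s in enumerate(res.sigma, start=1):
                fh.write(f"{scheme}\t{q}\t{q / n:.6g}\t{s:.6g}\n")


def _finalize(report: PipelineReport, out: Path | None) -> None:
    if out is not None:
        report.save(out / "report.json")
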