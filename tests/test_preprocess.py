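"""Batch adjustment and filtering behave like their closed-form cases."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from stagenet.preprocess import batch_adjust, svd_filter, variance_filter
from stagenet.simdata import ExpressionDataset, SimConfig, simulate_dataset


def _make_ds(X, batch, group=None):
    n_genes, n_s = X.shape
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i}" for i in range(n_s)]
    group = group if group is not None else np.array(["tumor"] * n_s)
    stage = np.where(group == "tumor", "early", None)
    ph = pd.DataFrame({"group": group, "stage": stage, "batch": batch},
                      index=samples)
    return ExpressionDataset(pd.DataFrame(X, index=genes, columns=samples), ph)


def test_single_batch_is_a_noop(rng):
    X = rng.normal(7, 1, size=(20, 10))
    ds = _make_ds(X, np.array(["b1"] * 10))
    out = batch_adjust(ds)
    assert np.abs(out.expr.to_numpy() - X).max() < 1e-12


def test_shared_additive_shift_is_removed_exactly(rng):
    # Two batches differing by one shared additive shift: the empirical-Bayes
    # prior mean coincides with every gene's true offset, so adjustment
    # equalizes per-gene batch means to numerical precision.
    base = rng.normal(0, 1, size=(30, 8))
    base = (base - base.mean(axis=1, keepdims=True)) / base.std(axis=1, keepdims=True)
    X = np.hstack([base, base + 2.5])  # batch 2: same profiles, shifted
    ds = _make_ds(X, np.array(["b1"] * 8 + ["b2"] * 8))
    out = batch_adjust(ds).expr.to_numpy()
    gap = out[:, :8].mean(axis=1) - out[:, 8:].mean(axis=1)
    assert np.abs(gap).max() < 1e-6


def test_per_gene_shifts_are_strongly_reduced(rng):
    # With gene-specific shifts the shrinkage leaves a small residual (the
    # prior pulls extreme offsets inward), but the batch-mean gap must drop
    # by a large factor.
    base = rng.normal(0, 1, size=(40, 20))
    shift = rng.normal(0, 2, size=(40, 1))
    X = base.copy()
    X[:, 10:] += shift
    ds = _make_ds(X, np.array(["b1"] * 10 + ["b2"] * 10))
    out = batch_adjust(ds).expr.to_numpy()
    gap_before = np.abs(
        X[:, :10].mean(axis=1) - X[:, 10:].mean(axis=1)
    ).mean()
    gap_after = np.abs(
        out[:, :10].mean(axis=1) - out[:, 10:].mean(axis=1)
    ).mean()
    assert gap_after < gap_before / 5.0


def test_batch_label_renaming_is_invariant(rng):
    X = rng.normal(7, 1, size=(25, 12))
    b1 = np.array(["b1"] * 6 + ["b2"] * 6)
    b2 = np.array(["groupA"] * 6 + ["groupB"] * 6)
    out1 = batch_adjust(_make_ds(X, b1)).expr.to_numpy()
    out2 = batch_adjust(_make_ds(X, b2)).expr.to_numpy()
    assert np.abs(out1 - out2).max() < 1e-12


def test_small_batch_is_an_error(rng):
    X = rng.normal(size=(10, 5))
    ds = _make_ds(X, np.array(["b1"] * 4 + ["b2"]))
    with pytest.raises(ValueError, match="fewer than 2"):
        batch_adjust(ds)


def test_dimensions_and_ids_preserved(small_ds):
    out = batch_adjust(small_ds)
    assert list(out.expr.index) == list(small_ds.expr.index)
    assert list(out.expr.columns) == list(small_ds.expr.columns)


def test_matches_reference_empirical_bayes_implementation(rng):
    """Dual route: our adjustment vs the Bioconductor sva::ComBat oracle."""
    n_genes, n_s = 40, 18
    X = rng.normal(7, 1, size=(n_genes, 1)) + rng.normal(0, 0.8, size=(n_genes, n_s))
    batch = np.array(["b1"] * 6 + ["b2"] * 6 + ["b3"] * 6)
    group = np.array(["normal", "tumor", "tumor"] * 6)
    for b, scale in (("b1", 1.0), ("b2", 1.5), ("b3", 0.7)):
        cols = batch == b
        mu = X[:, cols].mean(axis=1, keepdims=True)
        X[:, cols] = (X[:, cols] - mu) * scale + mu + rng.normal(0, 0.5, size=(n_genes, 1))
    ours = batch_adjust(_make_ds(X, batch, group)).expr.to_numpy()
    with tempfile.TemporaryDirectory() as td:
        np.savetxt(f"{td}/x.tsv", X, delimiter="\t")
        pd.DataFrame({"batch": batch, "group": group}).to_csv(f"{td}/ph.tsv", sep="\t")
        r_code = (
            'suppressMessages(library(sva));'
            f'x <- as.matrix(read.table("{td}/x.tsv"));'
            f'ph <- read.table("{td}/ph.tsv", header=TRUE, sep="\\t", row.names=1);'
            'mod <- model.matrix(~group, data=ph);'
            'out <- ComBat(dat=x, batch=ph$batch, mod=mod, par.prior=TRUE);'
            f'write.table(out, "{td}/out.tsv", sep="\\t", quote=FALSE,'
            'col.names=FALSE, row.names=FALSE)'
        )
        subprocess.run(["Rscript", "-e", r_code], check=True, capture_output=True)
        ref = np.loadtxt(f"{td}/out.tsv")
    assert np.abs(ours - ref).max() < 1e-8


def test_batch_adjust_reduces_batch_silhouette_but_keeps_signal():
    cfg = SimConfig(
        n_genes=400, n_normal=40, n_tumor_early=60, n_tumor_late=60,
        n_batches=3, batch_shift_sd=1.0, batch_scale_sd=0.2,
        n_modules=2, module_sizes=(50, 40), stage_module_index=1,
        stage_effect=0.6, n_de_genes=120, seed=3,
    )
    ds = simulate_dataset(cfg)
    adj = batch_adjust(ds)

    def batch_silhouette(d):
        pcs = PCA(n_components=2).fit_transform(d.expr.to_numpy().T)
        return silhouette_score(pcs, d.phenotype.loc[d.sample_ids, "batch"])

    assert batch_silhouette(adj) < batch_silhouette(ds)

    def stage_cor(d):
        tum = d.tumor_subset()
        genes = d.truth.index[d.truth["module"] == "planted_2"]
        factor = tum.expr.loc[genes].mean(axis=0)
        return abs(np.corrcoef(factor, tum.stage_trait())[0, 1])

    assert abs(stage_cor(adj) - stage_cor(ds)) < 0.05


# ---------------------------------------------------------------------------
# SVD steady-state filter
# ---------------------------------------------------------------------------

def test_rank_one_matrix_is_fully_removed():
    X = pd.DataFrame(np.outer(np.arange(1.0, 9.0), np.arange(1.0, 7.0)))
    out, report = svd_filter(X)
    assert report.eigen_fractions[0] == pytest.approx(1.0)
    assert report.entropy == pytest.approx(0.0, abs=1e-12)
    assert report.removed_indices == [1]
    assert np.linalg.norm(out.to_numpy()) < 1e-9


def test_equal_singular_values_give_maximum_entropy():
    X = pd.DataFrame(np.eye(5) * 3.0)
    out, report = svd_filter(X)
    assert report.entropy == pytest.approx(1.0)
    assert report.removed_indices == []
    assert out.equals(X)


def test_planted_steady_state_offset_triggers_filter(rng):
    X = pd.DataFrame(10.0 + rng.normal(0, 0.1, size=(50, 30)))
    out, report = svd_filter(X)
    assert report.eigen_fractions[0] > 0.95
    assert report.removed_indices == [1]
    # spectrum check against an independent eigendecomposition
    s2 = np.linalg.eigvalsh(X.to_numpy() @ X.to_numpy().T)[::-1]
    s2 = s2[s2 > 1e-9]
    assert report.eigen_fractions[0] == pytest.approx(s2[0] / s2.sum(), abs=1e-9)


def test_filter_is_idempotent_once_below_threshold(rng):
    X = pd.DataFrame(10.0 + rng.normal(0, 0.1, size=(40, 25)))
    once, rep1 = svd_filter(X)
    twice, rep2 = svd_filter(once)
    assert rep1.removed_indices == [1]
    assert rep2.removed_indices == []
    assert np.abs(twice.to_numpy() - once.to_numpy()).max() < 1e-12


# ---------------------------------------------------------------------------
# Variance filter
# ---------------------------------------------------------------------------

def test_variance_filter_quantiles(rng):
    rows = [np.full(20, 5.0)] + [
        rng.normal(0, sd, size=20) for sd in np.linspace(0.5, 3, 9)
    ]
    X = pd.DataFrame(rows, index=[f"g{i}" for i in range(10)])
    assert len(variance_filter(X, drop_quantile=0.0)) == 10
    kept = variance_filter(X, drop_quantile=0.5)
    assert "g0" not in kept.index  # the constant gene goes first


def test_variance_filter_known_variances():
    # Genes with variances exactly 1..10: dropping below the 0.3 quantile
    # removes the three smallest (threshold 3.7, strict comparison).
    base = np.array([-1.0, 1.0, -1.0, 1.0])  # variance 4/3
    rows = [base * np.sqrt(v / np.var(base, ddof=1)) for v in range(1, 11)]
    X = pd.DataFrame(rows, index=[f"g{i}" for i in range(1, 11)])
    kept = variance_filter(X, drop_quantile=0.3)
    assert list(kept.index) == [f"g{i}" for i in range(4, 11)]
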