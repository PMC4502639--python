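"""Signed adjacency, TOM, module detection and module statistics."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from stagenet.netbuild import (
    GREY,
    detect_modules,
    gene_significance,
    module_eigengene,
    module_significance,
    module_trait_correlation,
    pick_soft_power,
    power_law_test,
    profile_modules,
    scale_free_fit,
    scaled_connectivity,
    signed_adjacency,
    tom_similarity,
)
from stagenet.simdata import SimConfig, simulate_dataset

from conftest import jaccard, planted_blocks


# ---------------------------------------------------------------------------
# Signed adjacency
# ---------------------------------------------------------------------------

def test_signed_adjacency_limits():
    x = np.linspace(-1, 1, 10)
    X = pd.DataFrame([x, 2 * x + 1, -x, np.zeros(10) + 1e-300],
                     index=list("abcd"))
    with pytest.warns(UserWarning, match="zero-variance"):
        adj = signed_adjacency(X, beta=18)
    assert adj.at["a", "b"] == pytest.approx(1.0)          # cor +1
    assert adj.at["a", "c"] == pytest.approx(0.0, abs=1e-15)  # cor -1
    assert adj.at["a", "d"] == pytest.approx(0.5**18)      # cor 0 (flagged)
    assert adj.at["a", "a"] == 0.0
    A = adj.to_numpy()
    assert np.abs(A - A.T).max() < 1e-12
    assert A.min() >= 0 and A.max() <= 1


def test_uncorrelated_pair_at_beta_18_is_tiny(rng):
    # independent profiles: a_ij ~ 0.5^18 = 3.8e-6
    assert 0.5**18 == pytest.approx(3.814697e-06, rel=1e-6)


def test_beta_is_a_monotone_transform_of_ranking(rng):
    X = pd.DataFrame(rng.standard_normal((20, 30)))
    a1 = signed_adjacency(X, beta=1).to_numpy()
    a18 = signed_adjacency(X, beta=18).to_numpy()
    iu = np.triu_indices(20, k=1)
    assert (np.argsort(a1[iu]) == np.argsort(a18[iu])).all()


# ---------------------------------------------------------------------------
# Scale-free fit / soft power
# ---------------------------------------------------------------------------

def test_preferential_attachment_degrees_fit_power_law_shape():
    g = nx.barabasi_albert_graph(500, 2, seed=1)
    k = np.array([d for _, d in g.degree()], dtype=float)
    fit = scale_free_fit(k)
    assert fit["signed_r2"] >= 0.8


def test_independent_noise_takes_argmax_branch(rng):
    X = pd.DataFrame(rng.standard_normal((120, 30)))
    beta, table = pick_soft_power(X, betas=range(1, 7), r2_target=0.95)
    assert not table["target_reached"].any()
    assert beta == int(table.loc[table["signed_r2"].idxmax(), "beta"])


def test_all_equal_connectivity_is_an_error():
    with pytest.raises(ValueError):
        scale_free_fit(np.full(100, 3.0))


# ---------------------------------------------------------------------------
# TOM
# ---------------------------------------------------------------------------

def test_tom_two_isolated_partners():
    A = pd.DataFrame(np.array([[0.0, 1.0], [1.0, 0.0]]), index=list("ab"),
                     columns=list("ab"))
    tom = tom_similarity(A)
    assert tom.at["a", "b"] == pytest.approx(1.0)
    assert tom.at["a", "a"] == 1.0


def test_tom_of_empty_adjacency_is_zero_offdiagonal():
    A = pd.DataFrame(np.zeros((4, 4)))
    tom = tom_similarity(A).to_numpy()
    assert np.abs(tom[np.triu_indices(4, k=1)]).max() == 0.0


def test_tom_matches_brute_force_triple_loop(rng):
    for _ in range(3):
        A = rng.uniform(0, 1, size=(6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0.0)
        tom = tom_similarity(pd.DataFrame(A)).to_numpy()
        k = A.sum(axis=1)
        for i in range(6):
            for j in range(6):
                if i == j:
                    assert tom[i, j] == 1.0
                    continue
                num = sum(A[i, u] * A[u, j] for u in range(6)) + A[i, j]
                ref = num / (min(k[i], k[j]) + 1 - A[i, j])
                assert tom[i, j] == pytest.approx(ref, abs=1e-12)


# ---------------------------------------------------------------------------
# Module detection
# ---------------------------------------------------------------------------

def test_planted_blocks_recovered_exactly():
    X, block1, block2 = planted_blocks(n_samples=100, seed=0)
    tom = tom_similarity(signed_adjacency(X, beta=18))
    mod = detect_modules(tom, min_size=30)
    non_grey = sorted(set(mod) - {GREY})
    assert len(non_grey) == 2
    recovered = [set(mod.index[mod == m]) for m in non_grey]
    assert max(jaccard(r, block1) for r in recovered) == 1.0
    assert max(jaccard(r, block2) for r in recovered) == 1.0
    assert (mod == GREY).sum() == 20


def test_min_size_larger_than_gene_count_gives_all_grey(rng):
    X = pd.DataFrame(rng.standard_normal((10, 30)))
    tom = tom_similarity(signed_adjacency(X, beta=6))
    with pytest.warns(UserWarning):
        mod = detect_modules(tom, min_size=50)
    assert (mod == GREY).all()


def test_gene_permutation_gives_same_partition():
    X, *_ = planted_blocks(n_samples=100, seed=2)
    tom = tom_similarity(signed_adjacency(X, beta=18))
    mod = detect_modules(tom, min_size=30)
    perm = np.random.default_rng(1).permutation(len(X))
    tom_p = tom.iloc[perm, perm]
    mod_p = detect_modules(tom_p, min_size=30)
    # same partition up to relabeling
    for m in set(mod) - {GREY}:
        genes = set(mod.index[mod == m])
        labels = {mod_p[g] for g in genes}
        assert len(labels) == 1 and labels != {GREY}
    assert set(mod.index[mod == GREY]) == set(mod_p.index[mod_p == GREY])


# ---------------------------------------------------------------------------
# Eigengenes
# ---------------------------------------------------------------------------

def test_identical_gene_module_eigengene(rng):
    f = rng.standard_normal(30)
    X = pd.DataFrame(np.tile(f, (5, 1)), index=[f"g{i}" for i in range(5)])
    assignment = pd.Series("m1", index=X.index)
    me, ve = module_eigengene(X, assignment)
    assert ve["m1"] == pytest.approx(1.0)
    assert abs(np.corrcoef(me["m1"], f)[0, 1]) == pytest.approx(1.0)
    assert np.corrcoef(me["m1"], f)[0, 1] > 0  # sign convention


def test_var_explained_matches_eigendecomposition_oracle(rng):
    X = pd.DataFrame(rng.standard_normal((12, 25)))
    assignment = pd.Series("m1", index=X.index)
    me, ve = module_eigengene(X, assignment)
    Z = (X.to_numpy() - X.to_numpy().mean(1, keepdims=True)) / X.to_numpy().std(
        1, keepdims=True
    )
    evals = np.linalg.eigvalsh(Z @ Z.T)[::-1]
    assert ve["m1"] == pytest.approx(evals[0] / evals.sum(), abs=1e-10)


def test_sign_flip_of_module_flips_eigengene(rng):
    X = pd.DataFrame(rng.standard_normal((8, 30)) + np.outer(
        np.ones(8), rng.standard_normal(30)))
    assignment = pd.Series("m1", index=X.index)
    me, _ = module_eigengene(X, assignment)
    me_flip, _ = module_eigengene(-X, assignment)
    assert np.allclose(me["m1"].to_numpy(), -me_flip["m1"].to_numpy(), atol=1e-9) or \
        np.allclose(me["m1"].to_numpy(), me_flip["m1"].to_numpy(), atol=1e-9)
    # norm and sign convention still hold
    assert np.linalg.norm(me_flip["m1"]) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# GS / MS / module-trait
# ---------------------------------------------------------------------------

def test_gene_significance_limits(rng):
    trait = np.repeat([0.0, 1.0], 20)
    X = pd.DataFrame(
        [trait, rng.standard_normal(40), 3.0 * trait - 7.0],
        index=["same", "noise", "affine"],
    )
    gs = gene_significance(X, trait)
    assert gs["same"] == pytest.approx(1.0)
    assert gs["affine"] == pytest.approx(1.0)  # affine invariance
    assert 0 <= gs["noise"] <= 1


def test_gene_independent_of_trait_has_small_gs(rng):
    trait = np.tile([0.0, 1.0], 500)
    X = pd.DataFrame(rng.standard_normal((5, 1000)))
    assert gene_significance(X, trait).max() < 0.1


def test_constant_trait_is_an_error(rng):
    X = pd.DataFrame(rng.standard_normal((3, 10)))
    with pytest.raises(ValueError):
        gene_significance(X, np.ones(10))


def test_module_significance_is_the_mean():
    gs = pd.Series([0.4, 0.4, 0.4, 0.1, 0.3], index=list("abcde"))
    assignment = pd.Series(["m1", "m1", "m1", "m2", "m2"], index=list("abcde"))
    ms = module_significance(gs, assignment)
    assert ms["m1"] == pytest.approx(0.4)
    assert ms["m2"] == pytest.approx(0.2)
    # adding a zero-GS gene strictly lowers MS
    gs2 = pd.concat([gs, pd.Series({"f": 0.0})])
    asg2 = pd.concat([assignment, pd.Series({"f": "m1"})])
    assert module_significance(gs2, asg2)["m1"] < ms["m1"]


def test_module_trait_candidates_respect_r_min(rng):
    n = 100
    trait = np.repeat([0.0, 1.0], n // 2)
    z = (trait - trait.mean()) / trait.std()
    noise = rng.standard_normal(n)
    noise = noise - noise.mean()
    noise -= z * (noise @ z) / (z @ z)  # orthogonal to trait

    def me_with_r(r):
        v = r * z + np.sqrt(1 - r**2) * noise / noise.std()
        return v / np.linalg.norm(v)

    eig = pd.DataFrame({
        "exact": z / np.linalg.norm(z),
        "at_033": me_with_r(0.33),
        "at_010": me_with_r(0.10),
    })
    mt = module_trait_correlation(eig, trait, r_min=0.3)
    assert mt.at["exact", "r"] == pytest.approx(1.0)
    assert bool(mt.at["exact", "candidate"])
    assert mt.at["at_033", "r"] == pytest.approx(0.33, abs=1e-9)
    assert bool(mt.at["at_033", "candidate"])
    assert not bool(mt.at["at_010", "candidate"])


# ---------------------------------------------------------------------------
# Scaled connectivity
# ---------------------------------------------------------------------------

def test_scaled_connectivity_hand_computed():
    A = np.array([
        [0.0, 0.2, 0.4],
        [0.2, 0.0, 0.6],
        [0.4, 0.6, 0.0],
    ])
    adj = pd.DataFrame(A, index=list("abc"), columns=list("abc"))
    assignment = pd.Series("m1", index=list("abc"))
    K = scaled_connectivity(adj, assignment)
    k = A.sum(axis=1)  # 0.6, 0.8, 1.0
    assert K["a"] == pytest.approx(0.6, abs=1e-12)
    assert K["b"] == pytest.approx(0.8, abs=1e-12)
    assert K["c"] == pytest.approx(1.0, abs=1e-12)
    # scaling the adjacency leaves K unchanged
    K2 = scaled_connectivity(adj * 0.37, assignment)
    assert np.allclose(K, K2, atol=1e-12)
    # exactly one K = 1 per module
    assert (K == 1.0).sum() == 1


def test_grey_genes_have_zero_connectivity(rng):
    A = rng.uniform(0, 1, size=(5, 5))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0)
    adj = pd.DataFrame(A, index=list("abcde"), columns=list("abcde"))
    assignment = pd.Series(["m1", "m1", "m1", GREY, GREY], index=list("abcde"))
    K = scaled_connectivity(adj, assignment)
    assert K["d"] == 0.0 and K["e"] == 0.0


# ---------------------------------------------------------------------------
# Power-law test
# ---------------------------------------------------------------------------

def test_power_law_alpha_recovery():
    x = np.random.default_rng(0).zipf(2.5, size=2000)
    alpha, xmin, ks = power_law_test(x)
    assert 2.3 <= alpha <= 2.7
    assert ks < 0.05


def test_power_law_duplication_invariance():
    x = np.random.default_rng(1).zipf(2.2, size=800)
    a1, x1, _ = power_law_test(x)
    a2, x2, _ = power_law_test(np.concatenate([x, x]))
    assert a1 == pytest.approx(a2, abs=1e-6)
    assert x1 == x2


def test_power_law_discriminates_geometric():
    ks_pl, ks_geom = [], []
    for seed in range(20):
        r = np.random.default_rng(seed)
        ks_pl.append(power_law_test(r.zipf(2.5, size=600))[2])
        ks_geom.append(power_law_test(r.geometric(0.25, size=600))[2])
    assert np.median(ks_geom) > np.median(ks_pl)


def test_all_equal_degrees_error():
    with pytest.raises(ValueError):
        power_law_test(np.full(50, 4))


# ---------------------------------------------------------------------------
# End-to-end recovery on planted data (stage module + trait gating)
# ---------------------------------------------------------------------------

def _netbuild_run(seed, stage_effect):
    cfg = SimConfig(
        n_genes=1000, n_normal=0, n_tumor_early=100, n_tumor_late=100,
        n_batches=1, batch_shift_sd=0.0, batch_scale_sd=0.0,
        n_modules=5, module_sizes=(80, 60, 50, 40, 35), stage_module_index=2,
        stage_effect=stage_effect, n_de_genes=0, seed=seed,
    )
    ds = simulate_dataset(cfg).tumor_subset()
    trait = ds.stage_trait()
    adjacency = signed_adjacency(ds.expr, beta=18)
    tom = tom_similarity(adjacency)
    assignment = detect_modules(tom, min_size=30)
    profile = profile_modules(ds.expr, assignment, trait, adjacency)
    planted = set(ds.truth.index[ds.truth["module"] == "planted_3"])
    best = max(
        (jaccard(set(assignment.index[assignment == m]), planted)
         for m in set(assignment) - {GREY}),
        default=0.0,
    )
    return best, profile


def test_stage_module_recovery_and_gating_across_seeds():
    hits = 0
    for seed in range(10):
        j, profile = _netbuild_run(seed, stage_effect=0.5)
        if j >= 0.8 and profile.candidate_modules:
            hits += 1
    assert hits >= 8


def test_no_candidate_under_null_stage_effect():
    nulls = 0
    for seed in range(10):
        _, profile = _netbuild_run(seed, stage_effect=0.0)
        if not profile.candidate_modules:
            nulls += 1
    assert nulls >= 8


def test_connectivity_correlates_with_significance_in_stage_module():
    _, profile = _netbuild_run(0, stage_effect=0.6)
    # hubs carry the stage signal: cor(K, GS) > 0 within the stage module
    stage_mod = max(
        profile.candidate_modules,
        key=lambda m: profile.MS.get(m, 0.0),
    )
    genes = profile.module_genes(stage_mod)
    r = np.corrcoef(profile.K.loc[genes], profile.GS.loc[genes])[0, 1]
    assert r > 0
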