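# stagenet

Discovering tumor-stage gene signatures from signed coexpression networks.

Clinical stage (early I–II vs late III–IV) is the strongest prognostic
factor in solid tumors such as oral squamous cell carcinoma, yet most
expression studies contrast tumor against normal tissue rather than stage
against stage. `stagenet` implements the network-driven alternative as a
tested, reusable Python library: instead of ranking tens of thousands of
individual genes, it finds *modules* of coexpressed genes among tumor
samples, keeps the module whose summary profile tracks stage, and distills
it into a small, stable gene signature that classifies early vs late
disease.

The workflow, end to end:

1. **Merging and cleaning.** Multi-cohort expression matrices carry batch
   structure; the empirical-Bayes location/scale model (additive effects
   shrunk toward a normal prior, variance ratios toward an inverse-gamma
   prior, tumor/normal protected as a covariate) removes it. A steady-state
   SVD filter subtracts a dominant rank-1 offset eigenfeature, and a
   variance filter drops uninformative genes.
2. **Differential expression.** Moderated t-statistics (variance shrinkage
   via moment-matched scaled-F priors on log variances), with genes called
   DE when |log2 FC| ≥ 1 and BH FDR < 0.05 simultaneously.
3. **Signed network and modules.** On tumor samples and DE genes only:
   adjacency `a_ij = ((1 + cor_ij)/2)^β` (default β = 18, chosen for signed
   scale-free topology), topological overlap (TOM), average-linkage
   modules, module eigengenes (ME), gene significance `GS_i = |cor(x_i,
   stage)|`, module significance (mean GS) and scaled intramodular
   connectivity `K_i = k_i / k_max`. Modules with |cor(ME, stage)| ≥ 0.3
   are stage candidates; positive correlation and maximal MS break ties.
4. **Reliability of the module.** Permutation Z-summary preservation
   against resampled test sets (< 2 not preserved, 2–10 moderate, > 10
   strong) and topological robustness under targeted/random node removal:
   σ(ρ) largest-component curves, R-index (mean of σ) and vulnerability
   V = 1/2 − R.
5. **Signature selection.** Hubs are module genes with GS > 0.2 and
   K > 0.3; 1000 class-stratified bootstrap elastic-net fits (α, λ tuned by
   inner CV deviance) count each gene's inclusion frequency f, and **key
   hubs** are hubs with f > 0.675 × n_boot — the 90th-percentile cut of the
   fourth quartile, f > 675 at 1000 bootstraps.
6. **Classification.** Stratified 70/30 split, 5-fold cross-validated
   elastic-net logistic regression on the key hubs, rank-based (midrank
   Mann–Whitney) ROC/AUC, holdout evaluation.

Because the original multi-cohort microarray data are not shipped, the
package includes a first-class synthetic generator (`stagenet.simdata`)
that plants the exact structure the analysis assumes — batches, tumor/normal
DE, latent-factor coexpression modules, one module with a tunable stage
correlation, designated high-loading hubs — with full ground truth, so every
stage of the pipeline is testable against what was planted.

## Worked example

`examples/` contains one short script per capability. The core of the
analysis in a few lines (`examples/03_network_modules.py`):

```python
from stagenet import (SimConfig, simulate_dataset, signed_adjacency,
                      tom_similarity, detect_modules, profile_modules)

ds = simulate_dataset(SimConfig(
    n_genes=600, n_normal=0, n_tumor_early=100, n_tumor_late=100,
    n_batches=1, n_modules=4, module_sizes=(70, 55, 45, 35),
    stage_module_index=1, stage_effect=0.5, n_de_genes=0, seed=11,
)).tumor_subset()

trait = ds.stage_trait()                       # early = 0, late = 1
adjacency = signed_adjacency(ds.expr, beta=18)
assignment = detect_modules(tom_similarity(adjacency), min_size=30)
profile = profile_modules(ds.expr, assignment, trait, adjacency, r_min=0.3)
print(profile.module_trait)
```

which prints

```
               r       p       q  candidate
module
module_1  0.0400  0.5741  0.8104      False
module_2  0.3810  0.0000  0.0000       True
module_3 -0.0171  0.8104  0.8104      False
module_4 -0.0271  0.7035  0.8104      False
```

`module_2` is the planted stage module (recovered with Jaccard 1.0 against
truth); its eigengene correlates 0.38 with stage — close to the planted
effect of 0.5 diluted by the eigengene being a noisy factor estimate — and
it is the only module passing the |r| ≥ 0.3 gate.

Running the whole pipeline (`examples/06_full_pipeline.py`) on a 600-gene,
200-sample simulation with stage effect 0.6 prints:

```
stages completed: data -> preprocess -> degs -> network -> preservation
                  -> robustness -> hubs -> selection -> classify
DEGs: 296 (164 up / 132 down)
modules: {'module_1': 58, 'module_2': 50, 'module_3': 45, 'module_4': 35}
selected stage module: module_3 | trait r = 0.584
planted-module recovery Jaccard: 1.0
preservation: {'module_1': 'strong', ..., 'module_4': 'strong'}
attack R-indices: {'degree': 0.035, ..., 'random': 0.135}
hubs: 43; key hubs: 19
mean CV AUC: 0.843; holdout AUC: 0.852
```

The attack numbers say the module graph collapses quickly under targeted
hub removal (R ≈ 0.035) but resists random removal (R ≈ 0.135) — the usual
signature of scale-free-ish topology. The classifier built on the 19 key
hubs separates early from late samples with AUC well above chance.

A thin CLI mirrors the library (`stagenet simulate|preprocess|degs|network|
preserve|attack|hubs|enrich|select|classify|run`); `stagenet run --config
cfg.json --seed 1 --out out/` executes everything and writes per-stage TSV
artifacts plus a single JSON report.

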