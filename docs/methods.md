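# Methods

`stagenet` implements a network-driven workflow for discovering tumor-stage
gene signatures from merged expression compendia, exercised end to end on
synthetic data with planted ground truth. This note records the models, the
parameters that matter, the numerical choices, and what the synthetic
benchmark does and does not demonstrate.

## The synthetic data model

Real inputs to this kind of analysis are several microarray cohorts merged
into one log2 expression matrix: hundreds of tumor and normal samples,
strong additive/multiplicative batch structure, a few thousand genes
differentially expressed between tumor and normal, and correlated gene
groups among tumor samples, at least one of which tracks clinical stage.
The generator (`stagenet.simdata`) emulates exactly that structure:

- **Modules.** Each planted module m has a per-sample latent factor
  `f_m ~ N(0, 1)`. A gene in m is `x = baseline + loading * f_m + eps`,
  `eps ~ N(0, noise_sd^2)`, with `loading in {loading_high, loading_low}`;
  the high-loading genes are the planted hubs.
- **Stage linkage.** For the designated stage module the factor over tumor
  samples is `rho * z_stage + sqrt(1 - rho^2) * z`, with `z_stage` the
  standardized early/late indicator, so `cor(f, stage) = rho = stage_effect`
  by construction (interpretable and testable; bias < 0.05 at n = 2000).
- **Differential expression.** The first `n_de_genes` genes (module genes
  first, by layout) receive a +/- `de_lfc` shift in tumor samples. Putting
  modules inside the DE set mirrors the analysis flow, where the network is
  built on DEGs only.
- **Batches.** Batch b adds a gene-wise shift `~ N(0, batch_shift_sd^2)` and
  scales residual noise by `exp(N(0, batch_scale_sd^2))`; batches are
  assigned round-robin within each group/stage stratum, so batch is not
  confounded with biology.

Defaults are a desk-scale rendition of a merged oral-cancer compendium:
2000 genes, 60 normal + 200 tumor samples in 3 batches, five modules of
80/60/50/40/35 genes (published modules span 35-339), `loading_high = 0.85`,
`loading_low = 0.7`, `noise_sd = 0.5` (within-module Pearson correlations
~0.5-0.75, eigengene variance explained ~0.5), `de_lfc = 1.5` on the log2
scale, `batch_shift_sd = 0.4`, `batch_scale_sd = 0.1`. The early/late split
of tumor samples is a free parameter: published cohorts do not pin a ratio.
`loading_low = 0.7` matters: a signed beta = 18 network raises pairwise
correlation `(1+r)/2` to the 18th power, so modules whose weakest genes
correlate only ~0.5 with each other dissolve under soft thresholding. That
is a property of the signed-power transform, not an artifact of this
package.

What the generator does **not** emulate: probe-level noise and platform
differences, heavy-tailed expression distributions, overlapping or nested
modules, correlated noise between modules, confounded batches, and any
gene-identity biology. Passing the planted-recovery tests therefore shows
the machinery is correct and calibrated under the assumed factor model; it
does not certify performance on real arrays.

## Preprocessing

- **Batch adjustment** is the parametric empirical-Bayes location/scale
  model: per gene, data are standardized against a design that protects the
  tumor/normal covariate; per batch, additive effects shrink toward a
  normal prior and variance ratios toward an inverse-gamma prior
  (hyperparameters by method of moments across genes), solved by the usual
  fixed-point iteration (relative tolerance 1e-4). Genes with zero pooled
  or within-batch variance pass through unadjusted. The implementation is
  pinned against an independent R reference to ~1e-13 in the test suite.
  Shrinkage implies batch means are equalized exactly only when genes are
  exchangeable; with gene-specific offsets a small prior-ward residual
  remains by design.
- **Steady-state filter.** The SVD is taken of the uncentered matrix, so a
  dominant shared offset loads on the first eigenfeature; if its
  eigen-fraction s1^2/sum(s^2) reaches `steady_state_threshold` (default
  0.90) the rank-1 component is subtracted. The eigen-fraction spectrum and
  its normalized Shannon entropy are always reported; entropy is
  descriptive, not a gate. Real compendia show ~98% steady state with
  entropy ~0.02, which is the regime the default targets.
- **Variance filter** removes genes strictly below the `drop_quantile`
  variance quantile (ties kept).

## Differential expression

Two-group moderated t: per gene, pooled residual variance s^2 with
d = n_a + n_b - 2 df; prior (d0, s0^2) estimated by moment-matching a
scaled-F model on log s^2 (digamma/trigamma matching, Newton iteration for
the trigamma inverse; d0 = infinity when the moment equation has no
positive root); posterior variance (d0 s0^2 + d s^2)/(d0 + d); two-sided p
from t with d0 + d df capped at the summed residual df; Benjamini-Hochberg
q. The suite verifies equality with the standard Bioconductor
implementation to 1e-10 on a shared fixture. DEG selection requires
|log2 FC| >= 1 ("twofold") and q < 0.05 simultaneously.

## Network construction and modules

Signed adjacency `a_ij = ((1 + cor_ij)/2)^beta` with zero diagonal; the
default beta = 18 follows the published analysis (signed scale-free fit
R^2 = 0.95 there); `pick_soft_power` chooses the smallest beta whose signed
R^2 reaches 0.90, falling back to the argmax. The scale-free fit bins
connectivities into 10 **equal-width** bins and regresses log10 frequency on
log10 mean connectivity; equal-count bins would flatten the frequency axis
by construction. TOM is the standard
`(sum_u a_iu a_uj + a_ij)/(min(k_i, k_j) + 1 - a_ij)` with unit diagonal.

Modules are branches of an average-linkage dendrogram of `1 - TOM`, cut at
`cut_height_quantile x (maximal merge height)` (default 0.99); branches
with >= `min_size` (default 30, near the smallest published module of 35)
become size-ranked modules (`module_1` largest), everything else is grey.
The cut is relative to the top of the dendrogram rather than a quantile of
merge heights because merge-height distributions of modular data are
bimodal — most merges happen at height ~0 inside tight modules, and a
quantile cut lands inside the noise regime and merges everything. A color
alias table (largest = "turquoise", ...) is provided for report cosmetics.

Module eigengenes are leading right-singular vectors of gene-standardized
module submatrices (unit norm, sign fixed to correlate nonnegatively with
the module mean profile); variance explained is the leading eigen-fraction.
GS is |Pearson cor(gene, stage trait)|, MS the module mean GS, K the
intramodular connectivity scaled by the module maximum (grey and singleton
modules get K = 0). Module-trait correlations use the Student-t transform
with n - 2 df and BH adjustment across modules; candidates require
|r| >= 0.3, and when several qualify the pipeline keeps positive-r modules
first, then maximal MS. The degree distribution can be tested against a
discrete power law (zeta-function MLE, KS-optimal xmin).

## Preservation and robustness

**Z-summary.** For each module: density statistic = mean within-module
adjacency in the test network; connectivity statistic = correlation between
intramodular connectivities in reference vs test. The permutation null
permutes module labels on the test side only — the module keeps its
reference connectivity pattern, which is paired against `n_perm` random
same-size gene sets drawn from the test network. Z = (obs - null mean)/null
sd per statistic; the summary averages the informative components (a
component whose null is numerically constant, as happens on exact
self-comparison, is excluded rather than allowed to produce a 0/0 score).
Interpretation bands: < 2 not preserved, 2-10 moderate, > 10 strong.
`resample_preservation` repeats this against column-subsampled test sets
(default fraction 0.5) and reports per-module mean/sd. Preservation
networks use beta = 6, the customary preservation power; it need not match
the module-detection power. Only two component statistics are used; the
larger ensembles of the reference methodology are deliberately simplified.

**Attack curves.** The module graph is binarized at `edge_min` (default
0.1, prominently configurable — published analyses rarely state this
threshold) and treated as simple, undirected, unweighted. Removal order is
computed once on the intact graph (simultaneous deletion; no recomputation)
per scheme — degree, betweenness (pair counts), classic per-component
closeness, eigenvector (power iteration, tol 1e-10) — with ties broken by
node id; the random scheme averages over 20 seeded permutations.
sigma(rho) is the largest-component fraction after each removal;
R = mean(sigma), V = 1/2 - R. R is bounded by (N-1)/2N, attained on
complete graphs.

## Hub calling and bootstrap selection

Hubs of the stage module satisfy GS > 0.2 and K > 0.3 (strict). Gene-set
enrichment of the hubs is an upper-tail hypergeometric test against GMT
sets intersected with the network universe, BH-adjusted.

Bootstrap elastic net: the objective is mean binomial deviance +
`lambda * ((1-alpha)/2 ||w||_2^2 + alpha ||w||_1)` on standardized
predictors with an unpenalized intercept. Each of `n_boot` (default 1000)
class-stratified bootstrap resamples tunes (alpha, lambda) by inner
5-fold CV deviance over the grid alpha in {0.1, 0.55, 1.0} (the customary
coarse mixing grid) and lambda in 7 log-spaced points in [1e-3, 1], refits,
and increments f for every nonzero coefficient. Tuning follows the CV
minimum by default (`rule="min"`); a one-standard-error rule is available
for sparser selections. Key hubs are hubs with `f > 0.675 * n_boot` —
0.675 = 0.9 x 0.75, the 90th-percentile cut of the fourth quartile, i.e.
f > 675 at 1000 bootstraps, with a strict comparison (675 of 1000 fails,
676 passes).

Two behaviors of this procedure are worth knowing. First, with correlated
module genes the deviance-minimizing fit keeps many near-redundant proxies
(averaging noisy proxies of one factor genuinely lowers deviance), so on
factor-driven data most hubs cross the frequency cut together; the
one-standard-error rule instead rotates a sparse representative set across
bootstraps and spreads f. Second, a pure-noise dataset of n = 200 samples
and 20 genes contains, a few tens of percent of the time, a gene whose
chance correlation with the labels reaches |r| ~ 0.2 (nominal p ~ 1e-3);
the selector then legitimately keeps it. No resampling scheme can undo a
dataset-level false positive, so null guarantees are about rates, not
certainty — in the pipeline the module-trait gate upstream is what stops
null datasets from reaching selection at all.

## Classification

Late stage is the positive class (early = 0). The protocol is a stratified
70/30 split (per class, round(0.7 n) to training), stratified 5-fold CV on
the training part with per-fold inner tuning and AUC scoring, a final
tuned refit on all training samples, and holdout evaluation reusing the
training standardization (leakage-free). AUC is the Mann-Whitney U
statistic with midranks (equal to the trapezoidal area under the swept ROC
polyline, asserted to 1e-12 in the tests); accuracy uses a 0.5 probability
cutoff (published work leaves this convention unstated). The 5-fold CV is
the resampling layer; no additional bootstrap is nested inside it.

## Elastic-net solver

Fits use scikit-learn's saga solver with `C = 1/(lambda n)`, which makes
sklearn's objective proportional to the mean-deviance form above. Final
fits run at tol 1e-6 (max 5000 iterations); tuning paths are warm-started
across the descending lambda grid at tol 1e-4 (max 1000), since CV
deviance differences between grid points dwarf solver error at that level.
Non-converged fits at extreme grid points are tolerated during tuning.

## Problem sizes in tests and the acceptance script

The published analysis used ~22k genes and 486 arrays with 1000 bootstraps;
this package's checks run the same machinery at desk scale: structure
recovery at 1000 genes x 200 tumor samples over 10 seeds, bootstrap
selection at 30-200 bootstraps, preservation at 5-30 resamples x 60-200
permutations, and the acceptance pipeline at 800 genes, 230 samples,
200 bootstraps. These sizes are the package's own choices for a laptop-
class run; every threshold and statistic is identical to the full-scale
protocol.

## Known limitations

- Static relative-height tree cut, not the dynamic hybrid cut; modules
  merging by eigengene similarity is not implemented.
- Two-group moderated t only (no general linear contrasts).
- Preservation uses two component statistics, not the full ensemble.
- Attack analysis is unweighted and one-shot (no centrality recomputation
  after removals).
- Pathway-topology perturbation analysis and external database
  cross-referencing (GO topology, COSMIC-style lookups) are out of scope;
  enrichment is plain hypergeometric against user-supplied GMT sets.
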