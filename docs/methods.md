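# Methods

This note records the statistical model behind `netsig`, the choices made
where the design was genuinely open, and what the synthetic benchmarks do
and do not demonstrate.

## Co-expression scoring

Pearson correlations are computed per cohort over the shared gene panel;
zero-variance genes get correlation 0 to every partner (with a warning)
rather than being dropped, so matrices stay aligned across cohorts — the
inter-cohort distance requires identical gene sets. The CLR-style
adjustment z-scores |r_ij| against the off-diagonal background of each
gene's row (population SD, ddof = 0) and averages the two marginal scores.
This variant is signed: pairs weaker than their genes' backgrounds score
negative and are removed by the z > 0 threshold. The canonical CLR
combination √(max(0,m_i)² + max(0,m_j)²) is non-negative and was not used,
because downstream stages rely on the signed scores to prune edges.
A row with zero background SD contributes marginal scores of 0.

Because the scores are standardized per row, their sampling noise scales
like (1/√n)/σ_row: cohorts of very different sample size differ in score
scale, and the element-wise distance partially reflects that. The bundled
demo therefore uses cohorts of similar size; with strongly unequal cohorts
the clustering stage should be interpreted with care.

## Tumour clustering

d(A,B) is the Frobenius norm of the difference of the thresholded score
matrices — both triangles of the n² grid enter the double sum (the zeroed
diagonals contribute nothing). Ward linkage is applied to these distances
via the squared-distance Lance–Williams update (Ward.D2 semantics;
monotone merge heights). The branch cut is a simplified dynamic cut:
branches below a height form clusters, and clusters below
`min_cluster_size` (default 2) are merged into the nearest cluster by
average inter-cluster distance. When no explicit `cut_height` is given,
the height is chosen adaptively: every gap between consecutive merge
heights is a candidate, each candidate partition (2–8 clusters) is scored
by its mean silhouette coefficient against the distance matrix, and the
best-scoring gap wins (ties favour fewer clusters). A single largest-gap
rule was rejected because with unequal group sizes the biggest gap often
sits between the two top merges and can then only ever produce two
clusters. Structureless data will still be split into whichever partition
maximizes the (near-zero) silhouette; the published full dynamic tree cut
algorithm, with its many tuning parameters, is out of scope.

## Cluster networks and component selection

An edge of the cluster network requires a template interaction and a
positive pooled CLR score; the weight is the score. Isolated nodes are
retained in the node set but never analysed. Components are selected
largest-first: the giant component always, then each next component while
its size is at least `size_ratio` (default 0.5) of the giant — a
formalization of "keep secondary components of comparable size"; size ties
keep both.

## Spectral centrality

For a connected component with weighted Laplacian L = D − W, the default
diffusivity functional is the total relaxation time F = Σ 1/λ_k over
nonzero eigenvalues (a Kirchhoff-type quantity; large F = slow global
diffusion); λ₂ (algebraic connectivity) is available as an alternative.
SC_i = |F(G) − F(G∖i)|/F(G), where the remainder after removing i is
restricted to its largest connected component; the number of nodes cut off
is reported alongside the score. Scoring the giant remainder keeps SC
finite and rankable where assigning "infinite" centrality to every cut
vertex would not. For total relaxation, uniform rescaling of all weights
cancels exactly in the normalization.

Numerical choices: dense symmetric eigensolver (the analysed components
are a few hundred nodes); eigenvalues below 1e−9 in absolute value are
treated as zero. The signature is the ⌈(1 − p/100)·N⌉ top-SC nodes over
the union of selected components (p = 90 by default); boundary ties are
broken by higher strength, then lexicographic gene id, with a warning —
the selection is deterministic.

The total-relaxation functional is dominated by the smallest nonzero
eigenvalues, i.e. by the most weakly attached structures. On
CLR-weighted networks this has a practical consequence: node importance
reflects *attachment control* (whose removal strands or nearly strands
other nodes), not raw strength. Degree alone therefore does not make a
node spectrally central; position does.

## Mutation proximity

Distances are unweighted hop counts (the scientific question is
neighbourhood membership, not path cost); a mutated signature gene scores
0; unreachable genes are excluded from the mean and counted. The null
draws gene sets of the signature's size uniformly from the selected
components (degree-preserving sampling is intentionally not the default).
The p-value is (1 + #{null ≤ observed})/(B + 1), one-sided toward
proximity, with one refinement: hop-count means live on a coarse lattice
and tie heavily, which makes the plain "≤" count conservative enough to
fail uniformity under the null. Ties between null and observed statistics
are therefore split uniformly at random using the test's own seeded
generator — exactly uniform under exchangeability, bit-reproducible given
the seed, and identical to the plain count whenever there are no ties.

## Survival analysis

Patients are standardized per gene (pooled over the cluster) before
k-means with k = 2 (best of `n_init` restarts); standardization prevents
scale-dominant genes from owning the split. Group 0 is always the
worse-outcome group: smaller Kaplan–Meier median survival, falling back to
smaller mean observed time when a median is undefined. Kaplan–Meier
estimates use Greenwood 95% bands; the log-rank test is the standard
two-group chi-square with simultaneous risk-set accounting for ties (both
via lifelines). The imbalance index is the total-variation distance
between the two groups' tumour compositions,
S_T = ½ Σ_t |n_{t,0}/n_0 − n_{t,1}/n_1|, chosen for its [0, 1] range with
both extremes attained (0 = identical composition, 1 = fully segregated).
The random-signature benchmark reruns the stratification for R random
same-size gene sets and ranks the observed log-rank p among random
signatures whose S_T lies within ±0.05 of the observed one.

## Pharmacology

Target enrichment is tested at the gene level (a gene is "targeted" if at
least one drug lists it) with a one-sided Fisher exact test against the
template-network universe. IC50 contrasts are Welch t-tests (group sizes
are unbalanced by construction) on natural-log IC50 — the log scale makes
the contrast invariant to the concentration unit; cell lines with fewer
than two drugs in either group are skipped with a warning.

## The synthetic generator

The generator plants exactly the structure the pipeline is designed to
detect, in a "ring of modules" design:

* genes partition into co-expression modules (equicorrelated factor blocks,
  always PSD; default within-module correlation 0.6–0.75 before
  measurement noise of SD 0.5, which attenuates correlations by
  1/(1 + sd²));
* the first gene of each module is its hub; hubs share an extra latent
  factor (pairwise correlation 0.3) and are wired as a template clique, so
  their connector edges reliably carry positive CLR weight;
* each module is internally wired as a ring plus random chords (mean extra
  degree 4) and reaches the rest of the template only through its hub,
  plus a sparse noise background (mean cross degree 1); hubs are topped up
  to 3× the background mean degree;
* tumour clusters share the module layout but express different module
  subsets strongly (hot ρ vs cold ρ), which separates their score matrices
  while keeping every hub recoverable in every cluster;
* mutations are Bernoulli with rate `enrichment × base_rate` (capped at 1)
  within one hop of the hubs and `base_rate` elsewhere;
* survival is exponential with the hazard multiplied by `hazard_ratio` for
  patients whose mean standardized signature expression is positive;
  censoring is independent exponential with the rate chosen so each
  subject is censored with exactly the requested probability (the simplest
  mechanism compatible with the Kaplan–Meier assumptions);
* drug targets are assigned uniformly over genes; log-IC50 is normal with
  the mean shifted down by `signature_effect` for drugs targeting a hub.

The connector-clique design is deliberate: experiments during development
showed that planting hubs by elevated degree alone does not make them
spectrally central under the total-relaxation functional — weakly attached
noise edges elsewhere dominate the spectrum. Modules that attach to the
network exclusively through their hub, over correlation-backed connector
edges whose weights are bounded away from zero, are the minimal structure
for which CLR scoring, matrix-distance clustering and spectral hub
recovery are all identifiable at once.

What the generator does **not** emulate: real expression marginals (all
signals are Gaussian), batch or platform effects, realistic PPI topology
(only its modular, hub-bridged skeleton), linked mutational processes,
covariate-dependent censoring, or dose–response curve shapes. Passing
benchmarks therefore show the pipeline recovers the structure it assumes,
under that structure — not that real tumour cohorts satisfy the
assumptions.

## Problem sizes

The bundled demo uses 120 genes in 10 modules, 11 cohorts of 140–180
samples in planted groups of 2/6/3 (≈1700 samples), B = 1000 proximity
permutations and R = 100 benchmark signatures; the statistical test suite
uses up to 200 genes, 40 clustering seeds, 25 signature-recovery seeds and
500-replicate calibrations. These sizes were chosen so the full test suite
and the end-to-end demo each complete in minutes on a single CPU while
leaving every statistical check well-powered.

## Known limitations

* The CLR variant and the diffusivity functional are each one of several
  defensible conventions; both are exposed as parameters, and results
  should be reported per functional.
* Eq.-style matrix distances inherit the per-row standardization scale, so
  cohorts with very different sample sizes drift apart regardless of
  pattern (see above).
* The simplified dynamic cut is not the published hybrid algorithm; with
  weak separation it can under- or over-split.
* The permutation null is uniform over network genes, not
  degree-preserving; for signatures concentrated on high-degree nodes the
  test is anti-conservative with respect to a degree-matched null (a
  degree-preserving option is a natural extension).
* Multivariate survival adjustment (age, stage, tumour type as covariates)
  is out of scope.
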