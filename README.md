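# netsig

Multi-tumour network integration: cluster tumour transcriptome cohorts by
their co-expression structure, build cluster-specific weighted
protein-interaction networks, extract gene signatures by spectral (Laplacian)
centrality, and validate the signatures against somatic mutations, patient
survival and drug-sensitivity screens.

## The problem

Tumours from different tissues can share transcriptional programmes, and
those shared programmes suggest shared drug targets. Given expression
matrices for several tumour cohorts and a template protein–protein
interaction (PPI) network of cancer-associated genes, the pipeline asks:

1. Which cohorts have similar gene–gene correlation structure?
2. Within each group of cohorts, which genes are topologically critical in
   the co-expression-weighted interaction network?
3. Do those genes sit near somatic mutations, stratify patient survival, and
   predict drug sensitivity?

## The method

**Co-expression scores.** For each cohort, pairwise Pearson correlations
r<sub>ij</sub> over the shared gene panel are background-corrected in the
style of the Context Likelihood of Relatedness (CLR): with
x<sub>ij</sub> = |r<sub>ij</sub>| and per-gene off-diagonal background
(μ<sub>i</sub>, σ<sub>i</sub>),

    z_ij = ( (x_ij − μ_i)/σ_i + (x_ij − μ_j)/σ_j ) / 2 ,

a signed, symmetric score; only z<sub>ij</sub> > 0 is kept.

**Tumour clustering.** Cohorts are compared by the element-wise Euclidean
distance between their thresholded score matrices,
d(A,B) = √(Σ<sub>ij</sub> (a<sub>ij</sub> − b<sub>ij</sub>)²), clustered
with Ward-linkage hierarchical clustering, and partitioned by a simplified
dynamic branch cut (adaptive height + minimum cluster size).

**Cluster networks and signatures.** Pooling all samples of a cluster, the
CLR scores are superimposed on the template PPI: an edge requires both a
physical interaction and z<sub>ij</sub> > 0, with weight z<sub>ij</sub>.
On the largest component(s), each node i is scored by spectral centrality

    SC_i = |F(G) − F(G∖i)| / F(G) ,

where F is a Laplacian diffusivity functional — by default the total
relaxation time Σ<sub>k</sub> 1/λ<sub>k</sub> over nonzero eigenvalues of
L = D − W. The top decile of SC forms the cluster's gene signature.

**Validation.** (i) Mean hop distance from signature genes to the nearest
mutated gene, with a permutation null of random same-size gene sets;
(ii) k-means (k = 2) patient stratification on signature expression with
Kaplan–Meier curves, the log-rank test, and a tumour-composition imbalance
index S_T ∈ [0, 1]; (iii) Fisher enrichment of drug targets in the
signature and per-cell-line Welch t contrasts of ln IC50 for
signature-targeting versus other drugs.

A synthetic-data module generates all inputs with planted structure
(co-expression modules joined through a correlated hub core, mutations
enriched near hubs, survival hazards tied to hub expression, hub-targeting
drugs with lower IC50), so the whole pipeline is testable offline.

## Worked example

```bash
python examples/01_simulate_and_cluster.py
```

```
tumour -> cluster: {'T01': 0, 'T02': 0, 'T03': 1, ..., 'T11': 2}
clusters found: 3   planted: 3
adjusted Rand index vs planted groups: 1.00
```

Eleven simulated cohorts in three planted co-expression groups are
recovered exactly (ARI = 1). Continuing with the signature stage:

```bash
python examples/02_spectral_signature.py
```

```
selected components: [200] nodes
signature size: 20 (top decile of 200 scored genes)
planted hubs recovered: 100%
overlap with top-degree set:      12/20
overlap with top-betweenness set: 12/20
```

The top-decile spectral-centrality signature contains all ten planted
module-connector hubs, and only partially overlaps the rankings by degree
or betweenness — the diffusivity criterion is not reducible to either.
`examples/03–06` continue with mutation proximity (permutation p ≈ 0.06 on
that run), survival stratification (log-rank p ≈ 5 × 10⁻¹⁵ with imbalance
S_T ≈ 0.08 and rank 0 among random signatures), drug sensitivity (20/20
cell lines with lower IC50 for signature-targeting drugs), and the full
pipeline with its reproducibility manifest.

The same stages are scriptable from the shell:

```bash
netsig run-all --seed 1 --outdir demo_run      # full pipeline + manifest
netsig simulate / coexpress / cluster / build-net / centrality / signature \
       / mut-prox / survival / pharma          # individual stages
```

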