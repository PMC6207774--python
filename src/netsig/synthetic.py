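"""Synthetic multi-tumour data with planted structure.

Generates every input the analysis pipeline consumes — per-tumour expression
matrices, a template protein-interaction network, per-cluster mutation tables,
clinical survival records and drug/IC50 tables — with the statistical structure
the downstream method assumes:

* tumours belonging to the same planted cluster share the same block-correlated
  expression covariance (an equicorrelated-factor construction, always PSD);
* designated hub genes are wired with elevated degree in the template network,
  making them the planted diffusivity-central nodes;
* mutations are enriched in the one-hop neighbourhood of the hubs;
* survival hazard depends on mean standardized signature-gene expression;
* log-IC50 is shifted down for drugs targeting hub genes.

Everything is deterministic given the design / function seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import stage_rng

__all__ = [
    "SyntheticDesign",
    "ring_module_design",
    "generate_template_network",
    "generate_expression",
    "generate_mutations",
    "generate_survival",
    "generate_pharma",
]


@dataclass(frozen=True)
class SyntheticDesign:
    """Full description of a planted multi-tumour study.

    Parameters
    ----------
    n_genes:
        Number of genes shared by every tumour dataset.
    tumours:
        Sequence of ``(tumour_id, n_samples, planted_cluster)`` triples.
    k_planted_clusters:
        Number of distinct planted tumour clusters.
    block_spec:
        ``{cluster: [(gene_indices, rho), ...]}`` — within-block equicorrelation
        ``0 <= rho < 1``; blocks of one cluster must be disjoint.
    hub_genes:
        ``{cluster: [gene_indices]}`` — genes planted as network-central.
    connector_spec:
        ``{cluster: [(gene_list, delta)]}`` — connector groups whose members
        share an extra latent factor (pairwise correlation ``delta``), so
        the template edges wired among them carry a reproducible positive
        co-expression score; ``0 <= delta < 1``.
    noise_sd:
        SD of independent measurement noise added on top of the unit-variance
        correlated signal (attenuates within-block correlation by 1/(1+sd^2)).
    seed:
        Base seed; all generators derive their streams from it.
    """

    n_genes: int
    tumours: tuple
    k_planted_clusters: int
    block_spec: dict
    hub_genes: dict
    connector_spec: dict | None = None
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 4:
            raise ValueError("n_genes too small")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        object.__setattr__(self, "tumours", tuple((str(t), int(n), int(c)) for t, n, c in self.tumours))
        ids = [t for t, _, _ in self.tumours]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate tumour ids")
        for t, n, c in self.tumours:
            if n < 4:
                raise ValueError(f"tumour {t}: n_samples must be >= 4")
            if not (0 <= c < self.k_planted_clusters):
                raise ValueError(f"tumour {t}: planted_cluster {c} out of range")
        for c, blocks in self.block_spec.items():
            seen: set = set()
            for genes, rho in blocks:
                genes = list(genes)
                if not (0 <= rho < 1):
                    raise ValueError(f"cluster {c}: block correlation rho={rho} outside [0, 1)")
                if any(g < 0 or g >= self.n_genes for g in genes):
                    raise ValueError(f"cluster {c}: block gene index out of range")
                if seen & set(genes):
                    raise ValueError(f"cluster {c}: overlapping blocks")
                seen |= set(genes)
        for c, hubs in self.hub_genes.items():
            if any(g < 0 or g >= self.n_genes for g in hubs):
                raise ValueError(f"cluster {c}: hub gene index out of range")
        if self.connector_spec is None:
            object.__setattr__(self, "connector_spec", {})
        for c, groups in self.connector_spec.items():
            for genes, delta in groups:
                genes = list(genes)
                if not (0 <= delta < 1):
                    raise ValueError(f"cluster {c}: connector delta={delta} outside [0, 1)")
                if len(genes) < 2 or len(set(genes)) != len(genes):
                    raise ValueError(f"cluster {c}: connector group needs >= 2 distinct genes")
                if any(g < 0 or g >= self.n_genes for g in genes):
                    raise ValueError(f"cluster {c}: connector gene index out of range")

    @property
    def gene_names(self) -> list:
        width = max(4, len(str(self.n_genes)))
        return [f"G{i:0{width}d}" for i in range(self.n_genes)]

    def hub_names(self, cluster: int) -> list:
        names = self.gene_names
        return [names[g] for g in self.hub_genes.get(cluster, [])]

    def planted_labels(self) -> dict:
        return {t: c for t, _, c in self.tumours}


def _modules_of(design: SyntheticDesign) -> list:
    """Distinct gene blocks across clusters, deduplicated, deterministic order."""
    seen, out = set(), []
    for c in sorted(design.block_spec):
        for genes, _rho in design.block_spec[c]:
            key = frozenset(genes)
            if key not in seen:
                seen.add(key)
                out.append(sorted(genes))
    return out


def generate_template_network(
    design: SyntheticDesign,
    hub_degree_ratio: float = 3.0,
    chord_degree: float = 4.0,
    cross_degree: float = 1.0,
    seed: int | None = None,
) -> nx.Graph:
    """Template PPI-like network with modular structure and high-degree hubs.

    Wiring follows the design's correlation blocks, mimicking protein
    complexes embedded in a sparse interactome:

    * each block becomes a connected module (a ring over its genes plus
      random chords at ``chord_degree`` mean extra degree);
    * every connector group of ``connector_spec`` is wired as a clique
      (these are the correlated inter-module connector edges);
    * a sparse background of cross-module edges is added at ``cross_degree``
      mean degree per gene;
    * each hub is topped up, module mates first, until its degree reaches
      ``hub_degree_ratio`` times the realized background mean degree.
    """
    n = design.n_genes
    if n < 20:
        raise ValueError("template network needs at least 20 genes")
    all_hubs = sorted({g for hubs in design.hub_genes.values() for g in hubs})
    if len(all_hubs) > 0.2 * n:
        raise ValueError(
            f"hub sets cover {len(all_hubs)}/{n} genes (> 20%); planted signal would be "
            "unrecoverable by a top-decile rule"
        )
    rng = stage_rng(design.seed if seed is None else seed, "template_network")
    names = design.gene_names
    g = nx.Graph()
    g.add_nodes_from(names)
    modules = _modules_of(design)
    module_of = {}
    for mi, mod in enumerate(modules):
        for x in mod:
            module_of.setdefault(x, mi)
    for mod in modules:
        k = len(mod)
        if k >= 3:
            for i in range(k):  # ring keeps every module connected
                g.add_edge(names[mod[i]], names[mod[(i + 1) % k]])
        p = min(1.0, chord_degree / max(1, k - 1))
        for i in range(k):
            for j in range(i + 2, k):
                if (i, j) != (0, k - 1) and rng.random() < p:
                    g.add_edge(names[mod[i]], names[mod[j]])
    for c in sorted(design.connector_spec):
        for genes, _delta in design.connector_spec[c]:
            genes = sorted(genes)
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    g.add_edge(names[genes[i]], names[genes[j]])
    # sparse background of cross-module / unassigned-gene edges
    iu, ju = np.triu_indices(n, k=1)
    diff = np.array(
        [module_of.get(i, -1) != module_of.get(j, -2) or module_of.get(i, -1) == -1
         for i, j in zip(iu, ju)]
    )
    keep = diff & (rng.random(iu.size) < min(1.0, cross_degree / (n - 1) * 2))
    g.add_edges_from((names[i], names[j]) for i, j in zip(iu[keep], ju[keep]))
    # top hubs up to the requested degree ratio with cross-module contacts,
    # keeping the hub's one-hop neighbourhood a proper subset of the genome
    non_hub_deg = [g.degree(names[i]) for i in range(n) if i not in set(all_hubs)]
    target = int(round(hub_degree_ratio * max(1.0, float(np.mean(non_hub_deg)))))
    for h in all_hubs:
        hub = names[h]
        mates = {names[x] for x in modules[module_of[h]] if x != h} if h in module_of else set()
        cross = [v for v in names if v != hub and v not in mates and not g.has_edge(hub, v)]
        pool = [str(v) for v in rng.permutation(cross)]
        pool += [v for v in sorted(mates) if not g.has_edge(hub, v)]
        for v in pool[: max(0, target - g.degree(hub))]:
            g.add_edge(hub, v)
    giant = max(nx.connected_components(g), key=len)
    if len(giant) < 0.8 * n:
        raise RuntimeError(
            f"giant component covers only {len(giant)}/{n} nodes; raise cross_degree or add bridges"
        )
    return g


def _cluster_correlation(design: SyntheticDesign, cluster: int) -> np.ndarray:
    """Planted correlation matrix of one cluster (before measurement noise)."""
    c = np.eye(design.n_genes)
    for genes, rho in design.block_spec.get(cluster, []):
        idx = np.asarray(list(genes))
        for a in idx:
            for b in idx:
                if a != b:
                    c[a, b] = rho
    return c


def generate_expression(design: SyntheticDesign) -> dict:
    """Per-tumour expression matrices (genes x samples DataFrames).

    Within each planted block, gene ``i`` is ``sqrt(rho) * f_block +
    sqrt(1-rho) * e_i``; independent N(0, noise_sd^2) noise is added to every
    gene, so the realized within-block correlation is ``rho / (1 + noise_sd^2)``.
    Connector groups then mix in a shared factor:
    ``x <- sqrt(1-delta) * x + sqrt(delta) * f_group``, giving group members
    pairwise correlation ``delta`` while preserving unit signal variance.
    """
    names = design.gene_names
    out: dict = {}
    for tid, n_samples, cluster in design.tumours:
        rng = stage_rng(design.seed, f"expression/{tid}")
        x = rng.standard_normal((design.n_genes, n_samples))
        for genes, rho in design.block_spec.get(cluster, []):
            idx = np.asarray(list(genes))
            f = rng.standard_normal(n_samples)
            x[idx, :] = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * x[idx, :]
        for genes, delta in design.connector_spec.get(cluster, []):
            f = rng.standard_normal(n_samples)
            idx = np.asarray(list(genes))
            x[idx, :] = np.sqrt(1.0 - delta) * x[idx, :] + np.sqrt(delta) * f
        x = x + design.noise_sd * rng.standard_normal(x.shape)
        cols = [f"{tid}_S{i:04d}" for i in range(n_samples)]
        out[tid] = pd.DataFrame(x, index=names, columns=cols)
    return out


def ring_module_design(
    tumours,
    n_modules: int = 10,
    module_size: int = 20,
    k_clusters: int = 1,
    rho_hot: float = 0.7,
    rho_cold: float = 0.35,
    hub_core_delta: float = 0.3,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> SyntheticDesign:
    """Canonical planted design: co-expression modules joined by a hub core.

    Genes are partitioned into ``n_modules`` modules of ``module_size``; the
    first gene of each module is its hub. The hubs form a connector group
    sharing a latent factor (pairwise correlation ``hub_core_delta``) and are
    wired as a clique in the template, so each module reaches the rest of
    the network only through its hub — the planted diffusivity-central
    genes. Tumour clusters share the module layout but differ in which
    modules are strongly co-expressed: cluster ``c`` expresses module ``m``
    at ``rho_hot`` when ``m % k_clusters == c`` and at ``rho_cold``
    otherwise, which separates the clusters' CLR score matrices while
    keeping every module (and hence every hub) recoverable in every cluster.
    """
    n_genes = n_modules * module_size
    modules = [list(range(m * module_size, (m + 1) * module_size)) for m in range(n_modules)]
    hubs = [mod[0] for mod in modules]
    block_spec, hub_genes, connector_spec = {}, {}, {}
    for c in range(k_clusters):
        block_spec[c] = [
            (mod, rho_hot if m % k_clusters == c else rho_cold) for m, mod in enumerate(modules)
        ]
        hub_genes[c] = list(hubs)
        connector_spec[c] = [(list(hubs), hub_core_delta)]
    return SyntheticDesign(
        n_genes=n_genes,
        tumours=tuple(tumours),
        k_planted_clusters=k_clusters,
        block_spec=block_spec,
        hub_genes=hub_genes,
        connector_spec=connector_spec,
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_mutations(
    design: SyntheticDesign,
    network: nx.Graph,
    enrichment: float = 5.0,
    base_rate: float = 0.02,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-cluster mutation flags, enriched within one hop of the planted hubs.

    Genes at shortest-path distance <= 1 from a cluster's hub set are mutated
    with probability ``min(1, enrichment * base_rate)``, all others with
    ``base_rate``. Returns tidy records ``(cluster_id, gene, mutated)``.
    """
    if not (0 < base_rate < 1):
        raise ValueError("base_rate must lie in (0, 1)")
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    rng = stage_rng(design.seed if seed is None else seed, "mutations")
    names = design.gene_names
    rows = []
    for cluster in range(design.k_planted_clusters):
        hubs = set(design.hub_names(cluster))
        near = set(hubs)
        for h in hubs & set(network.nodes):
            near |= set(network.neighbors(h))
        p_near = min(1.0, enrichment * base_rate)
        u = rng.random(len(names))
        for g, ug in zip(names, u):
            p = p_near if g in near else base_rate
            rows.append((cluster, g, bool(ug < p)))
    return pd.DataFrame(rows, columns=["cluster_id", "gene", "mutated"])


def generate_survival(
    expression: pd.DataFrame,
    signature_genes,
    hazard_ratio: float = 3.0,
    censor_rate: float = 0.3,
    seed: int = 0,
    tumour_of: dict | None = None,
    baseline_scale: float = 1000.0,
) -> pd.DataFrame:
    """Clinical table whose hazard depends on signature-gene expression.

    Each patient's latent group is the sign of their mean standardized
    signature expression; the high-expression group's exponential event hazard
    is multiplied by ``hazard_ratio``. Censoring is independent exponential
    with the rate chosen so each subject is censored with probability
    ``censor_rate`` exactly. Times are in days.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must lie in [0, 1)")
    signature_genes = list(signature_genes)
    if not signature_genes:
        raise ValueError("signature_genes must be nonempty")
    missing = [g for g in signature_genes if g not in expression.index]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing}")
    rng = stage_rng(seed, "survival")
    sub = expression.loc[signature_genes]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sub.std(axis=1).replace(0.0, 1.0), axis=0)
    score = z.mean(axis=0)
    high = score.to_numpy() > 0
    lam = (1.0 / baseline_scale) * np.where(high, hazard_ratio, 1.0)
    t_event = rng.exponential(1.0 / lam)
    if censor_rate > 0:
        mu = lam * censor_rate / (1.0 - censor_rate)
        t_cens = rng.exponential(1.0 / mu)
    else:
        t_cens = np.full_like(t_event, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    patients = list(expression.columns)
    tumours = [tumour_of.get(p, p.split("_S")[0]) if tumour_of else p.split("_S")[0] for p in patients]
    return pd.DataFrame(
        {"patient_id": patients, "tumour_id": tumours, "time": time, "event": event}
    )


def generate_pharma(
    design: SyntheticDesign,
    n_drugs: int = 50,
    n_cell_lines: int = 20,
    signature_effect: float = 2.0,
    seed: int | None = None,
    max_targets_per_drug: int = 3,
) -> tuple:
    """Drug->target map and a cell-line x drug IC50 table.

    Targets are assigned uniformly over genes; log-IC50 is N(0, 1) in log-uM
    units, with the mean shifted down by ``signature_effect`` for drugs that
    target at least one planted hub gene. Returns ``(targets, ic50)`` frames.
    """
    if n_drugs < 4:
        raise ValueError("need at least 4 drugs")
    rng = stage_rng(design.seed if seed is None else seed, "pharma")
    names = design.gene_names
    hub_union = {g for c in range(design.k_planted_clusters) for g in design.hub_names(c)}
    drug_ids = [f"D{i:03d}" for i in range(n_drugs)]
    target_rows = []
    hub_drug = {}
    for d in drug_ids:
        k = int(rng.integers(1, max_targets_per_drug + 1))
        genes = rng.choice(names, size=k, replace=False)
        hub_drug[d] = any(g in hub_union for g in genes)
        target_rows += [(d, str(g)) for g in genes]
    targets = pd.DataFrame(target_rows, columns=["drug_id", "gene"])
    ic_rows = []
    for c in range(n_cell_lines):
        cl = f"CL{c:03d}"
        for d in drug_ids:
            mu = -signature_effect if hub_drug[d] else 0.0
            ic_rows.append((cl, d, float(np.exp(mu + rng.standard_normal()))))
    ic50 = pd.DataFrame(ic_rows, columns=["cell_line", "drug_id", "ic50"])
    return targets, ic50
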