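"""End-to-end pipeline: config validation, stage chaining, manifest.

A run executes coexpression -> tumour clustering -> cluster networks ->
spectral-centrality signatures -> validations (mutation proximity, survival,
pharmacology), writing every stage output plus a JSON manifest that records
parameters, seeds, input checksums and output file checksums. Reruns with an
identical config are bit-identical. Inputs are either read from paths or
simulated by the synthetic module when the config has a ``simulate`` section.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
import yaml

from . import centrality, clustering, coexpression, io, netbuild, pharm, proximity, survival, synthetic
from ._util import stage_seed

__all__ = ["demo_config", "design_from_config", "validate_config", "run_pipeline", "load_config"]

_DEFAULT_PARAMS = dict(
    min_cluster_size=2,
    cut_height=None,
    size_ratio=0.5,
    percentile=90.0,
    functional="total_relaxation",
    proximity_b=1000,
    benchmark_r=100,
    kmeans_n_init=10,
    st_band=0.05,
)


def demo_config(seed: int = 1) -> dict:
    """Bundled synthetic demo: 11 tumours in 3 planted groups, 120 genes.

    A scaled-down stand-in for a multi-cohort study: tumour group sizes 2/6/3
    over 10 co-expression modules of 12 genes joined through a correlated hub
    core, plus all downstream inputs (mutations enriched near hubs, survival
    tied to hub expression, hub-targeting drugs with lower IC50).
    """
    return {
        "seed": int(seed),
        "simulate": {
            "n_modules": 10,
            "module_size": 12,
            "k_clusters": 3,
            "tumours": [
                ["T01", 160, 0], ["T02", 150, 0],
                ["T03", 180, 1], ["T04", 170, 1], ["T05", 160, 1],
                ["T06", 150, 1], ["T07", 140, 1], ["T08", 140, 1],
                ["T09", 170, 2], ["T10", 150, 2], ["T11", 140, 2],
            ],
            "rho_hot": 0.75,
            "rho_cold": 0.25,
            "hub_core_delta": 0.3,
            "noise_sd": 0.5,
            "hub_degree_ratio": 3.0,
            "mutation_enrichment": 8.0,
            "mutation_base_rate": 0.02,
            "hazard_ratio": 3.0,
            "censor_rate": 0.3,
            "n_drugs": 60,
            "n_cell_lines": 20,
            "signature_effect": 2.0,
        },
        "params": dict(_DEFAULT_PARAMS),
    }


def design_from_config(sim: dict, seed: int) -> synthetic.SyntheticDesign:
    """Build the ring-of-modules planted design from the ``simulate`` section."""
    return synthetic.ring_module_design(
        tumours=tuple((t, n, c) for t, n, c in sim["tumours"]),
        n_modules=int(sim.get("n_modules", 10)),
        module_size=int(sim.get("module_size", 12)),
        k_clusters=int(sim["k_clusters"]),
        rho_hot=float(sim.get("rho_hot", 0.7)),
        rho_cold=float(sim.get("rho_cold", 0.35)),
        hub_core_delta=float(sim.get("hub_core_delta", 0.3)),
        noise_sd=float(sim.get("noise_sd", 0.5)),
        seed=int(seed),
    )


def validate_config(config: dict) -> dict:
    """Normalize a run config; check paths exist before any computation."""
    cfg = dict(config)
    if "seed" not in cfg:
        raise ValueError("config needs a seed")
    cfg["params"] = {**_DEFAULT_PARAMS, **cfg.get("params", {})}
    if "simulate" not in cfg:
        inputs = cfg.get("inputs", {})
        need = ["expression_dir", "template_network", "mutations", "clinical", "drug_targets", "ic50"]
        missing = [k for k in need if k not in inputs]
        if missing:
            raise ValueError(f"config without a simulate section needs input paths: {missing}")
        for k in need:
            if not Path(inputs[k]).exists():
                raise ValueError(f"input path does not exist: {inputs[k]} ({k})")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        return validate_config(yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_inputs(cfg: dict, outdir: Path) -> dict:
    sim = cfg["simulate"]
    seed = int(cfg["seed"])
    design = design_from_config(sim, seed)
    template = synthetic.generate_template_network(
        design, hub_degree_ratio=float(sim.get("hub_degree_ratio", 3.0))
    )
    expression = synthetic.generate_expression(design)
    mutations = synthetic.generate_mutations(
        design, template,
        enrichment=float(sim.get("mutation_enrichment", 8.0)),
        base_rate=float(sim.get("mutation_base_rate", 0.02)),
    )
    clin_parts = []
    for c in range(design.k_planted_clusters):
        members = [t for t, _, pc in design.tumours if pc == c]
        pooled = pd.concat([expression[t] for t in members], axis=1)
        clin_parts.append(
            synthetic.generate_survival(
                pooled, design.hub_names(c),
                hazard_ratio=float(sim.get("hazard_ratio", 3.0)),
                censor_rate=float(sim.get("censor_rate", 0.3)),
                seed=stage_seed(seed, f"survival/{c}"),
            )
        )
    clinical = pd.concat(clin_parts, ignore_index=True)
    targets, ic50 = synthetic.generate_pharma(
        design,
        n_drugs=int(sim.get("n_drugs", 60)),
        n_cell_lines=int(sim.get("n_cell_lines", 20)),
        signature_effect=float(sim.get("signature_effect", 2.0)),
    )
    d = outdir / "inputs"
    d.mkdir(parents=True, exist_ok=True)
    for tid, expr in expression.items():
        io.write_expression(expr, d / f"expression_{tid}.tsv")
    io.write_network_tsv(template, d / "template_network.tsv")
    io.write_network_graphml(template, d / "template_network.graphml")
    io.write_mutations(mutations, d / "mutations.tsv")
    io.write_clinical(clinical, d / "clinical.tsv")
    io.write_drug_targets(targets, d / "drug_targets.tsv")
    io.write_ic50(ic50, d / "ic50.tsv")
    pd.DataFrame(
        [(t, c) for t, _, c in design.tumours], columns=["tumour_id", "planted_cluster"]
    ).to_csv(d / "planted_clusters.tsv", sep="\t", index=False)
    return dict(
        design=design, template=template, expression=expression,
        mutations=mutations, clinical=clinical, targets=targets, ic50=ic50,
    )


def _load_inputs(cfg: dict) -> dict:
    paths = cfg["inputs"]
    expr_dir = Path(paths["expression_dir"])
    expression = {
        p.stem.replace("expression_", ""): io.read_expression(p)
        for p in sorted(expr_dir.glob("expression_*.tsv*"))
    }
    if not expression:
        raise ValueError(f"no expression_*.tsv files under {expr_dir}")
    return dict(
        design=None,
        template=io.read_network_tsv(paths["template_network"]),
        expression=expression,
        mutations=io.read_mutations(paths["mutations"]),
        clinical=io.read_clinical(paths["clinical"]),
        targets=io.read_drug_targets(paths["drug_targets"]),
        ic50=io.read_ic50(paths["ic50"]),
    )


def run_pipeline(config: dict, outdir) -> dict:
    """Execute the full analysis; returns the manifest (also written as JSON).

    Stage errors propagate annotated with the stage name. All paths recorded
    in the manifest are relative to ``outdir`` so reruns are comparable.
    """
    cfg = validate_config(config)
    params = cfg["params"]
    seed = int(cfg["seed"])
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": _jsonable(cfg), "stages": {}, "outputs": {}}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:  # annotate failures with the stage
                raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc
        return deco

    @stage("inputs")
    def data():
        return _simulate_inputs(cfg, outdir) if "simulate" in cfg else _load_inputs(cfg)

    template, expression = data["template"], data["expression"]

    @stage("coexpression")
    def z_matrices():
        out = {}
        for tid, expr in expression.items():
            out[tid] = coexpression.threshold_matrix(
                coexpression.clr_adjust(coexpression.pearson_matrix(expr))
            )
        return out

    @stage("tumour_clustering")
    def assignment():
        dist = clustering.distance_matrix(z_matrices)
        linkage, labels = clustering.ward_tree(dist)
        assign = clustering.dynamic_cut(
            linkage, labels,
            min_cluster_size=int(params["min_cluster_size"]),
            cut_height=params["cut_height"], dist=dist,
        )
        io.write_matrix(dist, outdir / "tumour_distance.tsv")
        (outdir / "dendrogram.nwk").write_text(clustering.dendrogram_newick(linkage, labels))
        pd.DataFrame(sorted(assign.items()), columns=["tumour_id", "cluster"]).to_csv(
            outdir / "cluster_assignment.tsv", sep="\t", index=False
        )
        return assign

    clusters = sorted(set(assignment.values()))

    @stage("networks_and_signatures")
    def per_cluster():
        result = {}
        for c in clusters:
            members = sorted(t for t, cc in assignment.items() if cc == c)
            pooled = pd.concat([expression[t] for t in members], axis=1)
            z = coexpression.clr_adjust(coexpression.pearson_matrix(pooled))
            net = netbuild.build_cluster_network(template, z, cluster_id=c)
            comps = netbuild.select_components(net, size_ratio=float(params["size_ratio"]))
            scores = centrality.score_components(net, comps, functional=params["functional"])
            sig = centrality.extract_signature(
                scores, net, percentile=float(params["percentile"]), cluster_id=c
            )
            alt = centrality.alt_centralities(net, sorted(set().union(*comps)))
            tab = scores.join(alt).reset_index()
            tab.to_csv(outdir / f"centrality_cluster{c}.tsv", sep="\t", index=False)
            io.write_network_tsv(net, outdir / f"network_cluster{c}.tsv")
            result[c] = dict(members=members, pooled=pooled, net=net, comps=comps, signature=sig)
        io.write_gmt(
            {f"cluster{c}": result[c]["signature"].genes for c in clusters},
            outdir / "signatures.gmt",
        )
        return result

    @stage("mutation_proximity")
    def prox():
        out = {}
        mut = data["mutations"]
        for c in clusters:
            sub = mut[mut["mutated"]] if "mutated" in mut.columns else mut
            # cluster networks are matched to mutation clusters positionally
            mut_genes = set(sub[sub["cluster_id"] == c]["gene"]) if "cluster_id" in sub.columns else set(sub["gene"])
            if not mut_genes:
                continue
            res = proximity.proximity_permutation_test(
                per_cluster[c]["net"], per_cluster[c]["signature"], mut_genes,
                b=int(params["proximity_b"]),
                seed=stage_seed(seed, f"proximity/{c}"),
                size_ratio=float(params["size_ratio"]),
            )
            out[c] = res
        return out

    @stage("survival")
    def surv():
        out = {}
        clin = data["clinical"]
        for c in clusters:
            info = per_cluster[c]
            clin_c = clin[clin["tumour_id"].isin(info["members"])]
            patients = [p for p in clin_c["patient_id"] if p in info["pooled"].columns]
            if len(patients) < 20:
                continue
            grp = survival.kmeans_groups(
                info["pooled"], info["signature"], clin_c,
                seed=stage_seed(seed, f"kmeans/{c}"),
                n_init=int(params.get("kmeans_n_init", 10)),
            )
            stat, p = survival.logrank_test(grp)
            st = survival.imbalance_st(grp).st
            km = survival.km_estimate(grp)
            for g, tab in km.tables.items():
                tab.to_csv(outdir / f"km_cluster{c}_group{g}.tsv", sep="\t", index=False)
            grp.to_csv(outdir / f"groups_cluster{c}.tsv", sep="\t", index=False)
            pool_genes = sorted(set().union(*info["comps"]))
            bench = survival.random_signature_benchmark(
                info["pooled"], pool_genes, len(info["signature"]), clin_c,
                observed_signature=info["signature"],
                r=int(params["benchmark_r"]),
                seed=stage_seed(seed, f"benchmark/{c}"),
                n_init=int(params.get("kmeans_n_init", 10)),
                band=float(params["st_band"]),
            )
            bench.table.to_csv(outdir / f"benchmark_cluster{c}.tsv", sep="\t", index=False)
            out[c] = dict(logrank_stat=stat, logrank_p=p, st=st,
                          group_sizes=km.group_sizes, censored=km.censored,
                          benchmark_rank=bench.rank, benchmark_in_band=bench.n_in_band)
        return out

    @stage("pharmacology")
    def drugs():
        out = {}
        targets, ic50 = data["targets"], data["ic50"]
        universe = sorted(template.nodes)
        for c in clusters:
            sig = per_cluster[c]["signature"]
            enr = pharm.target_overrepresentation(sig, targets, universe)
            contrast = pharm.ic50_contrast(ic50, targets, sig)
            contrast.to_csv(outdir / f"ic50_contrast_cluster{c}.tsv", sep="\t", index=False)
            frac_lower = float((contrast["mean_log_diff"] < 0).mean()) if len(contrast) else float("nan")
            n_sig_lower = int(((contrast["p_value"] < 0.05) & (contrast["mean_log_diff"] < 0)).sum())
            out[c] = dict(
                enrichment_table=enr.table, enrichment_odds=enr.odds_ratio,
                enrichment_p=enr.p_value, frac_cell_lines_lower=frac_lower,
                n_cell_lines_significant=n_sig_lower, n_cell_lines_tested=len(contrast),
            )
        return out

    manifest["stages"] = {
        "clusters": {t: int(c) for t, c in sorted(assignment.items())},
        "signatures": {
            str(c): list(per_cluster[c]["signature"].genes) for c in clusters
        },
        "component_sizes": {str(c): [len(s) for s in per_cluster[c]["comps"]] for c in clusters},
        "mutation_proximity": {
            str(c): dict(observed=r.observed, p_value=r.p_value, b=r.b,
                         n_unreachable=r.n_unreachable)
            for c, r in prox.items()
        },
        "survival": {str(c): _jsonable(v) for c, v in surv.items()},
        "pharmacology": {str(c): _jsonable(v) for c, v in drugs.items()},
    }
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "item"):
        return obj.item()
    return obj
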