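"""Extract a spectral-centrality gene signature from a cluster network.

Builds a weighted network for one tumour cluster (template interactions
weighted by pooled CLR scores), ranks nodes by the change in total
relaxation time (sum of inverse nonzero Laplacian eigenvalues) caused by
their removal, and reports the top-decile signature against the planted
hub genes and against degree/strength/betweenness rankings.
"""

import pandas as pd

import netsig as ns

design = ns.ring_module_design(
    tumours=(("T1", 120, 0), ("T2", 120, 0)), n_modules=10, module_size=20, seed=7
)
template = ns.generate_template_network(design)
pooled = pd.concat(ns.generate_expression(design).values(), axis=1)

z = ns.clr_adjust(ns.pearson_matrix(pooled))
net = ns.build_cluster_network(template, z)
components = ns.select_components(net)
scores = ns.score_components(net, components, functional="total_relaxation")
signature = ns.extract_signature(scores, net, percentile=90)

hubs = set(design.hub_names(0))
recall = len(hubs & set(signature.genes)) / len(hubs)
alt = ns.alt_centralities(net, sorted(set().union(*components)))
top_degree = set(alt.sort_values("degree", ascending=False).index[: len(signature)])
top_betw = set(alt.sort_values("betweenness", ascending=False).index[: len(signature)])

print(f"selected components: {[len(c) for c in components]} nodes")
print(f"signature size: {len(signature)} (top decile of {len(scores)} scored genes)")
print(f"planted hubs recovered: {recall:.0%}")
print(f"overlap with top-degree set:      {len(set(signature.genes) & top_degree)}/{len(signature)}")
print(f"overlap with top-betweenness set: {len(set(signature.genes) & top_betw)}/{len(signature)}")
print("High hub recall shows the diffusivity ranking finds the planted")
print("module connectors; partial overlap with degree/betweenness shows it")
print("is not reducible to either classical measure.")
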