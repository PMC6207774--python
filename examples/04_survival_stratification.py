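"""Stratify patients by signature expression and compare survival.

Survival times are simulated with a 3-fold hazard increase for patients
with high mean signature expression (30% independent censoring). Patients
are split into two groups by k-means on the standardized signature genes;
the groups are compared by the log-rank test, the tumour-composition
imbalance index S_T, and a benchmark of random same-size signatures.
"""

import pandas as pd

import netsig as ns
from netsig._util import stage_seed

design = ns.ring_module_design(
    tumours=(("T1", 150, 0), ("T2", 150, 0), ("T3", 120, 0)),
    n_modules=10, module_size=20, seed=5,
)
expression = ns.generate_expression(design)
pooled = pd.concat(expression.values(), axis=1)
hubs = design.hub_names(0)
clinical = ns.generate_survival(pooled, hubs, hazard_ratio=3.0, censor_rate=0.3,
                                seed=stage_seed(5, "survival"))

groups = ns.kmeans_groups(pooled, hubs, clinical, seed=5)
stat, p = ns.logrank_test(groups)
st = ns.imbalance_st(groups).st
km = ns.km_estimate(groups)
bench = ns.random_signature_benchmark(
    pooled, list(pooled.index), len(hubs), clinical,
    observed_signature=hubs, r=200, seed=5,
)

print(f"group sizes: {km.group_sizes}   censored: {km.censored}")
print(f"log-rank chi-square: {stat:.1f}   p-value: {p:.3g}")
print(f"tumour-composition imbalance S_T: {st:.3f}  (0 = balanced, 1 = fully split)")
print(f"rank of observed p among {bench.n_in_band} random signatures with similar S_T: "
      f"{bench.rank:.3f}")
print("A tiny log-rank p with small S_T means the signature separates good")
print("from poor outcomes without merely splitting tumour types; rank ~0 means")
print("random signatures almost never separate patients this well.")
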