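import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netsig as ns


@pytest.fixture(scope="session")
def small_design():
    """Compact planted design: 6 modules of 10 genes, one tumour cluster."""
    return ns.ring_module_design(
        tumours=(("TA", 100, 0), ("TB", 100, 0)),
        n_modules=6, module_size=10, k_clusters=1, seed=11,
    )


@pytest.fixture(scope="session")
def small_template(small_design):
    return ns.generate_template_network(small_design)


@pytest.fixture(scope="session")
def small_cluster_network(small_design, small_template):
    expr = ns.generate_expression(small_design)
    pooled = pd.concat(expr.values(), axis=1)
    z = ns.clr_adjust(ns.pearson_matrix(pooled))
    return ns.build_cluster_network(small_template, z)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_weighted_graph(rng, n, p=0.25, w_lo=0.2, w_hi=3.0, connected=True):
    """Random connected weighted graph for oracle comparisons."""
    while True:
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if not connected or (g.number_of_nodes() and nx.is_connected(g)):
            break
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(w_lo, w_hi))
    return g
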