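"""Cluster-specific weighted networks from a template PPI and CLR scores.

A cluster network keeps exactly the template edges whose pooled-sample CLR
score is strictly positive, weighted by that score: an edge requires both a
physical interaction (template) and correlated expression (z_ij > 0).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

__all__ = ["build_cluster_network", "select_components"]


def build_cluster_network(template: nx.Graph, pooled_z: pd.DataFrame, cluster_id=None) -> nx.Graph:
    """Superimpose pooled CLR scores on the template network.

    Edge present iff it is a template edge and z_ij > 0; weight = z_ij.
    All template nodes are retained (isolated ones carry no edges). Raises if
    any template node has no row in the score matrix.
    """
    unmatched = sorted(set(template.nodes) - set(pooled_z.index))
    if unmatched:
        raise ValueError(f"template genes missing from score matrix: {unmatched[:20]}")
    g = nx.Graph(cluster=cluster_id)
    g.add_nodes_from(template.nodes)
    z = pooled_z
    for u, v in template.edges:
        w = float(z.at[u, v])
        if w > 0:
            g.add_edge(u, v, weight=w)
    return g


def select_components(net: nx.Graph, size_ratio: float = 0.5) -> list:
    """Components retained for centrality analysis, largest first.

    The giant component is always selected; each next-largest component is
    also selected while its size is >= ``size_ratio`` times the giant's
    (ties in size are both kept). Isolated nodes never form components here.
    Returns a list of node sets.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty network")
    comps = [c for c in nx.connected_components(net) if len(c) > 1]
    if not comps:
        raise ValueError("network has no edges")
    comps.sort(key=lambda c: (-len(c), sorted(c)[0]))
    giant = len(comps[0])
    selected = [comps[0]]
    for c in comps[1:]:
        if len(c) >= size_ratio * giant:
            selected.append(c)
        else:
            break
    return selected
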