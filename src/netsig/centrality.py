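"""Spectral centrality: node impact on Laplacian diffusivity.

For a connected weighted graph G with Laplacian L = D - W, global diffusivity
is summarized by a spectral functional F:

* ``total_relaxation`` — sum of 1/lambda_k over the nonzero eigenvalues (the
  Kirchhoff-type total relaxation time; larger means slower diffusion);
* ``algebraic_connectivity`` — lambda_2, the slowest relaxation rate.

The spectral centrality of node i is the normalized change of F when i is
removed: SC_i = |F(G) - F(G_i)| / F(G), where G_i is the largest connected
component of G minus i. Removals that disconnect nodes are scored on the
remaining giant component, with the number of disconnected nodes reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "laplacian_spectrum",
    "diffusivity",
    "spectral_centrality",
    "score_components",
    "alt_centralities",
    "extract_signature",
    "signature_overlap",
    "GeneSignature",
]

_ZERO_TOL = 1e-9
_FUNCTIONALS = ("total_relaxation", "algebraic_connectivity")


@dataclass(frozen=True)
class GeneSignature:
    """Top-decile spectral-centrality gene set of one cluster network."""

    genes: tuple
    percentile: float
    cluster_id: object = None

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))

    def __len__(self):
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def _subgraph(net: nx.Graph, nodes) -> nx.Graph:
    sub = net.subgraph(nodes)
    if sub.number_of_nodes() == 0:
        raise ValueError("empty node subset")
    if not nx.is_connected(sub):
        raise ValueError("induced subgraph is not connected; pass one component")
    return sub


def laplacian_spectrum(net: nx.Graph, nodes=None) -> np.ndarray:
    """Ascending eigenvalues of L = D - W on a connected induced subgraph."""
    sub = _subgraph(net, nodes if nodes is not None else net.nodes)
    order = sorted(sub.nodes)
    lap = nx.laplacian_matrix(sub, nodelist=order, weight="weight").toarray().astype(float)
    eigs = np.linalg.eigvalsh(lap)
    eigs[np.abs(eigs) < _ZERO_TOL] = 0.0
    return np.sort(eigs)


def _functional_from_eigs(eigs: np.ndarray, functional: str) -> float:
    if functional == "total_relaxation":
        nz = eigs[eigs > _ZERO_TOL]
        return float(np.sum(1.0 / nz)) if nz.size else 0.0
    if functional == "algebraic_connectivity":
        return float(eigs[1]) if eigs.size > 1 else 0.0
    raise ValueError(f"unknown functional {functional!r}; choose from {_FUNCTIONALS}")


def diffusivity(net: nx.Graph, nodes=None, functional: str = "total_relaxation") -> float:
    """Diffusivity functional of a connected induced subgraph (>= 2 nodes)."""
    sub = _subgraph(net, nodes if nodes is not None else net.nodes)
    if sub.number_of_nodes() < 2:
        raise ValueError("diffusivity undefined for a single node")
    return _functional_from_eigs(laplacian_spectrum(net, sub.nodes), functional)


def spectral_centrality(net: nx.Graph, nodes=None, functional: str = "total_relaxation") -> pd.DataFrame:
    """Per-node spectral centrality on one connected component.

    Returns a frame indexed by node with columns ``sc`` (the normalized
    functional change) and ``disconnects`` (how many other nodes the removal
    cuts off the giant remainder).
    """
    sub = _subgraph(net, nodes if nodes is not None else net.nodes)
    if sub.number_of_nodes() < 3:
        raise ValueError("need at least 3 nodes")
    f0 = diffusivity(sub, functional=functional)
    rows = []
    node_list = sorted(sub.nodes)
    for node in node_list:
        rest = sub.subgraph([n for n in sub.nodes if n != node])
        comps = sorted(nx.connected_components(rest), key=lambda c: (-len(c), sorted(c)[0]))
        giant = comps[0]
        disconnects = rest.number_of_nodes() - len(giant)
        if len(giant) < 2:
            f1 = 0.0
        else:
            f1 = _functional_from_eigs(laplacian_spectrum(rest, giant), functional)
        rows.append((node, abs(f0 - f1) / f0, disconnects))
    return pd.DataFrame(rows, columns=["node", "sc", "disconnects"]).set_index("node")


def score_components(net: nx.Graph, components, functional: str = "total_relaxation") -> pd.DataFrame:
    """Spectral centrality over a union of components (one frame, tagged)."""
    frames = []
    for k, comp in enumerate(components):
        part = spectral_centrality(net, comp, functional=functional)
        part["component"] = k
        frames.append(part)
    out = pd.concat(frames)
    out.attrs["functional"] = functional
    return out


def alt_centralities(net: nx.Graph, nodes=None) -> pd.DataFrame:
    """Degree, strength (weighted degree) and betweenness for comparison.

    Betweenness treats edge weights as proximities: path lengths use 1/w.
    """
    sub = net.subgraph(nodes) if nodes is not None else net
    h = nx.Graph()
    h.add_nodes_from(sub.nodes)
    for u, v, d in sub.edges(data=True):
        w = float(d.get("weight", 1.0))
        h.add_edge(u, v, weight=w, length=1.0 / w)
    deg = dict(h.degree)
    strength = dict(h.degree(weight="weight"))
    btw = nx.betweenness_centrality(h, weight="length", normalized=True)
    order = sorted(h.nodes)
    return pd.DataFrame(
        {
            "degree": [deg[n] for n in order],
            "strength": [strength[n] for n in order],
            "betweenness": [btw[n] for n in order],
        },
        index=pd.Index(order, name="node"),
    )


def extract_signature(
    scores: pd.DataFrame,
    net: nx.Graph,
    percentile: float = 90.0,
    cluster_id=None,
) -> GeneSignature:
    """Top-decile signature: the ceil((1 - p/100) * N) highest-SC nodes.

    Ties at the boundary are broken by higher strength, then lexicographic
    node id (with a warning), so the selection is deterministic.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must lie in (0, 100)")
    n = len(scores)
    if n < 10:
        raise ValueError("need at least 10 scored nodes")
    k = math.ceil((1.0 - percentile / 100.0) * n)
    strength = dict(net.degree(weight="weight"))
    ranked = sorted(
        scores.index,
        key=lambda g: (-float(scores.at[g, "sc"]), -float(strength.get(g, 0.0)), str(g)),
    )
    boundary = float(scores.at[ranked[k - 1], "sc"])
    if k < n and float(scores.at[ranked[k], "sc"]) == boundary:
        warnings.warn("tie at the signature boundary; broken by strength then gene id", stacklevel=2)
    return GeneSignature(genes=ranked[:k], percentile=percentile, cluster_id=cluster_id)


def signature_overlap(sig_a, sig_b) -> tuple:
    """(intersection size, Jaccard index) of two signatures."""
    a, b = set(sig_a), set(sig_b)
    inter = len(a & b)
    union = len(a | b)
    return inter, (inter / union if union else 0.0)
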