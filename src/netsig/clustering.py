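"""Tumour clustering by distance between thresholded CLR matrices.

The distance between two tumour datasets A and B is the element-wise
Euclidean (Frobenius) distance between their thresholded z-score matrices,

    d(A, B) = sqrt( sum_i sum_j (a_ij - b_ij)^2 ),

summed over the full n^2 grid (both triangles; the zeroed diagonals cancel).
Tumours are then clustered with Ward-linkage hierarchical clustering and a
simplified dynamic branch cut (height cut followed by minimum-size merging).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from ._util import check_aligned
from . import coexpression, netbuild, centrality

__all__ = [
    "matrix_distance",
    "distance_matrix",
    "ward_tree",
    "dynamic_cut",
    "dendrogram_newick",
    "subsample_stability",
]


def matrix_distance(a: pd.DataFrame, b: pd.DataFrame) -> float:
    """Element-wise Euclidean distance between two aligned score matrices."""
    check_aligned(a.index, b.index)
    check_aligned(a.columns, b.columns)
    diff = a.to_numpy(dtype=float) - b.to_numpy(dtype=float)
    return float(np.sqrt(np.sum(diff * diff)))


def distance_matrix(tumour_matrices: dict) -> pd.DataFrame:
    """All pairwise matrix distances, as a symmetric tumour x tumour frame."""
    ids = list(tumour_matrices)
    if len(ids) < 2:
        raise ValueError("need at least 2 tumours")
    d = np.zeros((len(ids), len(ids)))
    for i, ti in enumerate(ids):
        for j in range(i + 1, len(ids)):
            d[i, j] = d[j, i] = matrix_distance(tumour_matrices[ti], tumour_matrices[ids[j]])
    return pd.DataFrame(d, index=ids, columns=ids)


def ward_tree(dist: pd.DataFrame) -> tuple:
    """Ward-linkage dendrogram from a precomputed distance matrix.

    Uses the squared-distance Lance–Williams update (Ward.D2 semantics), which
    guarantees monotone non-decreasing merge heights. Returns ``(Z, labels)``
    with ``Z`` a scipy linkage matrix over ``labels`` in the given order.
    """
    if dist.shape[0] < 2:
        raise ValueError("need at least 2 tumours")
    condensed = squareform(dist.to_numpy(dtype=float), checks=False)
    z = hierarchy.linkage(condensed, method="ward")
    return z, list(dist.index)


def _adaptive_cut_height(linkage: np.ndarray, dmat: pd.DataFrame, labels: list) -> float:
    """Adaptive cut: the gap between merge heights with the best silhouette.

    Candidate cut heights are the midpoints of gaps between consecutive
    sorted merge heights; each candidate partition (2..8 clusters) is scored
    by its mean silhouette coefficient against the tumour distance matrix and
    the best-scoring height is returned (ties favour fewer clusters). Robust
    to unequal group sizes, where the single largest height gap often sits
    between the two top merges and can only ever yield two clusters.
    """
    from sklearn.metrics import silhouette_score

    hs = np.sort(np.unique(linkage[:, 2]))
    if hs.size < 2:
        return float(hs[-1]) + 1.0
    candidates = (hs[:-1] + hs[1:]) / 2.0
    d = dmat.loc[labels, labels].to_numpy()
    best_t, best_score, best_k = float(hs[-1]) + 1.0, -np.inf, np.inf
    for t in candidates:
        flat = hierarchy.fcluster(linkage, t=float(t), criterion="distance")
        k = len(np.unique(flat))
        if not (2 <= k <= min(8, len(labels) - 1)):
            continue
        score = silhouette_score(d, flat, metric="precomputed")
        if score > best_score + 1e-12 or (abs(score - best_score) <= 1e-12 and k < best_k):
            best_t, best_score, best_k = float(t), float(score), k
    return best_t


def dynamic_cut(
    linkage: np.ndarray,
    labels: list,
    min_cluster_size: int = 2,
    cut_height: float | None = None,
    dist: pd.DataFrame | None = None,
) -> dict:
    """Cut a dendrogram into clusters, merging undersized ones.

    Branches below ``cut_height`` form initial clusters; clusters smaller than
    ``min_cluster_size`` are merged into the nearest cluster by average
    inter-cluster distance (cophenetic if ``dist`` is not given). If
    ``cut_height`` is None it is chosen adaptively among the gaps between
    merge heights by silhouette score. Returns ``{label: cluster_int}`` with
    clusters numbered from 0 by first appearance in ``labels``.
    """
    if cut_height is not None and cut_height <= 0:
        raise ValueError("cut_height must be positive")
    if dist is None:
        dmat = pd.DataFrame(squareform(hierarchy.cophenet(linkage)), index=labels, columns=labels)
    else:
        dmat = dist.loc[labels, labels]
    t = _adaptive_cut_height(linkage, dmat, labels) if cut_height is None else float(cut_height)
    flat = hierarchy.fcluster(linkage, t=t, criterion="distance")
    groups: dict = {}
    for lab, c in zip(labels, flat):
        groups.setdefault(int(c), []).append(lab)
    # merge undersized clusters into the closest (average-distance) big one
    while len(groups) > 1:
        small = [c for c, members in groups.items() if len(members) < min_cluster_size]
        if not small:
            break
        c = min(small, key=lambda cc: len(groups[cc]))
        members = groups.pop(c)
        best, best_d = None, np.inf
        for other, omembers in groups.items():
            d = float(dmat.loc[members, omembers].to_numpy().mean())
            if d < best_d:
                best, best_d = other, d
        groups[best] = groups[best] + members
    # deterministic renumbering by first appearance
    order: dict = {}
    assign = {}
    for lab in labels:
        c = next(cc for cc, mm in groups.items() if lab in mm)
        if c not in order:
            order[c] = len(order)
        assign[lab] = order[c]
    return assign


def dendrogram_newick(linkage: np.ndarray, labels: list) -> str:
    """Serialize a scipy linkage tree as a Newick string (heights as lengths)."""
    tree = hierarchy.to_tree(linkage)

    def rec(node, parent_height):
        length = max(0.0, parent_height - (node.dist if not node.is_leaf() else 0.0))
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(tree, tree.dist) + ";"


def subsample_stability(
    expressions: dict,
    template,
    signature,
    fraction: float = 0.5,
    repeats: int = 100,
    seed: int = 0,
    functional: str = "total_relaxation",
    percentile: float = 90.0,
    size_ratio: float = 0.5,
) -> pd.Series:
    """Occurrence counts of signature genes under patient subsampling.

    For each repeat, ``fraction`` of every tumour's samples are drawn without
    replacement, the pooled correlation -> CLR -> network -> spectral-centrality
    signature pipeline is rerun, and each original signature gene's presence is
    tallied. Returns counts (out of ``repeats``) indexed by signature gene.
    """
    rng = np.random.default_rng(seed)
    genes = list(signature.genes) if hasattr(signature, "genes") else list(signature)
    counts = pd.Series(0, index=genes, dtype=int)
    for _ in range(repeats):
        parts = []
        for tid, expr in expressions.items():
            k = int(round(fraction * expr.shape[1]))
            if k < 4:
                raise ValueError(f"tumour {tid}: subsample of {k} samples is too small")
            cols = rng.choice(expr.shape[1], size=k, replace=False)
            parts.append(expr.iloc[:, np.sort(cols)])
        pooled = pd.concat(parts, axis=1)
        z = coexpression.clr_adjust(coexpression.pearson_matrix(pooled))
        net = netbuild.build_cluster_network(template, z)
        comps = netbuild.select_components(net, size_ratio=size_ratio)
        scores = centrality.score_components(net, comps, functional=functional)
        sig = centrality.extract_signature(scores, net, percentile=percentile)
        counts.loc[counts.index.isin(sig.genes)] += 1
    return counts
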