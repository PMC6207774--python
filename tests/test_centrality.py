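"""Spectral centrality against closed forms and a brute-force oracle."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netsig as ns
from conftest import random_weighted_graph


# ---------------------------------------------------------------- oracle ---
def _oracle_components(adj):
    """Connected components from a plain adjacency dict (DFS, no networkx)."""
    seen, comps = set(), []
    for start in adj:
        if start in seen:
            continue
        stack, comp = [start], set()
        while stack:
            u = stack.pop()
            if u in comp:
                continue
            comp.add(u)
            stack.extend(v for v in adj[u] if v not in comp)
        seen |= comp
        comps.append(comp)
    return comps


def _oracle_functional(adj, nodes, functional):
    nodes = sorted(nodes)
    idx = {v: k for k, v in enumerate(nodes)}
    lap = np.zeros((len(nodes), len(nodes)))
    for u in nodes:
        for v, w in adj[u].items():
            if v in idx:
                lap[idx[u], idx[v]] -= w
                lap[idx[u], idx[u]] += w
    eigs = np.sort(np.linalg.eigvalsh(lap))
    if functional == "total_relaxation":
        nz = eigs[eigs > 1e-9]
        return float(np.sum(1.0 / nz)) if nz.size else 0.0
    return float(eigs[1]) if eigs.size > 1 else 0.0


def oracle_spectral_centrality(g, functional="total_relaxation"):
    """Independent remove-and-recompute implementation (dict + numpy only)."""
    adj = {u: {v: float(d.get("weight", 1.0)) for v, d in g[u].items()} for u in g}
    f0 = _oracle_functional(adj, adj.keys(), functional)
    out = {}
    for node in adj:
        rest = {u: {v: w for v, w in nb.items() if v != node}
                for u, nb in adj.items() if u != node}
        comps = _oracle_components(rest)
        giant = max(comps, key=len)
        if len(giant) < 2:
            f1 = 0.0
        else:
            f1 = _oracle_functional(rest, giant, functional)
        out[node] = abs(f0 - f1) / f0
    return out


# ----------------------------------------------------------------- spectra ---
class TestLaplacianSpectrum:
    def test_complete_graph_closed_form(self):
        eigs = ns.laplacian_spectrum(nx.complete_graph(4))
        assert np.allclose(eigs, [0, 4, 4, 4], atol=1e-9)

    def test_path_graph_closed_form(self):
        eigs = ns.laplacian_spectrum(nx.path_graph(3))
        assert np.allclose(eigs, [0, 1, 3], atol=1e-9)

    def test_matches_dense_solver_on_random_graph(self, rng):
        g = random_weighted_graph(rng, 20)
        eigs = ns.laplacian_spectrum(g)
        expected = np.sort(np.linalg.eigvalsh(
            nx.laplacian_matrix(g, nodelist=sorted(g), weight="weight").toarray()
        ))
        assert np.allclose(eigs, expected, atol=1e-9)
        assert abs(eigs[0]) <= 1e-9

    def test_disconnected_input_rejected(self):
        g = nx.Graph([(0, 1), (2, 3)])
        with pytest.raises(ValueError, match="not connected"):
            ns.laplacian_spectrum(g)


class TestDiffusivity:
    def test_complete_graph_total_relaxation(self):
        # K_n has eigenvalues {0, n x (n-1)}: sum 1/lambda = (n-1)/n
        assert ns.diffusivity(nx.complete_graph(4)) == pytest.approx(0.75, abs=1e-12)

    def test_complete_graph_algebraic_connectivity(self):
        val = ns.diffusivity(nx.complete_graph(5), functional="algebraic_connectivity")
        assert val == pytest.approx(5.0, abs=1e-9)

    def test_doubling_weights_halves_relaxation(self, rng):
        g = random_weighted_graph(rng, 12)
        f1 = ns.diffusivity(g)
        for u, v in g.edges:
            g[u][v]["weight"] *= 2.0
        assert ns.diffusivity(g) == pytest.approx(f1 / 2.0, rel=1e-10)

    def test_single_node_rejected(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.raises(ValueError):
            ns.diffusivity(g)


class TestSpectralCentrality:
    def test_complete_graph_symmetry(self):
        sc = ns.spectral_centrality(nx.complete_graph(6))
        assert np.allclose(sc["sc"], sc["sc"].iloc[0])

    def test_path_middle_node_most_central(self):
        sc = ns.spectral_centrality(nx.path_graph(5))
        assert sc.loc[2, "sc"] > sc.loc[0, "sc"]
        assert sc.loc[2, "sc"] > sc.loc[4, "sc"]

    @pytest.mark.parametrize("functional", ["total_relaxation", "algebraic_connectivity"])
    def test_matches_brute_force_oracle(self, rng, functional):
        g = random_weighted_graph(rng, 30)
        sc = ns.spectral_centrality(g, functional=functional)
        oracle = oracle_spectral_centrality(g, functional)
        for node, expected in oracle.items():
            assert sc.loc[node, "sc"] == pytest.approx(expected, abs=1e-9)

    def test_invariant_to_relabeling_and_weight_scale(self, rng):
        g = random_weighted_graph(rng, 15)
        sc = ns.spectral_centrality(g)
        relabel = {v: f"x{v}" for v in g}
        sc2 = ns.spectral_centrality(nx.relabel_nodes(g, relabel))
        for v in g:
            assert sc2.loc[f"x{v}", "sc"] == pytest.approx(sc.loc[v, "sc"], abs=1e-12)
        h = g.copy()
        for u, v in h.edges:
            h[u][v]["weight"] *= 7.5
        sc3 = ns.spectral_centrality(h)
        assert np.allclose(sc3["sc"], sc["sc"], atol=1e-9)

    def test_cut_vertex_reports_disconnections(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "d"), ("d", "b")])
        sc = ns.spectral_centrality(g)
        assert sc.loc["b", "disconnects"] > 0       # cut vertex strands 'a'
        leaves_tree = nx.Graph([(0, 1), (1, 2), (1, 3)])
        sc_tree = ns.spectral_centrality(leaves_tree)
        assert sc_tree.loc[0, "disconnects"] == 0   # leaf removal strands nobody


class TestAltCentralities:
    def test_star_center_dominates(self):
        g = nx.star_graph(4)
        alt = ns.alt_centralities(g)
        assert alt.loc[0, "degree"] == 4
        assert alt.loc[0, "betweenness"] == alt["betweenness"].max()

    def test_strength_is_incident_weight_sum(self, rng):
        g = random_weighted_graph(rng, 10)
        alt = ns.alt_centralities(g)
        for v in g:
            expected = sum(d["weight"] for _, _, d in g.edges(v, data=True))
            assert alt.loc[v, "strength"] == pytest.approx(expected)

    def test_unit_weights_strength_equals_degree(self):
        g = nx.cycle_graph(6)
        alt = ns.alt_centralities(g)
        assert (alt["strength"] == alt["degree"]).all()


class TestSignature:
    def test_top_decile_of_distinct_scores(self, rng):
        scores = pd.DataFrame({"sc": rng.permutation(np.linspace(0.01, 1.0, 100))},
                              index=[f"g{i:03d}" for i in range(100)])
        net = nx.Graph()
        net.add_nodes_from(scores.index)
        sig = ns.extract_signature(scores, net, percentile=90)
        assert len(sig) == 10
        top10 = set(scores.sort_values("sc", ascending=False).index[:10])
        assert set(sig.genes) == top10

    def test_all_equal_scores_lexicographic_tie_break(self):
        scores = pd.DataFrame({"sc": np.ones(20)}, index=[f"g{i:02d}" for i in range(20)])
        net = nx.Graph()
        net.add_nodes_from(scores.index)
        with pytest.warns(UserWarning, match="tie"):
            sig = ns.extract_signature(scores, net, percentile=90)
        assert list(sig.genes) == [f"g{i:02d}" for i in range(2)]  # ceil(0.1 * 20) = 2

    @pytest.mark.parametrize("percentile", [0.0, 100.0, -5.0])
    def test_percentile_bounds(self, percentile):
        scores = pd.DataFrame({"sc": np.arange(12, dtype=float)}, index=[f"g{i}" for i in range(12)])
        with pytest.raises(ValueError):
            ns.extract_signature(scores, nx.Graph(), percentile=percentile)

    def test_signature_size_deterministic_in_n(self):
        for n in (10, 25, 101, 240):
            scores = pd.DataFrame({"sc": np.arange(n, dtype=float)}, index=[f"g{i:04d}" for i in range(n)])
            net = nx.Graph()
            net.add_nodes_from(scores.index)
            sig = ns.extract_signature(scores, net, percentile=90)
            assert len(sig) == int(np.ceil(0.1 * n))


class TestOverlap:
    def test_identical_and_disjoint(self):
        a = ["g1", "g2", "g3"]
        assert ns.signature_overlap(a, a) == (3, 1.0)
        assert ns.signature_overlap(a, ["x", "y"]) == (0, 0.0)

    def test_partial_overlap_jaccard(self):
        a = [f"a{i}" for i in range(14)] + [f"c{i}" for i in range(13)]
        b = [f"b{i}" for i in range(14)] + [f"c{i}" for i in range(13)]
        inter, jac = ns.signature_overlap(a, b)
        assert inter == 13
        assert jac == pytest.approx(13 / 41)
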