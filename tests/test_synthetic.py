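"""Statistical and structural properties of the synthetic generators."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import netsig as ns


def _one_block_design(rho, n_genes=30, n_samples=200, block=10, noise=0.2, seed=0):
    return ns.SyntheticDesign(
        n_genes=n_genes,
        tumours=(("T1", n_samples, 0),),
        k_planted_clusters=1,
        block_spec={0: [(list(range(block)), rho)]} if rho > 0 else {0: []},
        hub_genes={},
        noise_sd=noise,
        seed=seed,
    )


class TestDesignValidation:
    def test_rejects_bad_specs(self):
        with pytest.raises(ValueError, match="n_samples"):
            ns.SyntheticDesign(30, (("T", 2, 0),), 1, {}, {})
        with pytest.raises(ValueError, match="out of range"):
            ns.SyntheticDesign(30, (("T", 10, 3),), 2, {}, {})
        with pytest.raises(ValueError, match="overlap"):
            ns.SyntheticDesign(30, (("T", 10, 0),), 1,
                               {0: [([0, 1, 2], 0.5), ([2, 3], 0.5)]}, {})
        with pytest.raises(ValueError, match="rho"):
            ns.SyntheticDesign(30, (("T", 10, 0),), 1, {0: [([0, 1], 1.0)]}, {})
        with pytest.raises(ValueError, match="delta"):
            ns.SyntheticDesign(30, (("T", 10, 0),), 1, {}, {},
                               connector_spec={0: [([0, 1], 1.5)]})


class TestTemplateNetwork:
    def test_seeded_determinism(self, small_design):
        g1 = ns.generate_template_network(small_design)
        g2 = ns.generate_template_network(small_design)
        assert set(g1.edges) == set(g2.edges)

    def test_hub_degree_ratio_realized(self):
        d = ns.ring_module_design(tumours=(("T1", 50, 0),), n_modules=10, module_size=20, seed=2)
        g = ns.generate_template_network(d, hub_degree_ratio=3.0)
        hubs = set(d.hub_names(0))
        hub_deg = np.mean([g.degree(h) for h in hubs])
        other_deg = np.mean([g.degree(v) for v in g if v not in hubs])
        assert hub_deg / other_deg >= 2.0

    def test_giant_component_covers_most_genes(self, small_template, small_design):
        giant = max(nx.connected_components(small_template), key=len)
        assert len(giant) >= 0.8 * small_design.n_genes

    def test_small_design_rejected(self):
        d = _one_block_design(0.5, n_genes=10, block=5)
        with pytest.raises(ValueError, match="20 genes"):
            ns.generate_template_network(d)

    def test_oversized_hub_set_rejected(self):
        d = ns.SyntheticDesign(30, (("T", 10, 0),), 1, {}, {0: list(range(10))})
        with pytest.raises(ValueError, match="20%"):
            ns.generate_template_network(d)


class TestExpression:
    def test_strong_block_realized_correlation(self):
        d = _one_block_design(0.9, noise=0.2)
        expr = ns.generate_expression(d)["T1"]
        r = np.corrcoef(expr.iloc[:10].to_numpy())
        mean_abs = np.abs(r[np.triu_indices(10, k=1)]).mean()
        assert mean_abs >= 0.7

    def test_null_correlation_near_zero(self):
        d = _one_block_design(0.0, n_samples=500)
        expr = ns.generate_expression(d)["T1"]
        r = np.corrcoef(expr.to_numpy())
        assert np.abs(r[np.triu_indices(30, k=1)]).mean() <= 0.1

    def test_seeded_determinism(self, small_design):
        e1 = ns.generate_expression(small_design)
        e2 = ns.generate_expression(small_design)
        for t in e1:
            assert e1[t].equals(e2[t])

    def test_connector_pair_correlation(self):
        d = ns.SyntheticDesign(
            30, (("T1", 2000, 0),), 1, {0: []}, {},
            connector_spec={0: [([0, 1], 0.4)]}, noise_sd=0.2, seed=5,
        )
        expr = ns.generate_expression(d)["T1"].to_numpy()
        r = np.corrcoef(expr[0], expr[1])[0, 1]
        assert r == pytest.approx(0.4 / 1.04, abs=0.06)

    def test_sampling_error_shrinks_with_n(self):
        # Frobenius error vs the planted correlation roughly halves as n quadruples
        errs = []
        for n in (200, 800):
            d = _one_block_design(0.6, n_samples=n, noise=0.2, seed=9)
            expr = ns.generate_expression(d)["T1"].to_numpy()
            r = np.corrcoef(expr)
            planted = np.eye(30)
            rho_eff = 0.6 / 1.04
            planted[:10, :10] = rho_eff
            np.fill_diagonal(planted, 1.0)
            errs.append(np.linalg.norm(r - planted, "fro"))
        assert errs[1] <= 0.75 * errs[0]


class TestMutations:
    def test_null_enrichment_matches_base_rate(self):
        d = ns.ring_module_design(tumours=(("T1", 50, 0),), n_modules=10, module_size=20, seed=4)
        g = ns.generate_template_network(d)
        mut = ns.generate_mutations(d, g, enrichment=1.0, base_rate=0.05, seed=1)
        rate = mut["mutated"].mean()
        se = np.sqrt(0.05 * 0.95 / len(mut))
        assert abs(rate - 0.05) <= 4 * se

    def test_hub_adjacent_rate_exceeds_background(self):
        d = ns.ring_module_design(tumours=(("T1", 50, 0),), n_modules=10, module_size=20, seed=4)
        g = ns.generate_template_network(d)
        mut = ns.generate_mutations(d, g, enrichment=10.0, base_rate=0.02, seed=1)
        sub = mut[mut["cluster_id"] == 0].set_index("gene")["mutated"]
        hubs = set(d.hub_names(0))
        near = set(hubs)
        for h in hubs:
            near |= set(g.neighbors(h))
        near_rate = sub[sub.index.isin(near)].mean()
        bg_rate = sub[~sub.index.isin(near)].mean()
        assert near_rate > bg_rate

    def test_invalid_rates_rejected(self, small_design, small_template):
        with pytest.raises(ValueError):
            ns.generate_mutations(small_design, small_template, base_rate=0.0)
        with pytest.raises(ValueError):
            ns.generate_mutations(small_design, small_template, enrichment=0.5)


class TestSurvival:
    @staticmethod
    def _expr(rng, n_genes=5, n_pat=400):
        genes = [f"g{i}" for i in range(n_genes)]
        common = rng.normal(size=n_pat)
        x = 0.8 * common + 0.6 * rng.normal(size=(n_genes, n_pat))
        return pd.DataFrame(x, index=genes, columns=[f"T1_S{i:04d}" for i in range(n_pat)])

    def test_no_censoring_all_events(self, rng):
        expr = self._expr(rng)
        clin = ns.generate_survival(expr, list(expr.index), censor_rate=0.0, seed=1)
        assert (clin["event"] == 1).all()

    def test_high_hazard_group_dies_sooner(self, rng):
        expr = self._expr(rng)
        clin = ns.generate_survival(expr, list(expr.index), hazard_ratio=3.0,
                                    censor_rate=0.0, seed=2)
        score = ((expr - expr.values.mean(axis=1, keepdims=True))
                 / expr.values.std(axis=1, keepdims=True)).mean(axis=0)
        high = score > 0
        med_high = clin.loc[high.to_numpy(), "time"].median()
        med_low = clin.loc[~high.to_numpy(), "time"].median()
        assert med_high < med_low

    def test_hazard_ratio_recovered_within_20pct(self, rng):
        expr = self._expr(rng, n_pat=4000)
        hr = 2.5
        clin = ns.generate_survival(expr, list(expr.index), hazard_ratio=hr,
                                    censor_rate=0.0, seed=3)
        score = ((expr - expr.values.mean(axis=1, keepdims=True))
                 / expr.values.std(axis=1, keepdims=True)).mean(axis=0)
        high = (score > 0).to_numpy()
        rate_high = 1.0 / clin.loc[high, "time"].mean()
        rate_low = 1.0 / clin.loc[~high, "time"].mean()
        assert rate_high / rate_low == pytest.approx(hr, rel=0.2)

    def test_censor_rate_achieved(self, rng):
        expr = self._expr(rng, n_pat=2000)
        clin = ns.generate_survival(expr, list(expr.index), censor_rate=0.4, seed=4)
        assert (clin["event"] == 0).mean() == pytest.approx(0.4, abs=0.05)

    def test_invalid_arguments_rejected(self, rng):
        expr = self._expr(rng, n_pat=20)
        with pytest.raises(ValueError):
            ns.generate_survival(expr, list(expr.index), hazard_ratio=0.0)
        with pytest.raises(ValueError):
            ns.generate_survival(expr, ["absent"], hazard_ratio=2.0)


class TestPharma:
    def test_seeded_determinism(self, small_design):
        t1, i1 = ns.generate_pharma(small_design, n_drugs=20, seed=8)
        t2, i2 = ns.generate_pharma(small_design, n_drugs=20, seed=8)
        assert t1.equals(t2) and i1.equals(i2)

    def test_planted_effect_separates_groups(self, small_design):
        targets, ic50 = ns.generate_pharma(small_design, n_drugs=40, n_cell_lines=10,
                                           signature_effect=2.0, seed=3)
        hubs = {g for c in range(small_design.k_planted_clusters)
                for g in small_design.hub_names(c)}
        hub_drugs = set(targets.loc[targets["gene"].isin(hubs), "drug_id"])
        log_ic = np.log(ic50["ic50"])
        is_hub = ic50["drug_id"].isin(hub_drugs)
        assert log_ic[is_hub].mean() < log_ic[~is_hub].mean() - 1.0

    def test_too_few_drugs_rejected(self, small_design):
        with pytest.raises(ValueError):
            ns.generate_pharma(small_design, n_drugs=3)
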