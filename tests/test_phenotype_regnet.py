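"""Candidate intersection, phenotype correlation network, merge policy."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from impnet.phenotype_regnet import (
    CG,
    IMP_GENE,
    INTERMEDIATE,
    PHENOTYPE,
    build_threshold_graph,
    classify_phenotype_relation,
    intersect_candidate_networks,
    merge_regulatory_network,
    phenotype_correlation_matrix,
)


class TestIntersectCandidateNetworks:
    def test_identical_sets(self):
        nets = {"a": {"x", "y"}, "b": {"x", "y"}, "c": {"x", "y"}}
        rep = intersect_candidate_networks(nets, {"x", "y", "z"})
        assert rep.in_all_networks == {"x", "y"}
        assert rep.survivors == {"x", "y"}

    def test_constructed_25_to_15_filter(self):
        """25 genes shared by all three networks of which 10 are absent
        from the co-expression graph leave 15 candidates."""
        shared = {f"cg{i}" for i in range(25)}
        nets = {
            "net1": shared | {"only1"},
            "net2": shared | {"only2a", "only2b"},
            "net3": shared,
        }
        coexpr = {f"cg{i}" for i in range(15)} | {"unrelated"}
        rep = intersect_candidate_networks(nets, coexpr)
        assert len(rep.in_all_networks) == 25
        assert len(rep.survivors) == 15
        assert len(rep.removed_not_coexpressed) == 10

    def test_matches_brute_force_sets(self, rng):
        universe = [f"g{i}" for i in range(60)]
        nets = {
            f"n{k}": {g for g in universe if rng.random() < 0.6} for k in range(3)
        }
        coexpr = {g for g in universe if rng.random() < 0.5}
        rep = intersect_candidate_networks(nets, coexpr)
        expected = set(universe)
        for s in nets.values():
            expected &= s
        assert rep.in_all_networks == expected
        assert rep.survivors == expected & coexpr

    def test_fewer_than_two_networks_rejected(self):
        with pytest.raises(ValueError):
            intersect_candidate_networks({"a": {"x"}}, {"x"})

    def test_empty_network_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            rep = intersect_candidate_networks({"a": set(), "b": {"x"}}, {"x"})
        assert rep.survivors == frozenset()


class TestPhenotypeCorrelationMatrix:
    def _profiles(self, rng, n_genes=35, n_tp=6):
        return pd.DataFrame(
            rng.normal(size=(n_genes, n_tp)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[2, 4, 6, 8, 10, 12][:n_tp],
        )

    def test_symmetric_unit_diagonal(self, rng):
        profiles = self._profiles(rng)
        pheno = pd.Series(rng.normal(size=6), index=profiles.columns)
        corr = phenotype_correlation_matrix(profiles, pheno)
        assert corr.shape == (36, 36)
        np.testing.assert_allclose(corr.to_numpy(), corr.to_numpy().T)
        np.testing.assert_allclose(np.diag(corr), 1.0)
        assert (corr.abs().to_numpy() <= 1.0 + 1e-12).all()

    def test_gene_equal_to_phenotype_has_r_one(self, rng):
        profiles = self._profiles(rng, n_genes=3)
        pheno = profiles.loc["g0"].copy()
        pheno.name = "IMP"
        corr = phenotype_correlation_matrix(profiles, pheno)
        assert corr.loc["g0", "IMP_content"] == pytest.approx(1.0)

    def test_matches_pairwise_brute_force(self, rng):
        from impnet.coexpression_network import pearson_correlation

        profiles = self._profiles(rng, n_genes=10)
        pheno = pd.Series(rng.normal(size=6), index=profiles.columns)
        corr = phenotype_correlation_matrix(profiles, pheno)
        names = list(profiles.index) + ["IMP_content"]
        rows = np.vstack([profiles.to_numpy(), pheno.to_numpy()])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                assert corr.iloc[i, j] == pytest.approx(
                    pearson_correlation(rows[i], rows[j]), abs=1e-12
                )

    def test_constant_profile_flagged(self, rng):
        profiles = self._profiles(rng, n_genes=3)
        profiles.loc["g1"] = 4.2
        pheno = pd.Series(rng.normal(size=6), index=profiles.columns)
        with pytest.warns(UserWarning, match="g1"):
            corr = phenotype_correlation_matrix(profiles, pheno)
        assert np.isnan(corr.loc["g1", "g0"])

    def test_mismatched_time_points_rejected(self, rng):
        profiles = self._profiles(rng, n_genes=2)
        pheno = pd.Series(rng.normal(size=6), index=[1, 2, 3, 4, 5, 6])
        with pytest.raises(ValueError):
            phenotype_correlation_matrix(profiles, pheno)


class TestBuildThresholdGraph:
    def _corr(self, entries, names):
        m = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
        for a, b, r in entries:
            m.loc[a, b] = m.loc[b, a] = r
        return m

    def test_all_below_threshold_no_edges(self):
        corr = self._corr([("a", "b", 0.5)], ["a", "b"])
        g = build_threshold_graph(corr, 0.7)
        assert g.number_of_edges() == 0

    def test_negative_edge_kept_by_absolute_rule(self):
        corr = self._corr([("a", "b", -0.75)], ["a", "b"])
        g = build_threshold_graph(corr, 0.7)
        assert g["a"]["b"]["weight"] == pytest.approx(-0.75)

    def test_tiny_threshold_gives_complete_graph(self, rng):
        names = list("abcd")
        vals = rng.uniform(0.2, 0.9, size=(4, 4))
        corr = pd.DataFrame((vals + vals.T) / 2, index=names, columns=names)
        np.fill_diagonal(corr.values, 1.0)
        g = build_threshold_graph(corr, 0.01)
        assert g.number_of_edges() == 6

    def test_invalid_threshold(self):
        corr = self._corr([], ["a"])
        with pytest.raises(ValueError):
            build_threshold_graph(corr, 0.0)


class TestClassifyPhenotypeRelation:
    def test_partition_by_sign(self):
        corr = pd.DataFrame(
            np.eye(4), index=["A", "B", "C", "IMP"], columns=["A", "B", "C", "IMP"]
        )
        corr.loc["A", "IMP"] = corr.loc["IMP", "A"] = 0.8
        corr.loc["B", "IMP"] = corr.loc["IMP", "B"] = -0.75
        corr.loc["C", "IMP"] = corr.loc["IMP", "C"] = 0.3
        g = build_threshold_graph(corr, 0.7)
        rel = classify_phenotype_relation(g, "IMP")
        assert rel.positive == {"A"}
        assert rel.negative == {"B"}
        assert rel.unrelated == {"C"}

    def test_no_neighbors_all_unrelated(self):
        g = nx.Graph()
        g.add_nodes_from(["IMP", "x"])
        rel = classify_phenotype_relation(g, "IMP")
        assert rel.positive == rel.negative == frozenset()
        assert rel.unrelated == {"x"}

    def test_partition_is_complete_and_disjoint(self, rng):
        names = [f"g{i}" for i in range(10)] + ["IMP"]
        vals = rng.uniform(-1, 1, size=(11, 11))
        corr = pd.DataFrame((vals + vals.T) / 2, index=names, columns=names)
        np.fill_diagonal(corr.values, 1.0)
        g = build_threshold_graph(corr, 0.4)
        rel = classify_phenotype_relation(g, "IMP")
        union = rel.positive | rel.negative | rel.unrelated
        assert union == set(names) - {"IMP"}
        assert not (rel.positive & rel.negative)
        assert not (rel.positive & rel.unrelated)

    def test_constructed_couplings_recovered(self):
        """A phenotype built to correlate +0.9 with one gene and -0.9 with
        another at n = 6 classifies exactly as constructed."""
        from impnet.synthetic_data import SimulationSpec, generate_phenotype

        rng = np.random.default_rng(3)
        adsl = rng.normal(size=6)
        # opposing anchors: both couplings are only jointly attainable when
        # the two gene profiles themselves anticorrelate
        bmpr2 = -adsl + 0.3 * rng.normal(size=6)
        profiles = pd.DataFrame(
            np.vstack([adsl, bmpr2, rng.normal(size=(2, 6))]),
            index=["Adsl", "Bmpr2", "g2", "g3"],
            columns=[2, 4, 6, 8, 10, 12],
        )
        spec = SimulationSpec(seed=3)
        series, _ = generate_phenotype(spec, profiles)
        corr = phenotype_correlation_matrix(profiles, series)
        g = build_threshold_graph(corr, 0.7)
        rel = classify_phenotype_relation(g, "IMP_content")
        assert "Adsl" in rel.positive
        assert "Bmpr2" in rel.negative


def policy_oracle(nodes, corr_edges, keep_pairs):
    """Independent rule filter: survive iff the group pair is allowed."""
    kept = {}
    for (u, v), w in corr_edges.items():
        if frozenset({nodes[u], nodes[v]}) in keep_pairs:
            kept[frozenset({u, v})] = w
    return kept


class TestMergeRegulatoryNetwork:
    def _graph(self, groups, edges):
        g = nx.Graph()
        for n, grp in groups.items():
            g.add_node(n, group=grp)
        for u, v, w in edges:
            g.add_edge(u, v, weight=w)
        return g

    def test_clean_input_unchanged(self):
        g = self._graph(
            {"imp1": IMP_GENE, "int1": INTERMEDIATE, "cg1": CG, "IMP": PHENOTYPE},
            [("imp1", "int1", 0.8), ("int1", "cg1", 0.75), ("IMP", "imp1", 0.9)],
        )
        net = merge_regulatory_network(g, [])
        assert len(net.corr_edges) == 3

    def test_same_group_and_cg_imp_edges_removed(self):
        g = self._graph(
            {"cg1": CG, "cg2": CG, "imp1": IMP_GENE, "int1": INTERMEDIATE},
            [("cg1", "cg2", 0.9), ("cg1", "imp1", 0.8), ("cg1", "int1", 0.72)],
        )
        net = merge_regulatory_network(g, [])
        assert frozenset({"cg1", "cg2"}) not in net.corr_edges
        assert frozenset({"cg1", "imp1"}) not in net.corr_edges
        assert frozenset({"cg1", "int1"}) in net.corr_edges

    def test_regulator_edges_always_kept_with_provenance(self):
        g = self._graph({"cg1": CG, "int1": INTERMEDIATE}, [])
        net = merge_regulatory_network(
            g,
            [
                ("cg1", "int1", CG, INTERMEDIATE, "CR26"),
                ("int1", "cg1", INTERMEDIATE, CG, ""),
            ],
        )
        assert ("cg1", "int1", "CR26", False) in net.reg_edges
        assert ("int1", "cg1", "", True) in net.reg_edges  # hypothesized

    def test_phenotype_edges_survive(self):
        g = self._graph(
            {"IMP": PHENOTYPE, "cg1": CG, "imp1": IMP_GENE},
            [("IMP", "cg1", -0.8), ("IMP", "imp1", 0.9)],
        )
        net = merge_regulatory_network(g, [])
        assert len(net.corr_edges) == 2

    def test_missing_group_rejected(self):
        g = nx.Graph()
        g.add_node("x")
        with pytest.raises(ValueError, match="group"):
            merge_regulatory_network(g, [])

    def test_constructed_graph_matches_rule_filter_oracle(self, rng):
        from impnet.phenotype_regnet import DEFAULT_KEEP_PAIRS

        names = [f"n{i}" for i in range(12)]
        pools = [IMP_GENE, CG, INTERMEDIATE]
        groups = {n: pools[i % 3] for i, n in enumerate(names)}
        groups["n11"] = PHENOTYPE
        edges = []
        for i in range(12):
            for j in range(i + 1, 12):
                if rng.random() < 0.4:
                    edges.append((names[i], names[j], float(rng.uniform(-1, 1))))
        g = self._graph(groups, edges)
        net = merge_regulatory_network(g, [])
        expected = policy_oracle(
            groups, {(u, v): w for u, v, w in edges}, DEFAULT_KEEP_PAIRS
        )
        assert net.corr_edges == expected

    def test_merge_is_order_independent(self, rng):
        g = self._graph(
            {"a": IMP_GENE, "b": INTERMEDIATE, "c": CG},
            [("a", "b", 0.8), ("b", "c", 0.9)],
        )
        regs = [
            ("c", "a", CG, IMP_GENE, "CR1"),
            ("b", "a", INTERMEDIATE, IMP_GENE, ""),
        ]
        n1 = merge_regulatory_network(g, regs)
        n2 = merge_regulatory_network(g, list(reversed(regs)))
        assert n1.corr_edges == n2.corr_edges
        assert n1.reg_edges == n2.reg_edges

    def test_correlation_subnetwork_is_subgraph_of_threshold_graph(self, rng):
        names = [f"g{i}" for i in range(8)] + ["IMP"]
        vals = rng.uniform(-1, 1, size=(9, 9))
        corr = pd.DataFrame((vals + vals.T) / 2, index=names, columns=names)
        np.fill_diagonal(corr.values, 1.0)
        groups = {n: [IMP_GENE, CG, INTERMEDIATE][i % 3] for i, n in enumerate(names)}
        groups["IMP"] = PHENOTYPE
        g = build_threshold_graph(corr, 0.5, groups)
        net = merge_regulatory_network(g, [])
        for pair in net.corr_edges:
            u, v = sorted(pair)
            assert g.has_edge(u, v)
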