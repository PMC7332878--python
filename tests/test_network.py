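"""Network construction, centralities, communities and composite scoring."""

import networkx as nx
import numpy as np
import pytest

from helpers import (brute_betweenness, brute_closeness,
                     brute_modularity_best_partition)
from zhengnet import datasets, network as net
from zhengnet.errors import InvalidParameterError, ValidationError
from zhengnet.relations import RelationPrediction


def _preds(pairs, label=1):
    return [RelationPrediction(tuple(sorted(p)), float(label), label, 1)
            for p in pairs]


class TestBuildNetwork:
    def test_triangle(self):
        g = net.build_network(_preds([("A", "B"), ("B", "C"), ("A", "C")]))
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 3

    def test_duplicates_collapse(self):
        g = net.build_network(_preds([("A", "B"), ("B", "A"), ("A", "B")]))
        assert g.number_of_edges() == 1

    def test_negative_predictions_excluded(self):
        preds = _preds([("A", "B")]) + _preds([("C", "D")], label=0)
        g = net.build_network(preds)
        assert set(g.nodes) == {"A", "B"}

    def test_bulk_dedup_matches_set_oracle(self):
        rng = np.random.default_rng(3)
        pairs = [tuple(sorted(rng.choice(30, size=2, replace=False).tolist()))
                 for _ in range(150)]
        pairs = [(f"G{a}", f"G{b}") for a, b in pairs]
        g = net.build_network(_preds(pairs))
        assert g.number_of_edges() == len(set(pairs))

    def test_empty_predictions_warn_and_empty(self):
        g = net.build_network(_preds([("A", "B")], label=0))
        assert g.number_of_nodes() == 0


class TestCentralities:
    def test_star_center_all_ones(self):
        g = nx.relabel_nodes(nx.star_graph(3), str)
        prof = net.compute_centralities(g)["0"]
        assert (prof.cd, prof.cb, prof.cc, prof.ce) == (1, 1, 1, 1)

    def test_path_endpoint_zero_betweenness(self):
        g = nx.relabel_nodes(nx.path_graph(3), str)
        assert net.compute_centralities(g)["0"].cb == 0

    def test_single_node_degenerate_contract(self):
        g = nx.Graph()
        g.add_node("X")
        prof = net.compute_centralities(g)["X"]
        assert (prof.cd, prof.cb, prof.cc, prof.ce) == (0, 0, 0, 1)

    def test_betweenness_matches_brute_force(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(10, 0.35, seed=3), str)
        profs = net.compute_centralities(g)
        brute = brute_betweenness(g)
        mx = max(brute.values())
        for v in g:
            expect = brute[v] / mx if mx > 0 else 0.0
            assert profs[v].cb == pytest.approx(expect, abs=1e-12)

    def test_closeness_matches_brute_force(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(12, 0.25, seed=7), str)
        profs = net.compute_centralities(g)
        brute = brute_closeness(g)
        mx = max(brute.values())
        for v in g:
            assert profs[v].cc == pytest.approx(brute[v] / mx, abs=1e-12)

    def test_empty_network_rejected(self):
        with pytest.raises(ValidationError):
            net.compute_centralities(nx.Graph())


class TestCommunities:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        g.add_edges_from([("A", "B"), ("B", "C"), ("A", "C"),
                          ("X", "Y"), ("Y", "Z"), ("X", "Z")])
        part = net.detect_communities(g, seed=0)
        assert sorted(len(s.members) for s in part.subnets) == [3, 3]
        # modularity of the returned partition equals the brute-force optimum
        q = nx.community.modularity(g, [set(s.members) for s in part.subnets])
        assert q == pytest.approx(brute_modularity_best_partition(g), abs=1e-12)

    def test_complete_graph_single_subnet(self):
        g = nx.relabel_nodes(nx.complete_graph(4), str)
        part = net.detect_communities(g, seed=1)
        assert len(part.subnets) == 1

    def test_deterministic_under_fixed_seed(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(30, 0.15, seed=9), str)
        p1 = net.detect_communities(g, seed=4)
        p2 = net.detect_communities(g, seed=4)
        assert [s.members for s in p1.subnets] == [s.members for s in p2.subnets]

    def test_partition_covers_nodes_exactly_once(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(25, 0.2, seed=2), str)
        part = net.detect_communities(g, seed=0)
        all_members = [v for s in part.subnets for v in s.members]
        assert sorted(all_members) == sorted(g.nodes)


class TestFormulas:
    @pytest.mark.parametrize("gene", datasets.FORMULA_CONSISTENT_GENES)
    def test_cmi_reproduces_reference_rows(self, gene):
        table = {**datasets.CHD_TOP_GENES, **datasets.STROKE_TOP_GENES}
        ref = {**datasets.CHD_REFERENCE_CMI, **datasets.STROKE_REFERENCE_CMI}
        prof, _ = table[gene]
        cmi = net.compute_cmi(prof)
        digits = len(str(ref[gene]).split(".")[-1]) if "." in str(ref[gene]) else 0
        assert round(cmi, digits) == pytest.approx(ref[gene])

    def test_zero_betweenness_falls_back_to_hub(self):
        assert net.compute_cmi(net.CentralityProfile(0.9, 0.0, 0.5, 0.7)) == 0.7

    def test_cc_zero_guard(self):
        with pytest.raises(InvalidParameterError):
            net.compute_cmi(net.CentralityProfile(1.0, 0.5, 0.0, 0.2))

    @pytest.mark.parametrize("n,zjw,expected", [(5, 0.0, 5.0), (10, 2.5, 12.5)])
    def test_subnet_weight_sum(self, n, zjw, expected):
        part = net.SubnetPartition([net.SubnetInfo(1, frozenset(
            f"G{i}" for i in range(n)))])
        net.score_subnets(part, {1: zjw})
        assert part.subnets[0].sw == expected

    def test_negative_zjw_rejected(self):
        part = net.SubnetPartition([net.SubnetInfo(1, frozenset("AB"))])
        with pytest.raises(ValidationError):
            net.score_subnets(part, {1: -1.0})

    def test_minmax_normalization(self):
        subs = [net.SubnetInfo(i + 1, frozenset({f"G{i}{j}" for j in range(n)}))
                for i, n in enumerate([2, 4, 6])]
        part = net.SubnetPartition(subs)
        net.score_subnets(part)
        net.normalize_subnet_weights(part)
        assert [s.zsw for s in part.subnets] == [0.0, 0.5, 1.0]

    def test_single_subnet_zsw_one(self):
        part = net.SubnetPartition([net.SubnetInfo(1, frozenset("ABC"))])
        net.score_subnets(part)
        net.normalize_subnet_weights(part)
        assert part.subnets[0].zsw == 1.0

    @pytest.mark.parametrize("cmi,zsw,expected",
                             [(1.29, 1.0, 2.29), (1.70, 0.88, 2.58), (0, 0, 0)])
    def test_gene_weight_sum(self, cmi, zsw, expected):
        assert net.compute_gw(cmi, zsw) == pytest.approx(expected)

    def test_cmi_monotonicity_random_perturbations(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            cd, cb, ce = rng.uniform(0.05, 1, 3)
            cc = rng.uniform(0.1, 1)
            base = net.compute_cmi(net.CentralityProfile(cd, cb, cc, ce))
            eps = 0.01
            assert net.compute_cmi(
                net.CentralityProfile(min(cd + eps, 1), cb, cc, ce)) >= base
            assert net.compute_cmi(
                net.CentralityProfile(cd, min(cb + eps, 1), cc, ce)) >= base
            assert net.compute_cmi(
                net.CentralityProfile(cd, cb, cc, min(ce + eps, 1.01))) >= base
            assert net.compute_cmi(
                net.CentralityProfile(cd, cb, min(cc + eps, 1), ce)) <= base


class TestRanking:
    def test_star_center_ranked_first(self):
        g = nx.relabel_nodes(nx.star_graph(4), str)
        table = net.rank_genes(g, seed=0)
        assert table.iloc[0]["Gene"] == "0"

    def test_gw_identity_on_every_row(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(20, 0.2, seed=6), str)
        g.remove_nodes_from(list(nx.isolates(g)))
        table = net.rank_genes(g, seed=0)
        assert np.allclose(table["GW"], table["CMI"] + table["ZSW"], atol=1e-9)

    def test_table_matches_first_principles_recomputation(self):
        """Every row re-derived independently: centralities from networkx
        primitives scaled by hand, ZSW from explicit min-max, GW as a sum."""
        g = nx.relabel_nodes(nx.gnp_random_graph(20, 0.25, seed=13), str)
        g.remove_nodes_from(list(nx.isolates(g)))
        table = net.rank_genes(g, seed=3).set_index("Gene")

        part = net.detect_communities(g, seed=3)
        sw = {s.subnet_id: len(s.members) for s in part.subnets}
        lo, hi = min(sw.values()), max(sw.values())
        deg = dict(g.degree())
        btw = brute_betweenness(g)
        clo = brute_closeness(g)
        mdeg, mbtw, mclo = max(deg.values()), max(btw.values()), max(clo.values())
        for v in g:
            cd = deg[v] / mdeg
            cb = btw[v] / mbtw if mbtw else 0.0
            cc = clo[v] / mclo
            comp = next(c for c in nx.connected_components(g) if v in c)
            eig = nx.eigenvector_centrality_numpy(g.subgraph(comp))
            ce = eig[v] / max(eig.values())
            cmi = cd * cb / cc + ce if cb > 0 else ce
            sub = part.subnet_of(v)
            zsw = 1.0 if hi == lo else (sw[sub.subnet_id] - lo) / (hi - lo)
            row = table.loc[v]
            assert row["CMI"] == pytest.approx(cmi, abs=1e-9)
            assert row["ZSW"] == pytest.approx(zsw, abs=1e-12)
            assert row["GW"] == pytest.approx(cmi + zsw, abs=1e-9)

    def test_zsw_in_unit_interval_and_max_attained(self):
        g = nx.relabel_nodes(nx.gnp_random_graph(25, 0.15, seed=8), str)
        g.remove_nodes_from(list(nx.isolates(g)))
        table = net.rank_genes(g, seed=0)
        assert ((table["ZSW"] >= 0) & (table["ZSW"] <= 1)).all()
        assert np.isclose(table["ZSW"].max(), 1.0)
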