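"""Rank-average consensus, hub extraction, MCL subnetworks."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcellgrn import consensus as cns
from tcellgrn.grn import RankedEdgeList
from tcellgrn.metrics import edge_recovery_aupr, random_baseline_aupr


def make_list(method, triples, directed=False):
    edges = pd.DataFrame(triples, columns=["gene_a", "gene_b", "score"])
    edges["rank"] = stats.rankdata(-edges["score"], method="average")
    return RankedEdgeList(method=method, edges=edges, universe=len(edges),
                          directed=directed)


class TestAverageRankConsensus:
    def test_single_method_preserves_order(self):
        el = make_list("m1", [("a", "b", 3.0), ("a", "c", 2.0), ("b", "c", 1.0)])
        net = cns.average_rank_consensus([el], ["a", "b", "c"])
        assert list(net.edges[["gene_a", "gene_b"]].itertuples(index=False, name=None)) == \
            [("a", "b"), ("a", "c"), ("b", "c")]

    def test_opposed_rankings_tie_completely(self):
        e1 = make_list("m1", [("a", "b", 3.0), ("a", "c", 2.0), ("b", "c", 1.0)])
        e2 = make_list("m2", [("a", "b", 1.0), ("a", "c", 2.0), ("b", "c", 3.0)])
        net = cns.average_rank_consensus([e1, e2], ["a", "b", "c"])
        np.testing.assert_allclose(net.edges["score"], 2.0)

    def test_unanimous_top_edge_dominates(self):
        lists = [make_list(f"m{i}", [("a", "b", 9.0), ("a", "c", float(i)), ("b", "c", 1.0)])
                 for i in range(2, 5)]
        net = cns.average_rank_consensus(lists, ["a", "b", "c"])
        assert (net.edges.iloc[0][["gene_a", "gene_b"]] == ["a", "b"]).all()

    def test_missing_edges_get_midrank(self):
        # universe of 4 genes: E = 6 candidate pairs; one listed edge (L = 1)
        # unlisted pairs receive (1 + 1 + 6) / 2 = 4
        el = make_list("m1", [("a", "b", 5.0)])
        net = cns.average_rank_consensus([el], ["a", "b", "c", "d"])
        scores = net.edges.set_index(["gene_a", "gene_b"])["score"]
        assert scores.loc[("a", "b")] == 1.0
        assert scores.loc[("c", "d")] == 4.0

    def test_directed_list_symmetrized_by_max(self):
        el = make_list("m", [("a", "b", 0.9), ("b", "a", 0.2), ("a", "c", 0.5)],
                       directed=True)
        net = cns.average_rank_consensus([el], ["a", "b", "c"])
        scores = net.edges.set_index(["gene_a", "gene_b"])["score"]
        assert scores.loc[("a", "b")] == 1.0  # max(0.9, 0.2) outranks 0.5

    def test_method_and_row_order_invariance(self):
        rng = np.random.default_rng(0)
        genes = list("abcdef")
        triples = [(a, b, float(rng.random())) for i, a in enumerate(genes)
                   for b in genes[i + 1:]][:10]
        e1 = make_list("m1", triples)
        e2 = make_list("m2", [(a, b, s * 2) for a, b, s in triples[::-1]])
        net_ab = cns.average_rank_consensus([e1, e2], genes)
        net_ba = cns.average_rank_consensus([e2, e1], genes)
        pd.testing.assert_frame_equal(net_ab.edges, net_ba.edges)

    def test_disjoint_universe_rejected(self):
        el = make_list("m1", [("x", "y", 1.0)])
        with pytest.raises(ValueError):
            cns.average_rank_consensus([el], ["a", "b"])


class TestTopKAndHubs:
    def _net(self):
        el = make_list("m1", [("a", "b", 5.0), ("a", "c", 4.0), ("a", "d", 3.0),
                              ("b", "c", 2.0), ("c", "d", 1.0)])
        return cns.average_rank_consensus([el], list("abcd"))

    def test_top_k_identity_and_head(self):
        net = self._net()
        assert len(cns.top_k(net, k=100)) == len(net)
        top1 = cns.top_k(net, k=1)
        assert (top1.edges.iloc[0][["gene_a", "gene_b"]] == ["a", "b"]).all()

    def test_boundary_tie_resolves_lexicographically(self):
        e = make_list("m", [("a", "b", 2.0), ("a", "c", 1.0), ("b", "c", 1.0)])
        net = cns.average_rank_consensus([e], list("abc"))
        top2 = cns.top_k(net, k=2)
        assert list(top2.edges[["gene_a", "gene_b"]].itertuples(index=False, name=None)) == \
            [("a", "b"), ("a", "c")]

    def test_star_graph_center_is_hub(self):
        el = make_list("m", [("hub", x, 1.0) for x in ("a", "b", "c", "d")])
        net = cns.top_k(cns.average_rank_consensus([el], ["hub", "a", "b", "c", "d"]), k=4)
        hub_genes, n_edges = cns.hubs(net, fraction=0.2)
        assert hub_genes == ["hub"] and n_edges == 4

    def test_hand_degrees_and_tie_break(self):
        el = make_list("m", [("a", "b", 6.0), ("a", "c", 5.0), ("b", "c", 4.0),
                             ("d", "e", 3.0), ("e", "f", 2.0), ("a", "d", 1.0)])
        net = cns.top_k(cns.average_rank_consensus([el], list("abcdef")), k=6)
        deg = net.degrees
        assert deg.to_dict() == {"a": 3, "b": 2, "c": 2, "d": 2, "e": 2, "f": 1}
        hub_genes, _ = cns.hubs(net, fraction=0.5)
        assert hub_genes == ["a", "b", "c"]  # ties by id after degree


def triangle_edges(prefix, offset=0.0):
    nodes = [f"{prefix}{i}" for i in range(3)]
    return [(nodes[i], nodes[j], 1.0 + offset) for i in range(3) for j in range(i + 1, 3)]


class TestMCL:
    def test_two_disjoint_triangles(self):
        edges = pd.DataFrame(triangle_edges("x") + triangle_edges("y"),
                             columns=["gene_a", "gene_b", "weight"])
        clusters = cns.mcl(edges)
        assert len(set(clusters.values())) == 2
        assert len({clusters[f"x{i}"] for i in range(3)}) == 1
        assert len({clusters[f"y{i}"] for i in range(3)}) == 1

    def test_single_edge(self):
        edges = pd.DataFrame([("a", "b", 1.0)], columns=["gene_a", "gene_b", "weight"])
        clusters = cns.mcl(edges)
        assert clusters["a"] == clusters["b"]

    def test_high_inflation_still_partitions_triangle(self):
        edges = pd.DataFrame(triangle_edges("t"), columns=["gene_a", "gene_b", "weight"])
        clusters = cns.mcl(edges, inflation=50.0)
        assert set(clusters) == {"t0", "t1", "t2"}
        assert all(isinstance(c, int) for c in clusters.values())

    def test_k_disjoint_cliques_give_k_clusters(self):
        rows = []
        for k in range(4):
            nodes = [f"c{k}n{i}" for i in range(4)]
            rows += [(a, b, 1.0) for i, a in enumerate(nodes) for b in nodes[i + 1:]]
        edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight"])
        clusters = cns.mcl(edges)
        assert len(set(clusters.values())) == 4
        assert len(clusters) == 16  # a partition: every node exactly once

    def test_subnetwork_lookup_and_error(self):
        clusters = {"a": 1, "b": 1, "c": 2}
        assert cns.subnetwork_of(clusters, "a") == {"a", "b"}
        with pytest.raises(KeyError):
            cns.subnetwork_of(clusters, "zzz")


class TestRecoveryMetrics:
    def test_perfect_ranking_has_unit_aupr(self):
        truth = {("a", "b"), ("c", "d")}
        el = make_list("m", [("a", "b", 9.0), ("c", "d", 8.0), ("a", "c", 1.0)])
        assert edge_recovery_aupr(el, truth, list("abcd")) == pytest.approx(1.0)

    def test_random_baseline_is_prevalence(self):
        assert random_baseline_aupr({("a", "b")}, list("abcd")) == pytest.approx(1 / 6)

    def test_informative_method_lifts_consensus_above_chance(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(12)]
        truth = {(genes[i], genes[i + 1]) for i in range(0, 12, 2)}
        informative = make_list("good", [(a, b, 10.0) for a, b in truth])
        noise_edges = [(a, b, float(rng.random()))
                       for i, a in enumerate(genes) for b in genes[i + 1:]]
        noisy = make_list("rand", noise_edges)
        net = cns.average_rank_consensus([informative, noisy], genes)
        assert edge_recovery_aupr(net, truth, genes) > random_baseline_aupr(truth, genes)
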