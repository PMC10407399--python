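"""The five network-inference engines and the MI estimator behind three of them."""

import numpy as np
import pytest
from scipy import stats

from tcellgrn import grn

from conftest import toy_matrix


def mi_oracle(joint: np.ndarray) -> float:
    """Plug-in MI in bits from an explicit joint count table."""
    p = joint / joint.sum()
    px, py = p.sum(axis=1), p.sum(axis=0)
    total = 0.0
    for i in range(p.shape[0]):
        for j in range(p.shape[1]):
            if p[i, j] > 0:
                total += p[i, j] * np.log2(p[i, j] / (px[i] * py[j]))
    return total


class TestMI:
    def test_perfect_two_bin_dependence_is_one_bit(self):
        x = np.arange(10, dtype=float)
        m = toy_matrix(np.vstack([x, x]))
        est = grn.mi_matrix(m, bins=2)
        assert est.mi.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert mi_oracle(np.array([[5, 0], [0, 5]])) == pytest.approx(1.0)

    def test_factorized_joint_is_zero(self):
        # ranks of x: bins [0,0,1,1]; y arranged so the joint is uniform
        x = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        y = np.array([1.0, 3.0, 2.0, 4.0] * 2)
        m = toy_matrix(np.vstack([x, y]), samples=[f"s{i}" for i in range(8)])
        est = grn.mi_matrix(m, bins=2)
        assert est.mi.iloc[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_self_mi_is_entropy(self):
        x = np.arange(12, dtype=float)
        m = toy_matrix(np.vstack([x, x[::-1]]))
        est = grn.mi_matrix(m, bins=3)
        assert est.mi.iloc[0, 0] == pytest.approx(np.log2(3), abs=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        y = x + rng.normal(0, 0.5, 40)
        a = grn.mi_matrix(toy_matrix(np.vstack([x, y]))).mi.iloc[0, 1]
        b = grn.mi_matrix(toy_matrix(np.vstack([np.exp(x), y**3]))).mi.iloc[0, 1]
        assert a == pytest.approx(b, abs=1e-12)

    def test_gaussian_mi_monotone_in_correlation(self):
        rng = np.random.default_rng(1)
        n = 2000
        mis = []
        for r in np.arange(0.1, 1.0, 0.1):
            x = rng.normal(size=n)
            y = r * x + np.sqrt(1 - r**2) * rng.normal(size=n)
            mis.append(grn.mi_matrix(toy_matrix(np.vstack([x, y]))).mi.iloc[0, 1])
        assert all(b > a for a, b in zip(mis, mis[1:]))


class TestMISignificance:
    def test_zero_mi_gives_p_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0] * 2)
        y = np.array([1.0, 3.0, 2.0, 4.0] * 2)
        est = grn.mi_matrix(toy_matrix(np.vstack([x, y])), bins=2)
        p = grn.mi_significance(est)
        assert p.iloc[0, 1] == pytest.approx(1.0)

    def test_chi2_value_matches_cdf_oracle(self):
        # hand case: n = 100, B = 3, MI = 0.2 bits
        G = 2 * 100 * np.log(2) * 0.2
        expected = stats.chi2.sf(G, (3 - 1) ** 2)
        rng = np.random.default_rng(2)
        m = toy_matrix(rng.normal(size=(2, 100)))
        est = grn.mi_matrix(m, bins=3)
        est.mi.iloc[0, 1] = est.mi.iloc[1, 0] = 0.2
        p = grn.mi_significance(est)
        assert p.iloc[0, 1] == pytest.approx(expected, abs=1e-12)

    def test_permutation_floor(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        est = grn.mi_matrix(toy_matrix(np.vstack([x, x])), bins=3)
        p = grn.mi_significance(est, method="permutation", n_perm=49, seed=0)
        assert p.iloc[0, 1] >= 1 / 50


def _chain_estimate(seed, n=500, sd=0.1):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = x + rng.normal(0, sd, n)
    z = y + rng.normal(0, sd, n)
    m = toy_matrix(np.vstack([x, y, z]), genes=["X", "Y", "Z"])
    return grn.mi_matrix(m)


class TestAracne:
    def test_transitive_edge_removed_from_chain(self):
        est = _chain_estimate(seed=7)
        p = grn.mi_significance(est)
        result = grn.aracne(est, p, dpi_tolerance=0.01)
        pairs = set(map(tuple, result.edges[["gene_a", "gene_b"]].to_numpy()))
        assert ("X", "Y") in pairs and ("Y", "Z") in pairs and ("X", "Z") not in pairs

    def test_equal_mi_triangle_survives(self):
        est = _chain_estimate(seed=8)
        mi = est.mi.to_numpy()
        v = 1.5
        mi[0, 1] = mi[1, 0] = mi[0, 2] = mi[2, 0] = mi[1, 2] = mi[2, 1] = v
        est.mi.iloc[:, :] = mi
        p = est.mi.copy() * 0.0  # all significant
        assert len(grn.aracne(est, p, dpi_tolerance=0.01)) == 3

    def test_tolerance_one_removes_nothing(self):
        est = _chain_estimate(seed=9)
        p = grn.mi_significance(est)
        gated = (p < 0.05).to_numpy().sum() // 2
        assert len(grn.aracne(est, p, dpi_tolerance=1.0)) == gated


class TestTingeAndCLR:
    def test_tinge_ranks_everything(self):
        est = _chain_estimate(seed=10)
        result = grn.tinge_like(est)
        assert len(result) == 3
        top = result.edges.iloc[0]
        mi = est.mi.to_numpy()
        assert top["score"] == pytest.approx(max(mi[0, 1], mi[0, 2], mi[1, 2]))

    def test_clr_hand_matrix(self):
        genes = ["a", "b", "c", "d"]
        mi = np.array([
            [9.0, 0.6, 0.2, 0.1],
            [0.6, 9.0, 0.3, 0.3],
            [0.2, 0.3, 9.0, 0.4],
            [0.1, 0.3, 0.4, 9.0],
        ])
        import pandas as pd
        est = grn.MIEstimate(mi=pd.DataFrame(mi, index=genes, columns=genes),
                             bins=3, labels=np.zeros((4, 10), int), n_samples=10)
        result = grn.clr(est)
        # plug-in arithmetic for the (a,b) pair
        row_a = np.array([0.6, 0.2, 0.1])
        row_b = np.array([0.6, 0.3, 0.3])
        za = max(0.0, (0.6 - row_a.mean()) / row_a.std())
        zb = max(0.0, (0.6 - row_b.mean()) / row_b.std())
        expected = np.sqrt(za**2 + zb**2)
        edge = result.edges.set_index(["gene_a", "gene_b"]).loc[("a", "b"), "score"]
        assert edge == pytest.approx(expected, abs=1e-12)

    def test_clr_row_mean_scores_zero_contribution(self):
        row = np.array([0.3, 0.2, 0.4])
        z = (0.3 - row.mean()) / row.std()
        assert max(0.0, z) == 0.0  # anchors the clipping convention


class TestGenie3:
    def test_single_informative_regulator_takes_all_importance(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=80)
        const = np.zeros(80)
        target = 2 * x
        m = toy_matrix(np.vstack([x, const, target]), genes=["x", "flat", "y"])
        result = grn.genie3_like(m, ["x", "flat"], n_trees=30, seed=0)
        edge = result.edges.set_index(["gene_a", "gene_b"])
        assert edge.loc[("x", "y"), "score"] == pytest.approx(1.0)

    def test_planted_regulator_recovered_over_decoys(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(11, 200))
            y = 2 * X[0] + rng.normal(0, 1.0, 200)
            genes = [f"x{i}" for i in range(11)] + ["y"]
            m = toy_matrix(np.vstack([X, y]), genes=genes)
            result = grn.genie3_like(m, genes[:-1], n_trees=50, seed=seed)
            to_y = result.edges[result.edges["gene_b"] == "y"].sort_values("rank")
            hits += to_y.iloc[0]["gene_a"] == "x0"
        assert hits >= 19

    def test_determinism(self):
        rng = np.random.default_rng(12)
        m = toy_matrix(rng.normal(size=(5, 40)))
        a = grn.genie3_like(m, m.genes[:3], n_trees=25, seed=3)
        b = grn.genie3_like(m, m.genes[:3], n_trees=25, seed=3)
        assert a.edges.equals(b.edges)


class TestPearsonNetwork:
    def test_duplicate_pair_included(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=50)
        m = toy_matrix(np.vstack([x, x, rng.normal(size=50)]))
        result = grn.pearson_network(m, cutoff=0.7)
        top = result.edges.iloc[0]
        assert {top["gene_a"], top["gene_b"]} == {"g1", "g2"}
        assert top["score"] == pytest.approx(1.0)

    def test_independent_pair_excluded(self):
        excluded = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            m = toy_matrix(rng.normal(size=(2, 500)))
            excluded += len(grn.pearson_network(m, cutoff=0.7)) == 0
        assert excluded == 50

    def test_cutoff_zero_complete_graph(self):
        rng = np.random.default_rng(14)
        m = toy_matrix(rng.normal(size=(5, 30)))
        assert len(grn.pearson_network(m, cutoff=0.0)) == 10


class TestRankedEdgeListContract:
    def test_all_methods_emit_valid_ranks(self, gene_level_dataset):
        _, truth, matrix, _ = gene_level_dataset
        est = grn.mi_matrix(matrix)
        p = grn.mi_significance(est)
        results = [
            grn.pearson_network(matrix),
            grn.aracne(est, p),
            grn.tinge_like(est),
            grn.clr(est),
        ]
        for res in results:  # __post_init__ validates the rank permutation
            ranks = np.sort(res.edges["rank"].to_numpy())
            assert ranks.sum() == pytest.approx(len(ranks) * (len(ranks) + 1) / 2)
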