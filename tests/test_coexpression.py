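"""SOM, topological-overlap modules, eigengenes, GSEA, correlation profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tcellgrn import coexpression as coex
from tcellgrn.coexpression import _enrichment_score

from conftest import toy_matrix


class TestMostVariable:
    def test_ordering_matches_brute_force_sd(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(0, [0.5, 3.0, 1.0, 2.0, 0.1], size=(10, 5)).T
        m = toy_matrix(vals)
        got = coex.most_variable_genes(m, 5)
        sds = {g: np.std(vals[i], ddof=1) for i, g in enumerate(m.genes)}
        expected = sorted(m.genes, key=lambda g: (-sds[g], g))
        assert got == expected

    def test_constant_gene_never_first(self):
        m = toy_matrix([[1, 1, 1], [0, 5, 9]])
        assert coex.most_variable_genes(m, 1) == ["g2"]

    def test_n_too_large(self):
        with pytest.raises(ValueError):
            coex.most_variable_genes(toy_matrix([[1, 2]]), 5)


class TestSOM:
    def _antipodal(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=6)
        base = (base - base.mean()) / base.std()
        up = np.tile(base, (10, 1)) + rng.normal(0, 0.05, (10, 6))
        down = np.tile(-base, (10, 1)) + rng.normal(0, 0.05, (10, 6))
        genes = [f"u{i}" for i in range(10)] + [f"d{i}" for i in range(10)]
        return pd.DataFrame(np.vstack([up, down]), index=genes)

    def test_antipodal_groups_split_on_2x1_grid(self):
        grid = coex.som_fit(self._antipodal(), grid=(2, 1), iterations=500, seed=0)
        nodes_up = set(grid.assignment[:10])
        nodes_down = set(grid.assignment[10:])
        assert len(nodes_up) == 1 and len(nodes_down) == 1 and nodes_up != nodes_down

    def test_zero_iterations_uses_initial_prototypes(self):
        profiles = self._antipodal()
        grid = coex.som_fit(profiles, grid=(2, 2), iterations=0, seed=0)
        d = ((profiles.to_numpy()[:, None, :] - grid.prototypes[None, :, :]) ** 2).sum(axis=2)
        np.testing.assert_array_equal(grid.assignment.to_numpy(), d.argmin(axis=1))

    def test_determinism(self):
        a = coex.som_fit(self._antipodal(), grid=(3, 3), iterations=300, seed=5)
        b = coex.som_fit(self._antipodal(), grid=(3, 3), iterations=300, seed=5)
        np.testing.assert_array_equal(a.prototypes, b.prototypes)
        assert a.assignment.equals(b.assignment)

    def test_quantization_error_decreases(self):
        grid = coex.som_fit(self._antipodal(), grid=(2, 2), iterations=2000, seed=2)
        qe = grid.quantization_errors
        assert qe[-1] <= qe[0] + 1e-9


class TestTOMAndModules:
    def test_tom_bounds_and_diagonal(self):
        rng = np.random.default_rng(3)
        r = np.corrcoef(rng.normal(size=(8, 30)))
        tom = coex.topological_overlap(np.abs(r) ** 3)
        assert np.allclose(np.diag(tom), 1.0)
        off = tom[~np.eye(8, dtype=bool)]
        assert np.all(off >= 0) and np.all(off <= 1)

    def test_beta_one_adjacency_is_abs_correlation(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(4, 50))
        r = np.abs(np.corrcoef(vals))
        assert np.allclose(r ** 1, r, atol=1e-12)  # power identity anchors the convention

    def test_planted_modules_recovered_exactly(self):
        rng = np.random.default_rng(5)
        n, size = 60, 20
        drivers = rng.normal(size=(2, n))
        block1 = drivers[0] + rng.normal(0, 0.45, (size, n))
        block2 = drivers[1] + rng.normal(0, 0.45, (size, n))
        m = toy_matrix(np.vstack([block1, block2]))
        assignment = coex.wgcna_modules(m, beta=6, min_module_size=10)
        labels = assignment.labels
        first, second = set(labels[:size]), set(labels[size:])
        assert len(first) == 1 and len(second) == 1 and first != second
        assert 0 not in first | second

    def test_constant_gene_dropped_with_warning(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(size=(12, 30))
        vals[0] = 1.0
        with pytest.warns(UserWarning, match="constant"):
            assignment = coex.wgcna_modules(toy_matrix(vals), beta=3, min_module_size=5)
        assert "g1" not in assignment.labels.index


class TestEigengene:
    def test_identical_profiles(self):
        profile = np.array([1.0, 3.0, 2.0, 5.0])
        m = toy_matrix(np.tile(profile, (3, 1)))
        me = coex.module_eigengene(m, m.genes)
        z = (profile - profile.mean()) / profile.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(me.scores.to_numpy(), expected, atol=1e-9)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(3, 6))
        m = toy_matrix(vals)
        me = coex.module_eigengene(m, m.genes)
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        w, v = np.linalg.eigh(z.T @ z)
        top = v[:, np.argmax(w)]
        np.testing.assert_allclose(np.abs(me.scores), np.abs(top / np.linalg.norm(top)),
                                   atol=1e-9)

    def test_orientation_rule_is_deterministic_under_sign_flip(self):
        # flipping every gene leaves the eigengene subspace unchanged and the
        # orientation rule (non-negative correlation with the module's mean
        # standardized profile) holds in both cases
        rng = np.random.default_rng(8)
        vals = rng.normal(size=(4, 10)) + np.array([1.0, 2, 1.5, 1.8])[:, None] * rng.normal(size=10)
        genes = [f"g{i+1}" for i in range(4)]
        for sign in (1.0, -1.0):
            m = toy_matrix(sign * vals, genes=genes)
            me = coex.module_eigengene(m, genes)
            z = sign * vals
            z = (z - z.mean(axis=1, keepdims=True)) / z.std(axis=1, keepdims=True)
            assert np.dot(me.scores.to_numpy(), z.mean(axis=0)) >= 0
        a = coex.module_eigengene(toy_matrix(vals, genes=genes), genes).scores.to_numpy()
        b = coex.module_eigengene(toy_matrix(-vals, genes=genes), genes).scores.to_numpy()
        np.testing.assert_allclose(np.abs(a), np.abs(b), atol=1e-9)

    def test_explains_at_least_any_member_gene(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(size=(6, 20))
        m = toy_matrix(vals)
        me = coex.module_eigengene(m, m.genes)
        z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
        var_expl_me = ((z @ me.scores.to_numpy()) ** 2).sum()
        for row in z:
            u = row / np.linalg.norm(row)
            assert var_expl_me >= ((z @ u) ** 2).sum() - 1e-9


class TestModuleTrait:
    def test_indicator_extremes_and_oracle(self):
        ind = np.array([1.0, 1, 0, 0, 1, 0])
        orth = np.array([1.0, -1, 1, -1, 1, -1]) - (1/3)  # orthogonal to ind after centering?
        rng = np.random.default_rng(10)
        noise = rng.normal(size=6)
        eig = pd.DataFrame({"ME1": ind, "ME2": noise})
        traits = pd.DataFrame({"t": ind})
        r, p = coex.module_trait_correlation(eig, traits)
        assert r.loc["ME1", "t"] == pytest.approx(1.0)
        hand_r, hand_p = stats.pearsonr(noise, ind)
        assert r.loc["ME2", "t"] == pytest.approx(hand_r, abs=1e-12)
        assert p.loc["ME2", "t"] == pytest.approx(hand_p, abs=1e-9)


def enrichment_score_oracle(stats_by_gene: dict, gene_set: set) -> float:
    """Brute-force running sum on an explicit ordered list."""
    ordered = sorted(stats_by_gene, key=lambda g: -stats_by_gene[g])
    hits = [g in gene_set for g in ordered]
    total_hit_weight = sum(abs(stats_by_gene[g]) for g, h in zip(ordered, hits) if h)
    n_miss = len(ordered) - sum(hits)
    running, best = 0.0, 0.0
    for g, h in zip(ordered, hits):
        running += abs(stats_by_gene[g]) / total_hit_weight if h else -1.0 / n_miss
        if abs(running) > abs(best):
            best = running
    return best


class TestGSEA:
    def test_top_loaded_set_matches_running_sum_oracle(self):
        values = {f"g{i}": 10 - i for i in range(10)}
        gene_set = {"g0", "g1", "g2"}
        ranked = pd.Series(values)
        res = coex.gsea(ranked, gene_set, n_perm=50, seed=0)
        assert res.es == pytest.approx(enrichment_score_oracle(values, gene_set), abs=1e-12)
        assert res.es > 0

    def test_set_of_all_genes_scores_zero(self):
        ranked = pd.Series({"a": 3.0, "b": 1.0, "c": -2.0})
        res = coex.gsea(ranked, {"a", "b", "c"}, n_perm=10, seed=0)
        assert res.es == 0.0

    def test_disjoint_set_rejected(self):
        with pytest.raises(ValueError):
            coex.gsea(pd.Series({"a": 1.0}), {"zzz"}, n_perm=10, seed=0)

    def test_null_nes_centered_at_one(self):
        rng = np.random.default_rng(11)
        values = pd.Series(rng.normal(size=100), index=[f"g{i}" for i in range(100)])
        nes = []
        for i in range(100):
            gene_set = set(rng.choice(values.index, size=10, replace=False))
            res = coex.gsea(values, gene_set, n_perm=100, seed=i)
            if np.isfinite(res.nes):
                nes.append(abs(res.nes))
        assert abs(np.mean(nes) - 1.0) < 0.1

    def test_null_p_super_uniform(self):
        rng = np.random.default_rng(12)
        values = pd.Series(rng.normal(size=60), index=[f"g{i}" for i in range(60)])
        ps = []
        for i in range(100):
            gene_set = set(rng.choice(values.index, size=8, replace=False))
            ps.append(coex.gsea(values, gene_set, n_perm=99, seed=1000 + i).p)
        # super-uniform at permutation resolution: P(p <= x) <= x + MC slack
        for x in (0.05, 0.1, 0.25, 0.5):
            frac = np.mean([p <= x for p in ps])
            assert frac <= x + 3 * np.sqrt(x * (1 - x) / len(ps)) + 0.02


class TestCorrelationProfile:
    def test_duplicate_tops_anticorrelated_bottoms(self):
        rng = np.random.default_rng(13)
        q = rng.normal(size=30)
        vals = np.vstack([q, q + rng.normal(0, 1e-6, 30), -q, rng.normal(size=30)])
        m = toy_matrix(vals, genes=["q", "dup", "anti", "noise"])
        prof = coex.correlation_profile(m, "q")
        assert prof.index[0] == "dup" and prof["r"].iloc[0] == pytest.approx(1.0, abs=1e-6)
        assert prof.index[-1] == "anti" and prof["r"].iloc[-1] == pytest.approx(-1.0)

    def test_hand_fixture_matches_pearson(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(size=(4, 12))
        m = toy_matrix(vals)
        prof = coex.correlation_profile(m, "g1")
        for i, g in enumerate(m.genes[1:], start=1):
            assert prof.loc[g, "r"] == pytest.approx(stats.pearsonr(vals[0], vals[i])[0],
                                                     abs=1e-12)
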