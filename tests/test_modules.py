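"""Module detection by clustering the copula distance, eigengene summaries."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from codc.modules import (
    copula_distance_matrix,
    detect_modules,
    eigengene_network,
    module_eigengene,
)
from codc.scoring import DCMatrix
from codc.simulation import correlated_pair
from conftest import build_paired


def planted_block_distance(n_genes: int = 40, within: float = 0.8, between: float = 0.1):
    """Two equal DC-score blocks; returns (distance matrix, true labels)."""
    half = n_genes // 2
    labels = np.array([0] * half + [1] * (n_genes - half))
    scores = np.where(labels[:, None] == labels[None, :], within, between)
    np.fill_diagonal(scores, 0.0)
    genes = [f"g{i:03d}" for i in range(n_genes)]
    d = DCMatrix(genes=genes, scores=scores)
    return copula_distance_matrix(d), labels, genes


class TestCopulaDistance:
    def test_complements_scores(self, rng):
        scores = np.array([[0.0, 0.3], [0.3, 0.0]])
        d = DCMatrix(genes=["a", "b"], scores=scores)
        dist = copula_distance_matrix(d)
        assert dist[0, 1] == pytest.approx(0.7)
        assert dist[0, 0] == dist[1, 1] == 0.0

    def test_score_extremes(self):
        scores = np.array([[0, 1.0, 0], [1.0, 0, 0], [0, 0, 0]])
        dist = copula_distance_matrix(DCMatrix(genes=list("abc"), scores=scores))
        assert dist[0, 1] == 0.0  # score 1 -> distance 0
        assert dist[0, 2] == 1.0  # score 0 -> distance 1

    def test_symmetry_and_involution(self, rng):
        s = rng.uniform(0, 1, (5, 5))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 0)
        d = DCMatrix(genes=[f"g{i}" for i in range(5)], scores=s)
        dist = copula_distance_matrix(d)
        np.testing.assert_array_equal(dist, dist.T)
        back = 1.0 - dist
        np.fill_diagonal(back, 0.0)
        np.testing.assert_allclose(back, s)


class TestDetectModules:
    def test_k1_single_module(self):
        dist, _, genes = planted_block_distance(10)
        mods = detect_modules(dist, genes, k=1, min_size=1)
        assert mods.k == 1

    def test_k_equals_p_all_singletons(self, rng):
        # distinct random distances so every gene is its own cluster
        p = 6
        s = rng.uniform(0.1, 0.9, (p, p))
        dist = (s + s.T) / 2
        np.fill_diagonal(dist, 0)
        mods = detect_modules(dist, [f"g{i}" for i in range(p)], k=p, min_size=1)
        assert mods.k == p

    def test_planted_two_block_structure_recovered_exactly(self):
        dist, labels, genes = planted_block_distance(40, within=0.8, between=0.1)
        mods = detect_modules(dist, genes, k=2, min_size=1)
        assert adjusted_rand_score(labels, mods.labels) == 1.0

    def test_gene_order_invariance_up_to_relabeling(self, rng):
        dist, labels, genes = planted_block_distance(20)
        perm = rng.permutation(20)
        mods1 = detect_modules(dist, genes, k=2, min_size=1)
        mods2 = detect_modules(
            dist[np.ix_(perm, perm)], [genes[i] for i in perm], k=2, min_size=1
        )
        lab1 = dict(zip(mods1.genes, mods1.labels))
        lab2 = dict(zip(mods2.genes, mods2.labels))
        pairs = {(lab1[g], lab2[g]) for g in genes}
        assert len(pairs) == 2  # a bijection between label sets

    def test_min_size_merging(self):
        dist, _, genes = planted_block_distance(12, within=0.9, between=0.1)
        # force k=3 on two-block data, then require min size 3: the stray
        # cluster must be folded back in
        mods = detect_modules(dist, genes, k=3, min_size=3)
        sizes = np.bincount(mods.labels)[1:]
        assert (sizes[sizes > 0] >= 3).all()

    def test_default_cut_runs_without_parameters(self):
        dist, _, genes = planted_block_distance(20)
        mods = detect_modules(dist, genes)
        assert 1 <= mods.k <= 20

    def test_k_larger_than_p_rejected(self):
        dist, _, genes = planted_block_distance(6)
        with pytest.raises(ValueError):
            detect_modules(dist, genes, k=7)

    def test_both_k_and_height_rejected(self):
        dist, _, genes = planted_block_distance(6)
        with pytest.raises(ValueError):
            detect_modules(dist, genes, k=2, cut_height=0.5)


class TestModuleEigengene:
    def test_single_gene_module_is_standardized_profile(self, rng):
        expr = pd.DataFrame(rng.normal(2, 3, (1, 10)), index=["a"])
        eg = module_eigengene(expr, ["a"])
        x = expr.loc["a"].to_numpy()
        ref = (x - x.mean()) / x.std(ddof=1)
        ref = ref / np.linalg.norm(ref)
        np.testing.assert_allclose(eg.vector, ref, atol=1e-12)
        assert eg.variance_explained == pytest.approx(1.0)

    def test_duplicated_genes_explain_all_variance(self, rng):
        profile = rng.normal(size=12)
        expr = pd.DataFrame([profile, profile, profile], index=["a", "b", "c"])
        eg = module_eigengene(expr, ["a", "b", "c"])
        assert eg.variance_explained == pytest.approx(1.0)
        assert np.linalg.norm(eg.vector) == pytest.approx(1.0)

    def test_rayleigh_quotient_optimality(self, rng):
        """The eigengene beats 1000 random unit vectors on explained variance."""
        expr = pd.DataFrame(rng.normal(size=(10, 15)), index=[f"g{i}" for i in range(10)])
        eg = module_eigengene(expr, list(expr.index))
        x = expr.to_numpy()
        xs = (x - x.mean(1, keepdims=True)) / x.std(1, ddof=1, keepdims=True)
        total = np.sum(xs**2)
        best = np.sum((xs @ eg.vector) ** 2) / total
        assert best == pytest.approx(eg.variance_explained)
        for v in rng.normal(size=(1000, 15)):
            v = v / np.linalg.norm(v)
            assert np.sum((xs @ v) ** 2) / total <= best + 1e-12

    def test_sign_aligned_with_mean_profile(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 12)), index=[f"g{i}" for i in range(5)])
        eg = module_eigengene(expr, list(expr.index))
        xs = expr.to_numpy()
        xs = (xs - xs.mean(1, keepdims=True)) / xs.std(1, ddof=1, keepdims=True)
        assert float(eg.vector @ xs.mean(0)) >= 0

    def test_constant_gene_dropped_with_warning(self, rng):
        expr = pd.DataFrame(
            np.vstack([rng.normal(size=(2, 8)), np.full(8, 3.0)]), index=["a", "b", "c"]
        )
        with pytest.warns(UserWarning):
            eg = module_eigengene(expr, ["a", "b", "c"])
        assert np.isfinite(eg.vector).all()

    def test_all_constant_module_rejected(self):
        expr = pd.DataFrame(np.full((2, 6), 1.0), index=["a", "b"])
        with pytest.raises(ValueError):
            module_eigengene(expr, ["a", "b"])


class TestEigengeneNetwork:
    def test_single_module_trivial_matrix(self, rng):
        paired = build_paired(rng.normal(size=(4, 10)), rng.normal(size=(4, 10)))
        from codc.modules import ModuleSet

        mods = ModuleSet(genes=paired.genes, labels=np.ones(4, dtype=int))
        rn, rt, comp = eigengene_network(mods, paired)
        assert comp.shape == (1, 1)
        assert comp.iloc[0, 0] == 1.0

    def test_duplicated_module_perfectly_correlated(self, rng):
        arr_n = rng.normal(size=(2, 10))
        arr_t = rng.normal(size=(2, 10))
        paired = build_paired(np.vstack([arr_n, arr_n]), np.vstack([arr_t, arr_t]))
        from codc.modules import ModuleSet

        mods = ModuleSet(genes=paired.genes, labels=np.array([1, 1, 2, 2]))
        rn, rt, _ = eigengene_network(mods, paired)
        assert abs(rn.iloc[0, 1]) == pytest.approx(1.0)
        assert abs(rt.iloc[0, 1]) == pytest.approx(1.0)

    def test_planted_sign_flip_appears_across_diagonal(self):
        """Two modules correlated +0.9 in normal, -0.9 in tumor."""
        n = 30
        a_n, b_n = correlated_pair(n, 0.9, seed=5)
        a_t, b_t = correlated_pair(n, -0.9, seed=6)
        # modules of 3 duplicated genes each share their eigengene direction
        normal = np.vstack([a_n, a_n, a_n, b_n, b_n, b_n])
        tumor = np.vstack([a_t, a_t, a_t, b_t, b_t, b_t])
        paired = build_paired(normal, tumor)
        from codc.modules import ModuleSet

        mods = ModuleSet(genes=paired.genes, labels=np.array([1, 1, 1, 2, 2, 2]))
        _, _, comp = eigengene_network(mods, paired)
        assert comp.iloc[0, 1] == pytest.approx(0.9, abs=1e-9)
        assert comp.iloc[1, 0] == pytest.approx(-0.9, abs=1e-9)

    def test_condition_matrices_positive_semidefinite(self, rng):
        paired = build_paired(rng.normal(size=(9, 14)), rng.normal(size=(9, 14)))
        from codc.modules import ModuleSet

        mods = ModuleSet(genes=paired.genes, labels=np.repeat([1, 2, 3], 3))
        rn, rt, _ = eigengene_network(mods, paired)
        for mat in (rn, rt):
            eig = np.linalg.eigvalsh(mat.to_numpy())
            assert eig.min() >= -1e-8
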