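import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stressnet as sn
from stressnet import coexpression as cx
from stressnet.coexpression import UNASSIGNED

from conftest import make_expression


def _planted_dataset(seed, cor=0.7, n_genes=600, n_modules=3, size=40):
    cfg0 = sn.SimConfig(n_genes=n_genes, seed=0)
    ids = cfg0.gene_universe()
    mods = tuple(
        sn.PlantedModule(f"m{k}", tuple(ids[size * k: size * (k + 1)]), cor,
                         (("F", cor), ("M", cor)))
        for k in range(n_modules))
    cfg = sn.SimConfig(n_genes=n_genes, n_per_cell=3,
                       genotypes=("XX_F", "XY_M"), regions=("BLA", "PFC"),
                       modules=mods, seed=seed)
    design = sn.generate_design(cfg)
    counts, truth = sn.simulate_counts(cfg, design)
    return sn.log_cpm(counts), design, truth


class TestAdjacency:
    def test_perfectly_correlated_pair_reaches_one(self):
        vals = np.vstack([np.arange(6.0), 2 * np.arange(6.0) + 1])
        expr = sn.ExpressionMatrix(["a", "b"], vals, [f"s{i}" for i in range(6)])
        adj = sn.adjacency(expr, beta=6)
        assert adj.weights[0, 1] == pytest.approx(1.0)

    def test_power_transform_arithmetic(self):
        # r = 0.5 exactly via constructed vectors
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, -1.0, -1.0, 1.0])
        vals = np.vstack([x + y, x])            # cor((x+y)/sqrt2, x) = 1/sqrt2
        expr = sn.ExpressionMatrix(["a", "b"], vals, list("wxyz"))
        adj = sn.adjacency(expr, beta=2, kind="unsigned")
        assert adj.weights[0, 1] == pytest.approx(0.5)   # (1/sqrt2)^2

    def test_beta_one_equals_absolute_correlation(self):
        expr = make_expression(20, 10, seed=1)
        adj = sn.adjacency(expr, beta=1)
        ref = np.abs(np.corrcoef(expr.values))
        assert np.allclose(adj.weights, ref, atol=1e-12)

    def test_zero_variance_gene_isolated(self):
        vals = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        expr = sn.ExpressionMatrix(["flat", "a", "b"], vals,
                                   [f"s{i}" for i in range(6)])
        adj = sn.adjacency(expr, beta=6)
        assert adj.weights[0, 1] == 0.0
        assert adj.weights[0, 2] == 0.0

    def test_too_few_samples_rejected(self):
        expr = make_expression(5, 3)
        with pytest.raises(ValueError, match="4 samples"):
            sn.adjacency(expr)

    def test_signed_adjacency_separates_anticorrelation(self):
        x = np.arange(8.0)
        expr = sn.ExpressionMatrix(["a", "b"], np.vstack([x, -x]),
                                   [f"s{i}" for i in range(8)])
        adj = sn.adjacency(expr, beta=2, kind="signed")
        assert adj.weights[0, 1] == pytest.approx(0.0)


class TestPickSoftThreshold:
    def test_single_candidate_chosen(self):
        expr = make_expression(30, 10)
        beta, table = sn.pick_soft_threshold(expr, candidate_betas=(4,))
        assert beta == 4.0
        assert len(table) == 1

    def test_modular_structure_reaches_scale_free_fit(self):
        expr, _, _ = _planted_dataset(seed=31, cor=0.8, n_genes=500,
                                      n_modules=4, size=60)
        beta, table = sn.pick_soft_threshold(expr)
        assert table.loc[table["beta"] == beta, "r2_signed"].iloc[0] >= 0.8

    def test_noise_returns_full_table_with_fallback(self):
        expr = make_expression(120, 10, seed=3)
        beta, table = sn.pick_soft_threshold(expr, candidate_betas=(1, 2, 3))
        assert len(table) == 3
        assert beta in {1.0, 2.0, 3.0}


class TestTopologicalOverlap:
    def _brute_force(self, a):
        n = a.shape[0]
        b = a.copy()
        np.fill_diagonal(b, 0.0)
        k = b.sum(axis=1)
        tom = np.ones((n, n))
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                shared = sum(b[i, u] * b[u, j] for u in range(n)
                             if u != i and u != j)
                tom[i, j] = (shared + b[i, j]) / (min(k[i], k[j]) + 1 - b[i, j])
        return tom

    def test_matches_brute_force_triple_loop(self):
        rng = np.random.default_rng(7)
        a = rng.uniform(0, 1, (10, 10))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = cx.AdjacencyMatrix(np.array([f"g{i}" for i in range(10)],
                                          dtype=object), a, beta=6)
        assert np.allclose(sn.topological_overlap(adj), self._brute_force(a),
                           atol=1e-12)

    def test_exclusive_pair_reaches_one(self):
        a = np.eye(4)
        a[0, 1] = a[1, 0] = 1.0
        adj = cx.AdjacencyMatrix(np.array(list("abcd"), dtype=object), a, 1)
        tom = sn.topological_overlap(adj)
        assert tom[0, 1] == pytest.approx(1.0)

    def test_disconnected_pair_is_zero(self):
        a = np.eye(4)
        a[2, 3] = a[3, 2] = 0.9
        adj = cx.AdjacencyMatrix(np.array(list("abcd"), dtype=object), a, 1)
        tom = sn.topological_overlap(adj)
        assert tom[0, 1] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(0, 10_000), n=st.integers(3, 15))
    def test_tom_stays_in_unit_interval(self, seed, n):
        rng = np.random.default_rng(seed)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = cx.AdjacencyMatrix(
            np.array([f"g{i}" for i in range(n)], dtype=object), a, 1)
        tom = sn.topological_overlap(adj)
        assert np.all(tom >= -1e-12)
        assert np.all(tom <= 1.0 + 1e-12)


class TestDetectModules:
    def test_planted_modules_recovered(self):
        expr, _, truth = _planted_dataset(seed=33)
        tom = sn.topological_overlap(sn.adjacency(expr, beta=6))
        ms = sn.detect_modules(tom, expr.gene_ids, min_size=30)
        found = ms.modules()
        assert len(found) == 3
        # each planted module maps onto one detected label nearly intact
        for name in ("m0", "m1", "m2"):
            planted = {g for g, m in truth.module_assignment.items()
                       if m == name}
            best = max(found.values(),
                       key=lambda genes: len(planted & set(genes)))
            assert len(planted & set(best)) / len(planted) >= 0.8

    def test_all_noise_goes_grey(self):
        expr = make_expression(400, 24, seed=5)
        tom = sn.topological_overlap(sn.adjacency(expr, beta=6))
        ms = sn.detect_modules(tom, expr.gene_ids, min_size=30)
        assert (ms.labels == UNASSIGNED).mean() >= 0.95

    def test_cut_at_root_merges_everything(self):
        expr, _, _ = _planted_dataset(seed=35, n_genes=200, n_modules=2)
        tom = sn.topological_overlap(sn.adjacency(expr, beta=6))
        ms = sn.detect_modules(tom, expr.gene_ids, min_size=30,
                               cut_height=1.0)
        assert len(ms.modules()) == 1
        assert (ms.labels != UNASSIGNED).all()

    def test_gene_order_invariance(self):
        expr, _, _ = _planted_dataset(seed=37, n_genes=300, n_modules=2)
        tom = sn.topological_overlap(sn.adjacency(expr, beta=6))
        ms1 = sn.detect_modules(tom, expr.gene_ids, min_size=30)
        rng = np.random.default_rng(0)
        perm = rng.permutation(expr.n_genes)
        ms2 = sn.detect_modules(tom[np.ix_(perm, perm)],
                                expr.gene_ids[perm], min_size=30)
        a1 = ms1.assignment()
        a2 = ms2.assignment()
        # same partition up to label names
        from collections import defaultdict
        parts1 = defaultdict(set)
        parts2 = defaultdict(set)
        for g in expr.gene_ids:
            parts1[a1[g]].add(g)
            parts2[a2[g]].add(g)
        assert {frozenset(v) for v in parts1.values()} == \
            {frozenset(v) for v in parts2.values()}


class TestModulePreservation:
    def test_planted_module_highly_self_preserved(self):
        expr, design, truth = _planted_dataset(seed=39, n_genes=500,
                                               n_modules=1, size=50)
        labels = np.array([truth.module_assignment.get(g, UNASSIGNED)
                           for g in expr.gene_ids], dtype=object)
        ms = cx.ModuleSet(expr.gene_ids, labels)
        pres = sn.module_preservation(ms, expr, expr, n_perm=100, seed=0)
        assert pres.table["Z_summary"].iloc[0] > 10

    def test_random_gene_set_not_preserved(self):
        expr = make_expression(400, 24, seed=9)
        labels = np.full(400, UNASSIGNED, dtype=object)
        labels[:40] = "fake"
        ms = cx.ModuleSet(expr.gene_ids, labels)
        pres = sn.module_preservation(ms, expr, expr, n_perm=100, seed=1)
        assert abs(pres.table["Z_summary"].iloc[0]) < 3

    def test_preservation_increases_with_planted_correlation(self):
        zs = {}
        for cor in (0.3, 0.5, 0.7):
            vals = []
            for seed in (41, 42):
                expr, design, truth = _planted_dataset(
                    seed=seed, cor=cor, n_genes=300, n_modules=1, size=40)
                labels = np.array(
                    [truth.module_assignment.get(g, UNASSIGNED)
                     for g in expr.gene_ids], dtype=object)
                ms = cx.ModuleSet(expr.gene_ids, labels)
                stress_ids = design.loc[design["stress"] == "stress",
                                        "sample_id"]
                ctrl_ids = design.loc[design["stress"] == "ctrl", "sample_id"]
                pres = sn.module_preservation(
                    ms, expr.subset_samples(stress_ids),
                    expr.subset_samples(ctrl_ids), n_perm=100, seed=0)
                vals.append(pres.table["Z_summary"].iloc[0])
            zs[cor] = np.mean(vals)
        assert zs[0.3] < zs[0.5] < zs[0.7]

    def test_too_few_permutations_rejected(self):
        expr = make_expression(50, 12)
        labels = np.full(50, UNASSIGNED, dtype=object)
        labels[:10] = "m"
        ms = cx.ModuleSet(expr.gene_ids, labels)
        with pytest.raises(ValueError, match="50"):
            sn.module_preservation(ms, expr, expr, n_perm=10)
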