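import numpy as np
import pandas as pd
import pytest

import stressnet as sn
from stressnet.diffexpr import Contrast, _moments_prior


def _toy_result(p, fc, genes=None):
    genes = genes or [f"g{i}" for i in range(len(p))]
    p = np.asarray(p, dtype=float)
    fc = np.asarray(fc, dtype=float)
    return pd.DataFrame({
        "log2fc": np.log2(fc), "fold_change": fc, "t": np.ones_like(p),
        "p": p, "q": p, "direction": np.ones_like(p),
    }, index=pd.Index(genes, name="gene"))


class TestDeTest:
    def _paired_expr(self, seed=0, n_genes=50):
        rng = np.random.default_rng(seed)
        vals = rng.standard_normal((n_genes, 4))
        vals = np.hstack([vals, vals])          # group b duplicates group a
        design = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(8)],
            "genotype": ["XX_F"] * 4 + ["XY_M"] * 4,
            "stress": ["ctrl"] * 8,
            "region": ["BLA"] * 8,
        })
        expr = sn.ExpressionMatrix([f"g{i}" for i in range(n_genes)], vals,
                                   design["sample_id"].tolist())
        return expr, sn.validate_design(design)

    def test_identical_groups_give_zero_fold_change(self):
        expr, design = self._paired_expr()
        con = Contrast("c", (("genotype", "XX_F"),), (("genotype", "XY_M"),))
        res = sn.de_test(expr, design, con)
        assert np.allclose(res["log2fc"], 0.0)
        assert np.allclose(res["fold_change"], 1.0)

    def test_single_sample_group_rejected(self):
        expr, design = self._paired_expr()
        design = design.iloc[:5]                # one XY_M sample left
        expr = expr.subset_samples(design["sample_id"])
        con = Contrast("c", (("genotype", "XX_F"),), (("genotype", "XY_M"),))
        with pytest.raises(ValueError, match="2 samples"):
            sn.de_test(expr, design, con)

    def test_overlapping_groups_rejected(self):
        expr, design = self._paired_expr()
        con = Contrast("c", (("stress", "ctrl"),), (("genotype", "XY_M"),))
        with pytest.raises(ValueError, match="overlap"):
            sn.de_test(expr, design, con)

    @pytest.mark.parametrize("moderated", [False, True])
    def test_null_calibration(self, moderated):
        cfg = sn.SimConfig(n_genes=4000, n_per_cell=9,
                           genotypes=("XX_F", "XY_M"), regions=("BLA",),
                           seed=13)
        design = sn.generate_design(cfg)
        counts, _ = sn.simulate_counts(cfg, design)
        expr = sn.log_cpm(counts)
        con = Contrast("null", (("genotype", "XX_F"),),
                       (("genotype", "XY_M"),), (("stress", "ctrl"),))
        res = sn.de_test(expr, design, con, moderated=moderated)
        assert 0.03 <= (res["p"] < 0.05).mean() <= 0.07

    def test_planted_effect_recovered(self):
        cfg = sn.SimConfig(n_genes=4000, n_per_cell=9,
                           genotypes=("XX_F", "XY_M"), regions=("BLA",),
                           de_frac_gonadal=0.025, sex_effect_size=1.0,
                           seed=17)
        design = sn.generate_design(cfg)
        counts, truth = sn.simulate_counts(cfg, design)
        expr = sn.log_cpm(counts)
        con = Contrast("sex", (("genotype", "XX_F"),),
                       (("genotype", "XY_M"),), (("stress", "ctrl"),))
        res = sn.de_test(expr, design, con)
        planted = truth.de_genes_by_contrast["gonadal_F_vs_M"]
        est = np.array([res.loc[g, "log2fc"] * np.sign(e)
                        for g, e in planted.items()])
        assert est.mean() == pytest.approx(1.0, abs=0.1)

    def test_moments_prior_recovers_infinite_d0_for_constant_variances(self):
        d0, s02 = _moments_prior(np.full(100, 2.0), df=16)
        assert np.isinf(d0)
        assert s02 == pytest.approx(2.0)

    def test_bh_q_monotone_in_p(self):
        rng = np.random.default_rng(23)
        expr, design = self._paired_expr(seed=2, n_genes=80)
        expr = sn.ExpressionMatrix(expr.gene_ids,
                                   rng.standard_normal(expr.values.shape),
                                   expr.sample_ids)
        con = Contrast("c", (("genotype", "XX_F"),), (("genotype", "XY_M"),))
        res = sn.de_test(expr, design, con).sort_values("p")
        assert (np.diff(res["q"]) >= -1e-12).all()


class TestCallDe:
    @pytest.mark.parametrize("p,fc,included", [
        (0.04, 1.4, True),     # passes both strict thresholds
        (0.04, 1.3, False),    # fold change exactly at the boundary
        (0.06, 3.0, False),    # p too large no matter the effect
        (0.05, 1.4, False),    # p exactly at the boundary
    ])
    def test_strict_rule(self, p, fc, included):
        res = _toy_result([p], [fc])
        called = sn.call_de(res)
        assert (len(called) == 1) is included

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        res = _toy_result(rng.uniform(0, 1, 200), rng.uniform(1, 3, 200))
        tight = set(sn.call_de(res, 0.01, 1.5).index)
        loose = set(sn.call_de(res, 0.10, 1.2).index)
        assert tight <= loose


class TestAttribution:
    def test_pure_gonadal_attribution(self):
        sex = pd.Series([1, -1, 1], index=["a", "b", "c"])
        gon = pd.Series([1, -1, 1], index=["a", "b", "c"])
        gen = pd.Series(dtype=float)
        venn = sn.attribute_sex_differences(sex, gon, gen)
        assert venn.pct_gonadal == 100.0
        assert venn.pct_genetic == 0.0

    def test_disjoint_sets_have_empty_overlaps(self):
        sex = pd.Series([1], index=["a"])
        gon = pd.Series([1], index=["b"])
        gen = pd.Series([1], index=["c"])
        venn = sn.attribute_sex_differences(sex, gon, gen)
        assert venn.region_counts["sex&gonadal"] == 0
        assert venn.region_counts["sex&genetic"] == 0
        assert venn.region_counts["sex&gonadal&genetic"] == 0
        assert venn.pct_gonadal == 0.0

    def test_direction_mismatch_excluded_when_required(self):
        sex = pd.Series([1, 1], index=["a", "b"])
        gon = pd.Series([1, -1], index=["a", "b"])
        gen = pd.Series(dtype=float)
        strict = sn.attribute_sex_differences(sex, gon, gen, True)
        loose = sn.attribute_sex_differences(sex, gon, gen, False)
        assert strict.pct_gonadal == 50.0
        assert loose.pct_gonadal == 100.0

    def test_venn_regions_sum_to_union(self):
        rng = np.random.default_rng(11)
        universe = [f"g{i}" for i in range(50)]
        sets = [pd.Series(1.0, index=rng.choice(universe, rng.integers(5, 30),
                                                replace=False))
                for _ in range(3)]
        venn = sn.attribute_sex_differences(*sets)
        union = set().union(*(s.index for s in sets))
        assert sum(venn.region_counts.values()) == len(union)

    def test_synthetic_gonadal_only_planting_attributed_gonadal(self):
        # strong, abundant planted effects so the called set is dominated by
        # true positives rather than the DE rule's raw-p false positives
        cfg = sn.SimConfig(n_genes=2000, n_per_cell=18, regions=("BLA",),
                           de_frac_gonadal=0.3, sex_effect_size=2.0, seed=29)
        design = sn.generate_design(cfg)
        counts, truth = sn.simulate_counts(cfg, design)
        expr = sn.log_cpm(counts)
        from stressnet.pipeline import default_contrasts
        called = {}
        for con in default_contrasts(["BLA"])[:3]:
            called[con.name] = sn.call_de(sn.de_test(expr, design, con))
        venn = sn.attribute_sex_differences(called["sex_XXF_vs_XYM"],
                                            called["gonadal_F_vs_M"],
                                            called["genetic_XX_vs_XY"])
        assert venn.pct_gonadal >= 90.0


class TestStressOverlap:
    def test_identical_sets(self):
        out = sn.stress_overlap(["a", "b"], ["a", "b"])
        assert out["jaccard"] == 1.0
        assert out["pct_of_a"] == 100.0

    def test_disjoint_sets(self):
        out = sn.stress_overlap(["a"], ["b"])
        assert out["n_intersection"] == 0
        assert out["jaccard"] == 0.0

    def test_hand_enumerated_overlap(self):
        a = [f"g{i}" for i in range(1, 11)]
        b = [f"g{i}" for i in range(6, 16)]
        out = sn.stress_overlap(a, b)
        assert out["n_intersection"] == 5
        assert out["jaccard"] == pytest.approx(1 / 3)
        assert out["pct_of_a"] == 50.0
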