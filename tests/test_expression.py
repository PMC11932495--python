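import warnings

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from comarker.expression import (
    CASE,
    CONTROL,
    ConfigurationError,
    DataError,
    ExpressionStudy,
    call_degs,
    compute_alog2fc,
    detect_modules,
    filter_significant_modules,
    pick_soft_threshold,
    scale_free_fit_r2,
    topological_overlap,
)
from conftest import make_study


class TestALog2FC:
    def test_linear_scale_hand_example(self):
        # case mean log2 = 3, control mean log2 = 1
        study = make_study([[8, 8]], [[2, 2]], scale="linear")
        assert compute_alog2fc(study).iloc[0] == pytest.approx(2.0)

    def test_unequal_group_sizes(self):
        # mean log2(case) = 2, mean log2(control) = (2+4+2+4)/4 = 3
        study = make_study([[4, 4]], [[4, 16, 4, 16]], scale="linear")
        assert compute_alog2fc(study).iloc[0] == pytest.approx(-1.0)

    def test_identical_groups_give_zero(self):
        study = make_study([[5.0, 6.0, 7.0]], [[5.0, 6.0, 7.0]])
        assert compute_alog2fc(study).iloc[0] == pytest.approx(0.0)

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(8, 1, size=(20, 10))
        study = make_study(x[:, :5], x[:, 5:])
        shuffled = ExpressionStudy(
            disease_id="demo",
            values=study.values.iloc[:, ::-1],
            sample_groups=study.sample_groups.iloc[::-1],
        )
        pd.testing.assert_series_equal(compute_alog2fc(study), compute_alog2fc(shuffled))

    def test_label_swap_negates_fold_changes(self):
        rng = np.random.default_rng(1)
        x = rng.normal(8, 1, size=(30, 12))
        study = make_study(x[:, :6], x[:, 6:])
        flipped_groups = study.sample_groups.map({CASE: CONTROL, CONTROL: CASE})
        flipped = ExpressionStudy("demo", study.values, flipped_groups)
        np.testing.assert_allclose(compute_alog2fc(study), -compute_alog2fc(flipped))

    def test_nonpositive_linear_value_identifies_gene_and_sample(self):
        study = make_study([[2.0, 2.0]], [[2.0, 2.0]], scale="linear")
        study.values.iloc[0, 1] = -1.0
        with pytest.raises(DataError, match="g0.*case1"):
            compute_alog2fc(study)

    def test_group_size_invariant(self):
        with pytest.raises(DataError, match=">= 2 case"):
            make_study([[1.0]], [[1.0, 2.0]])


class TestSoftThreshold:
    def test_preferential_attachment_degrees_fit_power_law(self):
        g = nx.barabasi_albert_graph(2000, 2, seed=1)
        k = np.array([d for _, d in g.degree], dtype=float)
        assert scale_free_fit_r2(k) >= 0.9

    def test_mean_connectivity_decreases_with_beta(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, 30))
        study = make_study(x[:, :15], x[:, 15:])
        result = pick_soft_threshold(study, candidate_betas=[1, 3, 6, 9, 12])
        means = [result.mean_connectivity[b] for b in [1, 3, 6, 9, 12]]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_single_candidate_is_returned_with_warning_flag(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(60, 20))
        study = make_study(x[:, :10], x[:, 10:])
        result = pick_soft_threshold(study, candidate_betas=[1], r2_cutoff=0.999)
        assert result.beta == 1
        assert result.warning


class TestTOM:
    def test_bounds_symmetry_and_diagonal(self):
        rng = np.random.default_rng(4)
        a = np.abs(rng.normal(size=(40, 40)))
        a = (a + a.T) / 2
        a = a / a.max()
        tom = topological_overlap(a)
        assert np.allclose(tom, tom.T)
        assert (tom >= 0).all() and (tom <= 1).all()
        assert np.allclose(np.diag(tom), 1.0)

    def test_identical_neighborhood_full_adjacency_pair_scores_one(self):
        # 3 genes all fully adjacent: shared neighbor + direct link saturate
        a = np.ones((3, 3))
        tom = topological_overlap(a)
        assert tom[0, 1] == pytest.approx(1.0)


class TestModuleDetection:
    @staticmethod
    def _two_block_study(seed=7, n_samples=40):
        rng = np.random.default_rng(seed)

        def block(size, rho):
            f = rng.normal(size=n_samples)
            return np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * rng.normal(
                size=(size, n_samples)
            )

        x = np.vstack(
            [block(50, 0.8), block(40, 0.8), rng.normal(size=(200, n_samples))]
        ) + 8.0
        return make_study(x[:, : n_samples // 2], x[:, n_samples // 2 :]), (50, 40)

    def test_planted_blocks_recovered_and_noise_unassigned(self):
        study, (s1, s2) = self._two_block_study()
        result = detect_modules(study, beta=6, min_module_size=30)
        sizes = sorted(
            (len(result.module_genes(m)) for m in result.module_labels), reverse=True
        )
        assert len(sizes) == 2
        assert abs(sizes[0] - s1) <= 0.1 * s1
        assert abs(sizes[1] - s2) <= 0.1 * s2
        block1 = {f"g{i}" for i in range(50)}
        m1 = set(result.module_genes("M1"))
        assert len(m1 & block1) >= 0.9 * len(block1)
        n_unassigned = (result.module_assignment == "unassigned").sum()
        assert n_unassigned >= 0.9 * 200

    def test_zero_merge_height_never_reduces_module_count(self):
        study, _ = self._two_block_study(seed=8)
        strict = detect_modules(study, beta=6, min_module_size=30, merge_cut_height=0.0)
        merged = detect_modules(study, beta=6, min_module_size=30, merge_cut_height=1.2)
        assert len(strict.module_labels) >= len(merged.module_labels)

    def test_too_few_genes_yields_all_unassigned_with_warning(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=(10, 12))
        study = make_study(x[:, :6], x[:, 6:])
        with pytest.warns(UserWarning, match="unassigned"):
            result = detect_modules(study, beta=2, min_module_size=30)
        assert (result.module_assignment == "unassigned").all()


class TestModuleFilter:
    def test_trait_aligned_eigengene_is_retained(self):
        study, _ = TestModuleDetection._two_block_study(seed=10)
        result = detect_modules(study, beta=6, min_module_size=30)
        trait = result.eigengenes["M1"].to_numpy().copy()  # perfectly aligned trait
        filt = filter_significant_modules(result, trait)
        assert "M1" in filt.significant_modules
        assert filt.module_trait["M1"][0] == pytest.approx(1.0)

    def test_vacuous_thresholds_retain_all_module_genes(self):
        study, _ = TestModuleDetection._two_block_study(seed=12)
        result = detect_modules(study, beta=6, min_module_size=30)
        trait = study.trait_vector()
        filt = filter_significant_modules(result, trait, r_threshold=0.0, p_threshold=1.1)
        assigned = set(
            result.module_assignment.index[result.module_assignment != "unassigned"]
        )
        assert filt.retained_genes == assigned

    def test_constant_trait_is_rejected(self):
        study, _ = TestModuleDetection._two_block_study(seed=13)
        result = detect_modules(study, beta=6, min_module_size=30)
        with pytest.raises(DataError, match="variance"):
            filter_significant_modules(result, np.ones(40))


class TestCallDegs:
    def test_threshold_is_strict_and_filter_takes_precedence(self):
        fc = pd.Series({"a": 1.0, "b": 2.5, "c": -1.5, "d": 0.2})
        table = call_degs(fc, retained_genes={"a", "c", "d"})
        assert table.table.loc["a", "direction"] == "NS"  # exactly 1.0 is not > 1
        assert table.table.loc["b", "direction"] == "NS"  # not retained by filter
        assert table.table.loc["c", "direction"] == "DR"
        assert table.table.loc["d", "direction"] == "NS"

    def test_invalid_thresholds_rejected(self):
        fc = pd.Series({"a": 0.0})
        with pytest.raises(ConfigurationError):
            call_degs(fc, retained_genes=set(), up_threshold=-1.0, down_threshold=1.0)
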