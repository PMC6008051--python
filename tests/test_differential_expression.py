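"""ANOVA/BH differential expression against brute-force and scipy oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from muscletx import (
    anova_de,
    bh_qvalues,
    call_expressed,
    de_fraction_matrix,
    de_threshold_sweep,
    pairwise_de,
    venn_core_sets,
)
from muscletx.data_model import DataModelError
from muscletx.differential_expression import _anova_arrays


def bh_brute_force(p):
    """Independent oracle: q_(i) = min_{j>=i} p_(j)*m/j on sorted p, by loops."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order):
        best = np.inf
        for j in range(rank_pos, m):
            best = min(best, p[order[j]] * m / (j + 1))
        q[idx] = min(best, 1.0)
    return q


def _meta(tissues, reps):
    cols = [f"{t}_r{i}" for t in tissues for i in range(1, reps + 1)]
    return pd.DataFrame(
        {"tissue": [c.rsplit("_", 1)[0] for c in cols]},
        index=pd.Index(cols, name="sample_id"),
    )


def _expr(rows: dict, tissues, reps):
    meta = _meta(tissues, reps)
    mat = pd.DataFrame(rows, index=meta.index).T
    return mat, meta


class TestBhQvalues:
    def test_hand_example_all_collapse(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04], atol=0)

    def test_single_p(self):
        assert bh_qvalues([1.0]) == pytest.approx([1.0])

    def test_matches_brute_force_exactly_on_random_vectors(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            p = rng.random(n)
            assert np.array_equal(bh_qvalues(p), bh_brute_force(p))

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(0)
        p = rng.random(20)
        perm = rng.permutation(20)
        assert np.array_equal(bh_qvalues(p)[perm], bh_qvalues(p[perm]))

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        p = rng.random(500)
        _, q_sm, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(bh_qvalues(p), q_sm, atol=1e-12)

    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    @settings(deadline=None)
    def test_property_equals_brute_force(self, p):
        assert np.array_equal(bh_qvalues(p), bh_brute_force(p))

    def test_out_of_range_rejected(self):
        with pytest.raises(DataModelError):
            bh_qvalues([0.5, 1.5])


class TestAnovaCore:
    def test_worked_f_statistic(self):
        values = np.array([[1, 2, 3, 2, 3, 4, 3, 4, 5]], dtype=float)
        groups = [np.array([0, 1, 2]), np.array([3, 4, 5]), np.array([6, 7, 8])]
        F, p = _anova_arrays(values, groups)
        assert F[0] == pytest.approx(3.0, abs=1e-9)
        # independent F-distribution oracle
        f_or, p_or = stats.f_oneway([1, 2, 3], [2, 3, 4], [3, 4, 5])
        assert p[0] == pytest.approx(p_or, rel=1e-10)

    def test_all_identical_groups_tie_rule(self):
        values = np.full((1, 9), 2.5)
        groups = [np.arange(0, 3), np.arange(3, 6), np.arange(6, 9)]
        F, p = _anova_arrays(values, groups)
        assert F[0] == 0.0 and p[0] == 1.0

    def test_signal_with_zero_within_variance(self):
        values = np.array([[1, 1, 1, 2, 2, 2]], dtype=float)
        groups = [np.arange(0, 3), np.arange(3, 6)]
        F, p = _anova_arrays(values, groups)
        assert np.isinf(F[0]) and p[0] == 1e-300

    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b = rng.normal(size=6), rng.normal(size=5) + rng.normal()
            values = np.concatenate([a, b])[None, :]
            groups = [np.arange(6), np.arange(6, 11)]
            F, p = _anova_arrays(values, groups)
            t, pt = stats.ttest_ind(a, b, equal_var=True)
            assert F[0] == pytest.approx(t**2, rel=1e-10)
            assert p[0] == pytest.approx(pt, rel=1e-8)

    def test_matches_scipy_f_oneway_vectorized(self):
        rng = np.random.default_rng(3)
        values = rng.normal(size=(50, 12))
        groups = [np.arange(0, 4), np.arange(4, 8), np.arange(8, 12)]
        F, p = _anova_arrays(values, groups)
        for i in range(50):
            f_or, p_or = stats.f_oneway(*[values[i, g] for g in groups])
            assert F[i] == pytest.approx(f_or, rel=1e-10)
            assert p[i] == pytest.approx(p_or, rel=1e-8)


class TestExpressedAndVenn:
    def test_expressed_strict_threshold(self):
        fpkm, meta = _expr({"T": [0.5, 0.5, 1.5, 1.5]}, ["a", "b"], 2)
        calls = call_expressed(fpkm, meta, threshold=1.0)
        assert not calls.per_tissue.loc["T", "a"]
        assert calls.per_tissue.loc["T", "b"]
        assert calls.any_tissue.loc["T"] and not calls.all_tissue.loc["T"]

    def test_threshold_zero_boundary_is_strict(self):
        fpkm, meta = _expr({"T": [0.0, 0.0, 0.4, 0.4]}, ["a", "b"], 2)
        calls = call_expressed(fpkm, meta, threshold=0.0)
        assert not calls.per_tissue.loc["T", "a"]
        assert calls.per_tissue.loc["T", "b"]

    def test_venn_regions_by_set_logic(self):
        tissues = ["sk1", "sk2", "ca1", "sm1"]
        class_map = {"sk1": "skeletal", "sk2": "skeletal", "ca1": "cardiac", "sm1": "smooth"}
        rows = {
            "ALL": [5, 5, 5, 5],        # expressed everywhere -> core
            "SKEL": [5, 5, 0, 0],       # skeletal-only
            "PART": [5, 0, 5, 5],       # misses one skeletal tissue
            "NONE": [0, 0, 0, 0],
        }
        fpkm = pd.DataFrame(rows, index=[f"{t}_r1" for t in tissues]).T
        meta = pd.DataFrame({"tissue": tissues},
                            index=pd.Index([f"{t}_r1" for t in tissues], name="sample_id"))
        regions = venn_core_sets(call_expressed(fpkm, meta), class_map)
        assert regions["all_three"] == 1 == regions["core"]
        assert regions["skeletal_only"] == 1
        assert regions["cardiac_smooth"] == 1  # PART: every cardiac + every smooth
        assert regions["smooth_only"] == 0

    def test_empty_class_rejected(self):
        fpkm, meta = _expr({"T": [5, 5, 5, 5]}, ["a", "b"], 2)
        with pytest.raises(DataModelError):
            venn_core_sets(call_expressed(fpkm, meta), {"a": "skeletal", "b": "skeletal"})


class TestPairwiseAndSummaries:
    def _toy(self, seed=0, shift=0.0):
        rng = np.random.default_rng(seed)
        tissues = ["a", "b"]
        meta = _meta(tissues, 6)
        fpkm = pd.DataFrame(
            rng.lognormal(3, 0.1, size=(30, 12)), columns=meta.index,
            index=[f"T{i}" for i in range(30)],
        )
        fpkm.iloc[0, 6:] *= 2.0**shift
        log_expr = np.log2(fpkm + 1)
        return log_expr, fpkm, meta

    def test_identical_tissues_nothing_significant(self):
        log_expr, fpkm, meta = self._toy()
        fpkm["b_r" + "1"] = fpkm["a_r1"]
        de = pairwise_de(log_expr, fpkm, meta, "a", "b")
        assert de["significant"].sum() == 0

    def test_planted_fold_change_detected_and_signed(self):
        log_expr, fpkm, meta = self._toy(seed=1, shift=2.0)
        de = pairwise_de(log_expr, fpkm, meta, "a", "b")
        assert bool(de.loc["T0", "significant"])
        assert de.loc["T0", "direction"] == -1  # shifted up in b
        assert de.loc["T0", "log2_fc"] == pytest.approx(-2.0, abs=0.3)

    def test_fraction_matrix_symmetric_zero_diagonal(self):
        log_expr, fpkm, meta = self._toy(seed=2, shift=3.0)
        mat = de_fraction_matrix(log_expr, fpkm, meta)
        assert np.allclose(mat.values, mat.values.T)
        assert np.all(np.diag(mat.values) == 0.0)

    def test_threshold_sweep_monotone_and_boundary(self):
        log_expr, fpkm, meta = self._toy(seed=3, shift=3.0)
        sweep = de_threshold_sweep(
            log_expr, fpkm, meta, {"pair": ["a", "b"]}, q_grid=[0.001, 0.01, 0.1, 1.0]
        )
        col = sweep["pair"].to_numpy()
        assert np.all(np.diff(col) >= 0)
        # q = 1 counts every transcript passing the FC filter
        de = pairwise_de(log_expr, fpkm, meta, "a", "b", q_thresh=1.0)
        expected = 100.0 * (de["fold_change"] > 2.0).mean()
        assert col[-1] == pytest.approx(expected)

    def test_single_tissue_subset_rejected(self):
        log_expr, fpkm, meta = self._toy()
        with pytest.raises(DataModelError):
            anova_de(log_expr, fpkm, meta, ["a"])
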