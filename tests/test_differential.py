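import numpy as np
import pandas as pd
import pytest
from scipy import stats

import stratade as st
from stratade.differential import _pooled_d

from conftest import make_expression, make_metadata


@pytest.fixture
def two_group_expr():
    rng = np.random.default_rng(0)
    return make_expression(rng.normal(7, 1, (300, 10)))


GROUP_A = [f"s{i}" for i in range(5)]
GROUP_B = [f"s{i}" for i in range(5, 10)]


class TestSamDStatistics:
    def test_hand_computed_pooled_t(self):
        # A=(1,2,3), B=(3,4,5): diff=2, pooled var=1, s=sqrt(2/3)
        x = make_expression([[1, 2, 3, 3, 4, 5]])
        d, s = st.sam_d_statistics(x, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert d[0] == pytest.approx(2 / np.sqrt(2 / 3), abs=1e-12)
        assert round(float(d[0]), 3) == 2.449
        assert s[0] == pytest.approx(np.sqrt(2 / 3))

    def test_identical_group_means_give_zero(self):
        x = make_expression([[1.0, 2.0, 3.0, 3.0, 2.0, 1.0]])
        d, _ = st.sam_d_statistics(x, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert d[0] == pytest.approx(0.0, abs=1e-12)

    def test_swap_negates_d(self, two_group_expr):
        d1, _ = st.sam_d_statistics(two_group_expr, GROUP_A, GROUP_B)
        d2, _ = st.sam_d_statistics(two_group_expr, GROUP_B, GROUP_A)
        np.testing.assert_allclose(d1, -d2, atol=1e-10)

    def test_matches_pooled_t_at_s0_zero(self, two_group_expr):
        d, _ = st.sam_d_statistics(two_group_expr, GROUP_A, GROUP_B)
        a = two_group_expr.values[GROUP_A].to_numpy()
        b = two_group_expr.values[GROUP_B].to_numpy()
        t = stats.ttest_ind(b, a, axis=1).statistic
        np.testing.assert_allclose(d, t, atol=1e-10)

    def test_zero_variance_probe_defined_as_zero(self):
        x = make_expression([[5.0, 5.0, 5.0, 5.0, 5.0, 5.0]])
        d, _ = st.sam_d_statistics(x, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert d[0] == 0.0 and np.isfinite(d[0])

    def test_global_location_shift_leaves_d_unchanged(self, two_group_expr):
        d1, _ = st.sam_d_statistics(two_group_expr, GROUP_A, GROUP_B)
        shifted = make_expression(two_group_expr.values.to_numpy() + 3.7)
        d2, _ = st.sam_d_statistics(shifted, GROUP_A, GROUP_B)
        np.testing.assert_allclose(d1, d2, atol=1e-9)

    def test_s0_monotonically_shrinks_abs_d(self, two_group_expr):
        prev = np.abs(st.sam_d_statistics(two_group_expr, GROUP_A, GROUP_B)[0])
        for s0 in (0.1, 0.5, 2.0):
            cur = np.abs(
                st.sam_d_statistics(two_group_expr, GROUP_A, GROUP_B, s0=s0)[0]
            )
            assert np.all(cur <= prev + 1e-12)
            prev = cur

    def test_rejects_small_groups(self, two_group_expr):
        with pytest.raises(ValueError, match="at least 2"):
            st.sam_d_statistics(two_group_expr, ["s0"], GROUP_B)


class TestSelectS0:
    def test_equal_s_degenerate(self):
        # two probes with identical spread so every percentile coincides
        x = make_expression([[0, 1, 2, 0, 1, 2], [5, 6, 7, 5, 6, 7]] * 60)
        s0 = st.select_s0(x, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        _, s = st.sam_d_statistics(x, ["s0", "s1", "s2"], ["s3", "s4", "s5"])
        assert s0 == pytest.approx(s[0])

    def test_probe_reordering_invariance(self, two_group_expr):
        s0 = st.select_s0(two_group_expr, GROUP_A, GROUP_B)
        rng = np.random.default_rng(1)
        perm = rng.permutation(two_group_expr.n_probes)
        shuffled = make_expression(
            two_group_expr.values.to_numpy()[perm],
            probe_ids=[f"q{i}" for i in range(two_group_expr.n_probes)],
        )
        assert st.select_s0(shuffled, GROUP_A, GROUP_B) == pytest.approx(s0)

    def test_cv_criterion_beats_extremes(self, two_group_expr):
        """Chosen s0's CV <= CV at the 0th and 100th percentile of s."""
        d0, s = st.sam_d_statistics(two_group_expr, GROUP_A, GROUP_B)
        r = d0 * s
        order = np.argsort(s, kind="stable")
        windows = np.array_split(order, max(2, len(s) // 10))

        def cv(s0):
            d = r / (s + s0)
            spreads = np.array([
                stats.median_abs_deviation(d[w], scale="normal")
                for w in windows
            ])
            return spreads.std() / spreads.mean()

        chosen = st.select_s0(two_group_expr, GROUP_A, GROUP_B)
        assert cv(chosen) <= cv(np.min(s)) + 1e-9
        assert cv(chosen) <= cv(np.max(s)) + 1e-9

    def test_nonnegative_and_deterministic(self, two_group_expr):
        a = st.select_s0(two_group_expr, GROUP_A, GROUP_B)
        b = st.select_s0(two_group_expr, GROUP_A, GROUP_B)
        assert a == b >= 0


class TestSignedFoldChange:
    def test_equal_means_give_one(self):
        x = make_expression([[3.0, 3.0, 3.0, 3.0]])
        fc = st.signed_fold_change(x, ["s0", "s1"], ["s2", "s3"])
        assert fc[0] == pytest.approx(1.0)

    def test_ratio_two_and_half(self):
        x = make_expression([[3.0, 3.0, 4.0, 4.0], [3.0, 3.0, 2.0, 2.0]])
        fc = st.signed_fold_change(x, ["s0", "s1"], ["s2", "s3"])
        assert fc[0] == pytest.approx(2.0)
        assert fc[1] == pytest.approx(-2.0)

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        x = make_expression(rng.normal(6, 1, (50, 6)))
        a, b = ["s0", "s1", "s2"], ["s3", "s4", "s5"]
        fc = st.signed_fold_change(x, a, b)
        rev = st.signed_fold_change(x, b, a)
        big = np.abs(fc) > 1
        np.testing.assert_allclose(fc[big], -rev[big], rtol=1e-10)

    def test_abs_at_least_one(self):
        rng = np.random.default_rng(3)
        x = make_expression(rng.normal(6, 2, (200, 8)))
        fc = st.signed_fold_change(x, [f"s{i}" for i in range(4)],
                                   [f"s{i}" for i in range(4, 8)])
        assert np.all(np.abs(fc) >= 1.0)


class TestRunSam:
    def test_constant_matrix_calls_nothing(self):
        x = make_expression(np.full((120, 10), 8.0))
        sam = st.run_sam(x, GROUP_A, GROUP_B, n_permutations=50, seed=0)
        assert len(sam.called(0.05)) == 0
        assert len(sam.called(0.5)) == 0

    def test_rejects_zero_permutations(self, two_group_expr):
        with pytest.raises(ValueError, match="n_permutations"):
            st.run_sam(two_group_expr, GROUP_A, GROUP_B, n_permutations=0,
                       seed=0)

    def test_exhaustive_mode_for_small_groups(self, two_group_expr):
        sam = st.run_sam(two_group_expr, GROUP_A, GROUP_B,
                         n_permutations=1000, seed=0)
        # C(10, 5) minus the original labeling and its mirror
        assert sam.exhaustive
        assert sam.n_permutations == 250

    def test_deterministic_given_seed(self, two_group_expr):
        kw = dict(n_permutations=100, seed=9)
        s1 = st.run_sam(two_group_expr, GROUP_A, GROUP_B, **kw)
        s2 = st.run_sam(two_group_expr, GROUP_A, GROUP_B, **kw)
        pd.testing.assert_frame_equal(s1.table, s2.table)

    def test_p_q_in_unit_interval(self, two_group_expr):
        sam = st.run_sam(two_group_expr, GROUP_A, GROUP_B,
                         n_permutations=100, seed=1)
        assert ((sam.table["p"] > 0) & (sam.table["p"] <= 1)).all()
        assert ((sam.table["q"] >= 0) & (sam.table["q"] <= 1)).all()

    def test_group_swap_preserves_p_and_q(self, two_group_expr):
        s1 = st.run_sam(two_group_expr, GROUP_A, GROUP_B,
                        n_permutations=300, seed=2)
        s2 = st.run_sam(two_group_expr, GROUP_B, GROUP_A,
                        n_permutations=300, seed=2)
        # exhaustive enumeration: identical pooled null under relabeling
        # (float32 null arithmetic can flip single tail counts, so p and q
        # agree to ~1/pool-size rather than exactly)
        np.testing.assert_allclose(s1.table["d"], -s2.table["d"], atol=1e-9)
        np.testing.assert_allclose(s1.table["p"], s2.table["p"], atol=1e-3)
        np.testing.assert_allclose(s1.table["q"], s2.table["q"], atol=1e-3)

    def test_pooled_d_matches_loop_reference(self):
        """Batch permutation statistics agree with probe-by-probe formulas."""
        rng = np.random.default_rng(5)
        arr = rng.normal(size=(40, 9))
        member = np.zeros((9, 12))
        for j in range(12):
            member[rng.permutation(9)[:4], j] = 1.0
        d, s = _pooled_d(arr, member, 5, 4, 0.2)
        for j in range(12):
            b_idx = member[:, j] == 1
            for i in (0, 17, 39):
                a_vals, b_vals = arr[i, ~b_idx], arr[i, b_idx]
                pooled = (
                    ((a_vals - a_vals.mean()) ** 2).sum()
                    + ((b_vals - b_vals.mean()) ** 2).sum()
                ) / 7
                s_ref = np.sqrt(pooled * (1 / 5 + 1 / 4))
                d_ref = (b_vals.mean() - a_vals.mean()) / (s_ref + 0.2)
                assert d[i, j] == pytest.approx(d_ref, abs=1e-10)
                assert s[i, j] == pytest.approx(s_ref, abs=1e-10)


class TestBuildContrastList:
    def _sam(self, seed=0):
        rng = np.random.default_rng(seed)
        vals = rng.normal(7, 0.5, (200, 10))
        vals[:20, 5:] += 1.5
        x = make_expression(vals)
        return st.run_sam(x, GROUP_A, GROUP_B, n_permutations=252, seed=seed,
                          contrast="mN_mPD")

    def test_empty_list_is_valid(self):
        x = make_expression(np.full((50, 10), 3.0))
        sam = st.run_sam(x, GROUP_A, GROUP_B, n_permutations=50, seed=0)
        gl = st.build_contrast_list(sam, "stringent")
        assert len(gl) == 0
        assert list(gl.entries.columns) == ["probe_id", "gene",
                                            "fold_change", "q", "p"]

    def test_stringent_subset_of_relaxed(self):
        sam = self._sam()
        stringent = st.build_contrast_list(sam, "stringent")
        relaxed = st.build_contrast_list(sam, "relaxed")
        assert set(stringent.entries["probe_id"]) <= set(
            relaxed.entries["probe_id"]
        )

    def test_fold_cutoff_count_matches_brute_force(self):
        sam = self._sam(seed=3)
        gl = st.build_contrast_list(sam, "relaxed")
        count = (gl.entries["fold_change"].abs() > 1.5).sum()
        brute = sum(
            1 for pid in gl.entries["probe_id"]
            if abs(sam.table.at[pid, "fold_change"]) > 1.5
        )
        assert count == brute

    def test_entries_pass_gates_and_sorted(self):
        sam = self._sam(seed=4)
        gl = st.build_contrast_list(sam, "stringent")
        assert (gl.entries["q"] < 0.05).all()
        assert (gl.entries["p"] < 0.01).all()
        keys = list(zip(gl.entries["gene"], gl.entries["probe_id"]))
        assert keys == sorted(keys)


class TestAnovaPerGene:
    @staticmethod
    def _design(n_probes, seed, disease_effect=0.0):
        rng = np.random.default_rng(seed)
        rows = []
        for i in range(16):
            rows.append((f"s{i}", "male" if i % 2 else "female",
                         "PD" if i < 8 else "control", f"B{i % 4 // 2 + 1}"))
        meta = make_metadata(rows)
        vals = rng.normal(7, 1, (n_probes, 16))
        if disease_effect:
            pd_cols = [i for i in range(16) if i < 8]
            vals[: n_probes // 4, pd_cols] += disease_effect
        return make_expression(vals, sample_ids=[r[0] for r in rows]), meta

    def test_null_disease_p_uniform(self):
        x, meta = self._design(5000, seed=0)
        res = st.anova_per_gene(x, meta)
        ks = stats.kstest(res["p_disease"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_disease_leaves_gender_uniform(self):
        x, meta = self._design(4000, seed=1, disease_effect=1.5)
        res = st.anova_per_gene(x, meta)
        assert stats.kstest(res["p_gender"], "uniform").pvalue > 0.01
        # quarter of probes planted at ~3 SE: clear excess below p=0.01
        assert (res["p_disease"] < 0.01).mean() > 0.08

    def test_f_equals_t_squared_single_factor(self):
        rng = np.random.default_rng(2)
        rows = [(f"s{i}", "male", "PD" if i < 5 else "control", "B1")
                for i in range(10)]
        meta = make_metadata(rows)
        x = make_expression(rng.normal(size=(100, 10)),
                            sample_ids=[r[0] for r in rows])
        res = st.anova_per_gene(x, meta, factors=("disease",))
        a = meta.select(disease="control")
        b = meta.select(disease="PD")
        d, _ = st.sam_d_statistics(x, a, b, s0=0.0)
        f_from_t = d ** 2
        f_stat = stats.f.isf(res["p_disease"], 1, 8)
        np.testing.assert_allclose(f_stat, f_from_t, atol=1e-8)

    def test_rank_deficient_design_raises(self):
        # batch identical to disease -> aliased
        rows = [(f"s{i}", "male" if i % 2 else "female",
                 "PD" if i < 4 else "control",
                 "B1" if i < 4 else "B2") for i in range(8)]
        meta = make_metadata(rows)
        x = make_expression(np.random.default_rng(0).normal(size=(10, 8)),
                            sample_ids=[r[0] for r in rows])
        with pytest.raises(ValueError, match="aliased"):
            st.anova_per_gene(x, meta)

    def test_fdr_gate_columns(self):
        x, meta = self._design(500, seed=3, disease_effect=2.0)
        res = st.anova_per_gene(x, meta, fdr_gate=0.10)
        assert "sig_disease" in res.columns
        assert res["sig_disease"].sum() > 0
        assert (res["q_disease"][res["sig_disease"]] < 0.10).all()
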