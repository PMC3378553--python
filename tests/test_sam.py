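"""SAM statistic, s0 selection, fold change and permutation q-values."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

import rabscreen as rs
from rabscreen.sam import SamConfig, estimate_s0, relative_difference


class TestRelativeDifference:
    def test_identical_groups_give_zero(self):
        x = np.array([[1.0, 2.0, 3.0]])
        d, s = relative_difference(x, x, s0=0.5)
        assert d[0] == pytest.approx(0.0)

    def test_hand_arithmetic_oracle(self):
        # x1=(1,2,3), x2=(4,5,6): mean diff 3, SS1=SS2=2,
        # s = sqrt((1/3+1/3)*(4)/(4)) = sqrt(2/3)
        d, s = relative_difference(np.array([[1.0, 2.0, 3.0]]),
                                   np.array([[4.0, 5.0, 6.0]]), s0=0.0)
        assert s[0] == pytest.approx(np.sqrt(2.0 / 3.0))
        assert d[0] == pytest.approx(3.0 / np.sqrt(2.0 / 3.0))

    def test_matches_pooled_t_statistic(self):
        rng = np.random.default_rng(11)
        x1 = rng.normal(0, 1, size=(40, 5))
        x2 = rng.normal(0.3, 1, size=(40, 8))
        d, _ = relative_difference(x1, x2, s0=0.0)
        t = stats.ttest_ind(x2, x1, axis=1, equal_var=True).statistic
        np.testing.assert_allclose(d, t, rtol=1e-10)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            relative_difference(np.array([[1.0]]), np.array([[1.0, 2.0]]))

    @given(st.integers(0, 2 ** 32 - 1))
    def test_antisymmetric_under_label_swap(self, seed):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(0, 1, size=(10, 4))
        x2 = rng.normal(0, 1, size=(10, 6))
        d_ab, s_ab = relative_difference(x1, x2, s0=0.1)
        d_ba, s_ba = relative_difference(x2, x1, s0=0.1)
        np.testing.assert_allclose(d_ab, -d_ba, rtol=1e-12)
        np.testing.assert_allclose(s_ab, s_ba, rtol=1e-12)


class TestEstimateS0:
    def test_flat_criterion_returns_smallest_candidate(self):
        # homoscedastic: every candidate rescales d identically, so the
        # criterion is flat and the tie-break picks the smallest (0.0)
        s = np.full(40, 0.7)
        num = np.linspace(-1, 1, 40)
        assert estimate_s0(s, lambda c: num / (s + c + 1e-12)) == 0.0

    def test_matches_exhaustive_grid_oracle(self):
        rng = np.random.default_rng(23)
        m = 200
        s = np.sort(rng.gamma(2.0, 0.2, size=m))  # scatter grows with rank
        num = rng.normal(0, s + 0.1)              # heteroscedastic numerator
        d_at = lambda c: num / (s + c + (c == 0) * 1e-12)
        got = estimate_s0(s, d_at, n_windows=10)

        # independent brute-force evaluation of the same criterion
        candidates = np.unique(np.concatenate(
            [[0.0], np.percentile(s, np.arange(0, 101, 5))]))
        windows = np.array_split(np.argsort(s, kind="stable"), 10)
        best, best_cv = None, np.inf
        for cand in candidates:
            d = d_at(float(cand))
            mads = []
            for w in windows:
                dw = d[w]
                mads.append(np.median(np.abs(dw - np.median(dw))))
            mads = np.asarray(mads)
            cv = mads.std(ddof=1) / mads.mean()
            if cv < best_cv - 1e-12:
                best, best_cv = float(cand), cv
        assert got == pytest.approx(best)

    def test_too_few_genes_rejected(self):
        s = np.ones(5)
        with pytest.raises(ValueError, match="windows"):
            estimate_s0(s, lambda c: s)


class TestFoldChange:
    def test_equal_means_give_one(self, tiny_matrix):
        fc = rs.fold_change(tiny_matrix, ["s1", "s2"], ["s1", "s2"])
        np.testing.assert_allclose(fc, 1.0)

    def test_one_log2_unit_doubles(self):
        mat = pd.DataFrame([[5.0, 5.0, 6.0, 6.0]], index=["G"],
                           columns=list("abcd"))
        assert rs.fold_change(mat, ["a", "b"], ["c", "d"])["G"] == \
            pytest.approx(2.0)

    def test_down_regulation_boundary(self):
        delta = -np.log2(1.5)
        mat = pd.DataFrame([[5.0, 5.0, 5.0 + delta, 5.0 + delta]],
                           index=["G"], columns=list("abcd"))
        fc = rs.fold_change(mat, ["a", "b"], ["c", "d"])["G"]
        assert round(fc, 3) == 0.667

    def test_empty_group_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="non-empty"):
            rs.fold_change(tiny_matrix, [], ["s1"])


def _null_matrix(m, n1, n2, seed):
    rng = np.random.default_rng(seed)
    cols = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    return (pd.DataFrame(rng.normal(8, 0.5, size=(m, n1 + n2)),
                         index=[f"G{i}" for i in range(m)], columns=cols),
            cols[:n1], cols[n1:])


class TestRunSam:
    def test_same_seed_bit_identical(self):
        mat, g1, g2 = _null_matrix(60, 4, 8, seed=2)
        r1 = rs.run_sam(mat, g1, g2, SamConfig(seed=99))
        r2 = rs.run_sam(mat, g1, g2, SamConfig(seed=99))
        pd.testing.assert_frame_equal(r1.table, r2.table)
        assert r1.s0 == r2.s0

    def test_planted_gene_tops_ranking(self):
        mat, g1, g2 = _null_matrix(201, 4, 10, seed=3)
        mat.loc["G0", g2] += 3.0  # large planted shift
        res = rs.run_sam(mat, g1, g2, SamConfig(seed=1))
        t = res.table
        assert t["d"].abs().idxmax() == "G0"
        assert t.loc["G0", "q_percent"] == t["q_percent"].min()

    def test_q_bounds_and_s_nonnegative(self):
        mat, g1, g2 = _null_matrix(80, 5, 5, seed=4)
        res = rs.run_sam(mat, g1, g2, SamConfig(seed=12))
        assert ((res.table.q_percent >= 0) & (res.table.q_percent <= 100)).all()
        assert (res.table.s >= 0).all()
        assert (res.table.fc > 0).all()
        assert res.s0 >= 0

    def test_q_monotone_in_each_tail(self):
        mat, g1, g2 = _null_matrix(120, 4, 8, seed=9)
        mat.loc[[f"G{i}" for i in range(10)], g2] += 1.5
        res = rs.run_sam(mat, g1, g2, SamConfig(seed=5))
        t = res.table.sort_values("d")
        d, q = t["d"].to_numpy(), t["q_percent"].to_numpy()
        pos, neg = d > 0, d < 0
        assert (np.diff(q[pos]) <= 1e-9).all()
        assert (np.diff(q[neg]) >= -1e-9).all()

    def test_ranking_with_zero_s0_matches_t(self):
        mat, g1, g2 = _null_matrix(50, 4, 6, seed=6)
        res = rs.run_sam(mat, g1, g2,
                         SamConfig(seed=1, s0_mode="fixed", s0_fixed=0.0))
        t = stats.ttest_ind(mat[g2], mat[g1], axis=1,
                            equal_var=True).statistic
        order_d = np.argsort(-np.abs(res.table["d"].to_numpy()))
        order_t = np.argsort(-np.abs(t))
        np.testing.assert_array_equal(order_d, order_t)

    def test_missing_values_rejected(self):
        mat, g1, g2 = _null_matrix(40, 3, 3, seed=7)
        mat.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            rs.run_sam(mat, g1, g2)

    def test_small_group_rejected(self):
        mat, g1, g2 = _null_matrix(40, 2, 4, seed=8)
        with pytest.raises(ValueError, match="at least 2"):
            rs.run_sam(mat, g1[:1], g2)

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            SamConfig(n_permutations=0)
        with pytest.raises(ValueError):
            SamConfig(s0_mode="magic")
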