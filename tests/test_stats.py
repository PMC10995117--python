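import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from vwmutil.stats import (
    anova_with_contrasts,
    correlation_matrix,
    paired_contrast,
    rm_anova,
    spearman_brown,
    split_half_reliability,
    split_half_reliability_k,
    within_subject_ci,
)


def manual_rm_anova(matrix: np.ndarray):
    """Independent sums-of-squares oracle for a one-way RM-ANOVA."""
    n, c = matrix.shape
    grand = matrix.mean()
    ss_cond = n * sum((matrix[:, j].mean() - grand) ** 2 for j in range(c))
    ss_subj = c * sum((matrix[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = ((matrix - grand) ** 2).sum()
    ss_err = ss_tot - ss_cond - ss_subj
    df1, df2 = c - 1, (c - 1) * (n - 1)
    f = (ss_cond / df1) / (ss_err / df2)
    return f, df1, df2, ss_cond, ss_err, ss_tot


class TestSpearmanBrown:
    @pytest.mark.parametrize("r, expected", [(0.6, 0.75), (0.0, 0.0), (1.0, 1.0)])
    def test_known_values(self, r, expected):
        assert spearman_brown(r) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0, 1), st.floats(0, 1))
    def test_monotone_and_bounded_on_unit_interval(self, r1, r2):
        lo, hi = sorted([r1, r2])
        assert 0 <= spearman_brown(lo) <= spearman_brown(hi) <= 1


class TestSplitHalf:
    def trials(self, subject_means, n_trials=10, noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for subj, mu in enumerate(subject_means):
            for t in range(n_trials):
                rows.append(
                    {"subject_id": subj, "trial_id": t,
                     "value": mu + noise * rng.normal()}
                )
        return pd.DataFrame(rows)

    def test_identical_halves_give_unit_reliability(self):
        df = self.trials([1.0, 2.0, 3.0, 4.0])
        assert split_half_reliability(df, "value") == pytest.approx(1.0)

    def test_zero_variance_half_is_undefined(self):
        df = self.trials([2.0, 2.0, 2.0])
        assert math.isnan(split_half_reliability(df, "value"))

    def test_needs_three_subjects(self):
        with pytest.raises(ValueError):
            split_half_reliability(self.trials([1.0, 2.0]), "value")

    def test_first_n_restricts_the_sequence(self):
        df = self.trials([1.0, 2.0, 3.0], n_trials=30, noise=0.3)
        r_all = split_half_reliability(df, "value")
        r_15 = split_half_reliability(df, "value", first_n=15)
        assert not math.isnan(r_all) and not math.isnan(r_15)

    def test_k_split_half_perfect_subject_differences(self):
        # three subjects with stable, distinct hit rates -> high reliability
        rng = np.random.default_rng(3)
        rows = []
        for subj, p_hit in enumerate([1.0, 0.5, 0.0, 0.75]):
            i = 0
            for ss in (4, 8):
                for is_change in (True, False):
                    for t in range(20):
                        if is_change:
                            resp = "change" if rng.random() < p_hit else "same"
                        else:
                            resp = "same"
                        rows.append(
                            {"subject_id": subj, "trial_id": i, "set_size": ss,
                             "is_change": is_change, "response": resp, "rt_ms": 500.0}
                        )
                        i += 1
        r = split_half_reliability_k(pd.DataFrame(rows))
        assert r > 0.8


class TestWithinSubjectCI:
    def test_pure_subject_offsets_give_zero_width(self):
        base = np.array([1.0, 2.0, 3.0])
        matrix = pd.DataFrame([base + off for off in (0.0, 5.0, -2.0, 1.3)])
        ci = within_subject_ci(matrix)
        assert np.allclose(ci["ci_half_width"], 0.0, atol=1e-12)
        assert np.allclose(ci["mean"], base + 1.075)

    def test_agrees_with_hand_computation_on_3x3(self):
        matrix = pd.DataFrame(
            [[1.0, 2.0, 4.0], [2.0, 5.0, 6.0], [0.0, 1.0, 5.0]],
            columns=["a", "b", "c"],
        )
        # independent spreadsheet-style computation
        arr = matrix.to_numpy()
        grand = arr.mean()
        normalized = arr - arr.mean(axis=1, keepdims=True) + grand
        expected = []
        for j in range(3):
            col = normalized[:, j]
            sd = np.sqrt(((col - col.mean()) ** 2).sum() / 2)  # ddof=1, n=3
            sem = sd / np.sqrt(3)
            expected.append(np.sqrt(3 / 2) * sps.t.ppf(0.975, 2) * sem)
        ci = within_subject_ci(matrix)
        assert np.allclose(ci["ci_half_width"], expected)

    def test_morey_factor_for_two_conditions(self):
        matrix = pd.DataFrame([[1.0, 2.0], [1.5, 3.5], [0.5, 2.5], [1.0, 3.0]])
        ci = within_subject_ci(matrix)
        # with 2 conditions the normalized columns mirror each other; the
        # half-width is sqrt(2) * t * sd(normalized col) / sqrt(n)
        normalized = matrix.sub(matrix.mean(axis=1), axis=0) + matrix.to_numpy().mean()
        sd = normalized.iloc[:, 0].std(ddof=1)
        expected = math.sqrt(2) * sps.t.ppf(0.975, 3) * sd / 2
        assert ci["ci_half_width"].iloc[0] == pytest.approx(expected)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            within_subject_ci(pd.DataFrame({"only": [1.0, 2.0]}))


class TestRmAnova:
    def test_df_for_thirty_subjects_three_conditions(self):
        rng = np.random.default_rng(42)
        matrix = pd.DataFrame(rng.normal(size=(30, 3)), columns=["s1", "s2", "s4"])
        res = rm_anova(matrix)
        assert (res.df, res.df2) == (2.0, 58.0)
        assert 0 <= res.p <= 1

    def test_all_equal_cells_give_zero_f(self):
        matrix = pd.DataFrame(np.full((5, 3), 2.0))
        res = rm_anova(matrix)
        assert res.value == 0.0
        assert res.p == 1.0

    def test_matches_manual_sums_of_squares(self):
        matrix = pd.DataFrame(
            [[3.0, 4.0, 6.0], [2.0, 4.0, 5.0], [1.0, 3.0, 3.0],
             [4.0, 6.0, 7.0], [2.0, 2.0, 4.0]]
        )
        f, df1, df2, ss_c, ss_e, ss_t = manual_rm_anova(matrix.to_numpy())
        res = rm_anova(matrix)
        assert res.value == pytest.approx(f)
        assert (res.df, res.df2) == (df1, df2)
        assert res.eta_sq == pytest.approx(ss_c / (ss_c + ss_e))
        res_c = rm_anova(matrix, eta_sq="classical")
        assert res_c.eta_sq == pytest.approx(ss_c / ss_t)
        assert res.p == pytest.approx(sps.f.sf(f, df1, df2))

    def test_matches_oracle_on_random_integer_matrices(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            matrix = pd.DataFrame(rng.integers(0, 10, size=(4, 3)).astype(float))
            if matrix.to_numpy().var() == 0:
                continue
            f, df1, df2, *_ = manual_rm_anova(matrix.to_numpy())
            res = rm_anova(matrix)
            assert res.value == pytest.approx(f, rel=1e-9)

    def test_contrast_structure(self):
        rng = np.random.default_rng(0)
        matrix = pd.DataFrame(
            rng.normal(size=(12, 3)) + [0.0, 1.0, 1.2], columns=["ss1", "ss2", "ss4"]
        )
        results = anova_with_contrasts(matrix, name="util")
        names = [r.name for r in results]
        assert names == ["util_anova", "util_ss1_vs_rest", "util_ss2_vs_ss4"]
        # the ss1-vs-rest contrast is a paired t against the within-subject
        # mean of the two larger set sizes
        t_expected, _ = sps.ttest_rel(
            matrix["ss1"], matrix[["ss2", "ss4"]].mean(axis=1)
        )
        assert results[1].value == pytest.approx(float(t_expected))
        assert results[1].eta_sq == pytest.approx(
            float(t_expected**2 / (t_expected**2 + 11))
        )
        pairwise = anova_with_contrasts(matrix, contrast_scheme="pairwise", name="u")
        assert [r.name for r in pairwise] == [
            "u_anova", "u_ss1_vs_ss2", "u_ss1_vs_ss4", "u_ss2_vs_ss4"
        ]


class TestCorrelationMatrix:
    def test_bonferroni_and_diagonal(self):
        rng = np.random.default_rng(5)
        tbl = pd.DataFrame(rng.normal(size=(20, 4)), columns=list("abcd"))
        mat, results = correlation_matrix(tbl, reliabilities={"a": 0.9})
        assert len(results) == 6
        for res in results:
            assert res.p_adjusted == pytest.approx(min(1.0, res.p * 6))
            assert res.p_adjusted >= res.p
        assert mat.loc["a", "a"] == 0.9
        assert mat.loc["a", "b"] == mat.loc["b", "a"]

    def test_duplicated_column_correlates_perfectly(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        tbl = pd.DataFrame({"x": x, "y": x.copy()})
        _, results = correlation_matrix(tbl)
        assert results[0].value == pytest.approx(1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(11)
        tbl = pd.DataFrame(rng.normal(size=(1000, 2)), columns=["a", "b"])
        mat, _ = correlation_matrix(tbl)
        assert abs(mat.loc["a", "b"]) < 0.1

    def test_zero_variance_column_reported_missing(self):
        tbl = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0, 5.0], "b": [2.0] * 5})
        mat, results = correlation_matrix(tbl)
        assert math.isnan(mat.loc["a", "b"])
        assert math.isnan(results[0].p_adjusted)

    def test_needs_four_complete_cases(self):
        with pytest.raises(ValueError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]}))


def test_paired_contrast_requires_two_cases():
    with pytest.raises(ValueError):
        paired_contrast(pd.Series([1.0]), pd.Series([2.0]))
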