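"""Stability statistics: correlations, Stuart-Maxwell, prevalence, residuals."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.contingency_tables import SquareTable

import trustmotives as tm


class TestPearson:
    def test_perfect_correlations(self):
        x = np.array([0.1, 0.5, 0.2, 0.9])
        assert tm.pearson_test(x, x)[0] == pytest.approx(1.0)
        assert tm.pearson_test(x, -x)[0] == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        r, p = tm.pearson_test([1, 2, 3, 4], [1, 2, 3, 5])
        assert r == pytest.approx(6.5 / np.sqrt(5 * 8.75), abs=1e-6)
        assert 0 < p < 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            tm.pearson_test([1, 1, 1], [1, 2, 3])


class TestDistances:
    def test_identical_points(self):
        assert tm.interparticipant_distances([(0.1, 0.0), (0.1, 0.0)]).tolist() == [0.0]

    def test_euclidean_value(self):
        d = tm.interparticipant_distances([(0.0, 0.0), (0.3, 0.04)])
        assert d[0] == pytest.approx(np.sqrt(0.09 + 0.0016))

    def test_pair_count(self):
        d = tm.interparticipant_distances(np.zeros((4, 2)))
        assert len(d) == 6


class TestStuartMaxwell:
    def test_symmetric_table_is_null(self):
        table = np.array([[10, 3, 2], [3, 8, 5], [2, 5, 12]])
        res = tm.stuart_maxwell(table)
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == 1.0

    def test_reduces_to_mcnemar_on_2x2(self):
        res = tm.stuart_maxwell(np.array([[11, 8], [2, 9]]))
        assert res.statistic == pytest.approx((8 - 2) ** 2 / (8 + 2))
        assert res.df == 1

    def test_diagonal_table_is_null(self):
        res = tm.stuart_maxwell(np.diag([5, 9, 1, 7]))
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_invariant_to_category_permutation(self, rng):
        table = rng.integers(0, 15, size=(4, 4))
        base = tm.stuart_maxwell(table).statistic
        for _ in range(5):
            perm = rng.permutation(4)
            permuted = table[np.ix_(perm, perm)]
            assert tm.stuart_maxwell(permuted).statistic == pytest.approx(base)

    def test_matches_statsmodels(self, rng):
        """Independent oracle: statsmodels' marginal-homogeneity test."""
        for _ in range(10):
            table = rng.integers(1, 20, size=(4, 4))
            ours = tm.stuart_maxwell(table)
            ref = SquareTable(pd.DataFrame(table)).homogeneity()
            assert ours.statistic == pytest.approx(ref.statistic)
            assert ours.df == ref.df
            assert ours.pvalue == pytest.approx(ref.pvalue)

    def test_singular_covariance_uses_generalized_inverse(self):
        # first category never used: covariance of marginal diffs is singular
        table = np.zeros((4, 4), dtype=int)
        table[1:, 1:] = [[10, 4, 1], [1, 9, 2], [3, 2, 11]]
        res = tm.stuart_maxwell(table)
        assert res.used_generalized_inverse
        assert res.df < 3
        ref = tm.stuart_maxwell(table[1:, 1:])
        assert res.statistic == pytest.approx(ref.statistic)


class TestChiSquare:
    def test_identical_rows_null(self):
        stat, df, p = tm.chi_square_independence([[10, 20, 5, 15], [10, 20, 5, 15]])
        assert stat == pytest.approx(0.0) and df == 3

    def test_hand_computed_2x2(self):
        stat, df, p = tm.chi_square_independence([[10, 0], [0, 10]])
        assert stat == pytest.approx(20.0) and df == 1

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="zero marginal"):
            tm.chi_square_independence([[10, 0], [5, 0]])


class TestPairwisePrevalence:
    def _table(self):
        return pd.DataFrame(
            [[40, 10, 40, 10], [30, 20, 35, 15]],
            index=["study1", "study2"],
            columns=["IA", "GA", "MO", "GR"],
        )

    def test_six_pairs_for_four_strategies(self):
        out = tm.pairwise_prevalence_tests(self._table())
        assert len(out) == 6

    def test_bonferroni_rule(self):
        out = tm.pairwise_prevalence_tests(self._table())
        ok = out[~out["degenerate"]]
        assert np.allclose(
            ok["p_bonferroni"], np.minimum(1.0, ok["p_uncorrected"] * 6)
        )

    def test_identical_prevalence_rows(self):
        table = pd.DataFrame([[40, 10, 40, 10]] * 2, columns=list("ABCD"))
        out = tm.pairwise_prevalence_tests(table)
        assert np.allclose(out["p_uncorrected"], 1.0)

    def test_degenerate_pair_flagged(self):
        table = pd.DataFrame([[40, 0, 40, 10], [30, 0, 35, 15]],
                             columns=["IA", "GA", "MO", "GR"])
        out = tm.pairwise_prevalence_tests(table)
        flagged = out[out["degenerate"]]
        assert set(flagged["strategy_a"]) | set(flagged["strategy_b"]) >= {"GA"}
        assert flagged["chi2"].isna().all()


class TestResidualize:
    def test_exact_linear_relation_vanishes(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert np.allclose(tm.residualize(2 * x + 1, x), 0.0)

    @settings(deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_orthogonal_and_centered(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        res = tm.residualize(y, x)
        assert abs(res.mean()) < 1e-10
        assert abs(res @ x) < 1e-8

    def test_constant_regressor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            tm.residualize([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestTransitionTable:
    def test_identical_labels_are_diagonal(self):
        labels = ["GA", "IA", "MO", "MO", "GR"]
        table = tm.transition_table(labels, labels, tm.STRATEGY_LABELS)
        assert np.trace(table.counts) == 5
        assert table.percent_stable() == 100.0

    def test_row_percentage_of_switchers(self):
        a = ["MO"] * 48
        b = ["GA"] + ["MO"] * 47
        table = tm.transition_table(a, b, tm.STRATEGY_LABELS)
        mo = tm.STRATEGY_LABELS.index("MO")
        ga = tm.STRATEGY_LABELS.index("GA")
        assert table.row_percentages()[mo, ga] == pytest.approx(100 / 48)

    def test_empty_or_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            tm.transition_table([], [], tm.STRATEGY_LABELS)
        with pytest.raises(ValueError):
            tm.transition_table(["GA"], ["GA", "IA"], tm.STRATEGY_LABELS)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            tm.transition_table(["XX"], ["GA"], tm.STRATEGY_LABELS)
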