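"""Cross-tabulation, chi-square, ANCOVA/Tukey, rank tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lscohort.descriptives import (
    adjusted_group_comparison,
    chi_square_independence,
    cross_tabulate,
    rank_test,
    score_correlations,
)

from oracles import chi_square_reference


def _expand(labels, counts):
    out = []
    for lab, k in zip(labels, counts):
        out.extend([lab] * k)
    return out


class TestCrossTab:
    def test_row_percentages_from_printed_counts(self):
        # healthiest-lifestyle row of the LS x CONUT table
        rows = _expand(["T1"], [1014 + 965 + 73])
        cols = _expand(["low", "moderate", "high"], [1014, 965, 73])
        ct = cross_tabulate(rows, cols)
        pct = ct.row_pct.loc["T1"]
        assert pct["low"] == pytest.approx(49.4, abs=0.05)
        assert pct["moderate"] == pytest.approx(47.0, abs=0.05)
        assert pct["high"] == pytest.approx(3.6, abs=0.05)

    def test_row_percentages_sum_to_100(self):
        rng = np.random.default_rng(0)
        rows = rng.choice(["a", "b", "c"], 500)
        cols = rng.choice(["x", "y"], 500)
        ct = cross_tabulate(rows, cols)
        assert np.allclose(ct.row_pct.sum(axis=1), 100.0)

    def test_single_nonzero_cell_is_100_percent(self):
        ct = cross_tabulate(["a"] * 5, ["x"] * 5)
        assert ct.row_pct.loc["a", "x"] == 100.0

    def test_missing_pairs_dropped_and_counted(self):
        ct = cross_tabulate(["a", "a", None, "b"], ["x", None, "y", "x"])
        assert ct.n_missing == 2
        assert ct.n == 2

    def test_empty_or_misaligned_input_rejected(self):
        with pytest.raises(ValueError):
            cross_tabulate([], [])
        with pytest.raises(ValueError):
            cross_tabulate(["a"], ["x", "y"])


class TestChiSquare:
    def test_proportional_table_gives_zero_statistic(self):
        stat, df, p = chi_square_independence(np.array([[10, 20], [20, 40]]))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        stat, df, p = chi_square_independence(np.array([[10, 20], [20, 10]]))
        assert df == 1
        assert stat == pytest.approx(20 / 3, abs=1e-9)

    def test_agrees_with_brute_force_on_random_tables(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            shape = rng.integers(2, 5, size=2)
            table = rng.integers(1, 60, size=shape)
            stat, df, _ = chi_square_independence(table)
            ref_stat, ref_df = chi_square_reference(table)
            assert stat == pytest.approx(ref_stat, abs=1e-9)
            assert df == ref_df

    def test_small_expected_counts_warn(self):
        with pytest.warns(UserWarning, match="below 5"):
            chi_square_independence(np.array([[1, 9], [2, 8]]))

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi_square_independence(np.array([[0, 0], [5, 5]]))


class TestAdjustedComparison:
    def test_identical_group_distributions_give_p_one(self):
        frame = pd.DataFrame({
            "y": [1.0, 2.0, 3.0, 4.0] * 3,
            "g": ["a"] * 4 + ["b"] * 4 + ["c"] * 4,
        })
        res = adjusted_group_comparison(frame, "y", "g", covariates=())
        assert res.p_value == pytest.approx(1.0, abs=1e-9)
        assert (res.tukey["p_adj"] > 0.99).all()

    def test_simulated_hdl_gradient_detected_with_monotone_means(
            self, scored_cohort):
        res = adjusted_group_comparison(
            scored_cohort, "hdl", "ls_tercile",
            covariates=("age", "sex", "bmi"))
        assert res.p_value < 1e-10
        means = res.adjusted_means
        assert means["T1"] > means["T2"] > means["T3"]

    def test_tukey_pvalues_invariant_to_label_ordering(self):
        rng = np.random.default_rng(9)
        frame = pd.DataFrame({
            "y": rng.normal(size=90) + np.repeat([0.0, 0.4, 0.9], 30),
            "g": np.repeat(["a", "b", "c"], 30),
            "age": rng.uniform(40, 70, 90),
        })
        res1 = adjusted_group_comparison(frame, "y", "g", covariates=("age",))
        relabel = frame.assign(g=frame["g"].map({"a": "z", "b": "y", "c": "x"}))
        res2 = adjusted_group_comparison(relabel, "y", "g",
                                         covariates=("age",))
        assert np.allclose(sorted(res1.tukey["p_adj"]),
                           sorted(res2.tukey["p_adj"]), atol=1e-9)

    def test_singular_design_raises_informatively(self):
        frame = pd.DataFrame({
            "y": np.arange(12, dtype=float),
            "g": ["a", "b", "c"] * 4,
            "x1": np.tile([1.0, 2.0], 6),
            "x2": np.tile([2.0, 4.0], 6),  # collinear with x1
        })
        with pytest.raises(ValueError, match="singular|collinear|x2"):
            adjusted_group_comparison(frame, "y", "g", covariates=("x1", "x2"))

    def test_type_one_error_calibrated_under_null(self):
        """Permutation-style calibration: with no group effect the ANCOVA
        p-value rejects at close to the nominal 5% rate."""
        rng = np.random.default_rng(2024)
        reps, rejections = 400, 0
        for _ in range(reps):
            frame = pd.DataFrame({
                "y": rng.normal(size=60),
                "g": rng.permutation(np.repeat(["a", "b", "c"], 20)),
                "age": rng.uniform(40, 70, 60),
            })
            res = adjusted_group_comparison(frame, "y", "g",
                                            covariates=("age",))
            rejections += res.p_value < 0.05
        rate = rejections / reps
        se = np.sqrt(0.05 * 0.95 / reps)
        assert abs(rate - 0.05) < 3 * se + 1e-9


class TestRankTest:
    def test_three_identical_groups_give_p_one(self):
        y = [1.0, 2.0, 3.0] * 3
        g = np.repeat(["a", "b", "c"], 3)
        stat, p = rank_test(y, g)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_detects_shifted_lognormal_groups(self):
        rng = np.random.default_rng(12)
        y = np.concatenate([rng.lognormal(0.0, 0.5, 200),
                            rng.lognormal(0.45, 0.5, 200)])
        g = np.repeat(["a", "b"], 200)
        stat, p = rank_test(y, g)
        assert p < 1e-6

    def test_groups_of_one_rejected(self):
        with pytest.raises(ValueError):
            rank_test([1.0, 2.0], ["a", "b"])

    def test_constant_outcome_warns_p_one(self):
        with pytest.warns(UserWarning, match="constant"):
            stat, p = rank_test([5.0] * 8, ["a", "b"] * 4)
        assert p == 1.0


class TestCorrelations:
    def _frame(self, ls):
        n = len(ls)
        return pd.DataFrame({
            "ls": ls, "ls_no_smoking": ls, "framingham_risk": ls,
            "diet_subscore": ls, "pa_subscore": ls,
            "smoking_subscore": ls, "alcohol_subscore": ls,
            "conut": ls, "pni": ls, "nri": ls,
        })

    def test_identity_gives_unit_correlations(self):
        frame = self._frame(np.arange(20, dtype=float))
        out = score_correlations(frame)
        ident = out[out["pair"] == "LS vs FS"]
        assert np.allclose(ident["estimate"], 1.0)
        kendall = out[out["method"] == "kendall"]
        assert np.allclose(kendall["estimate"], 1.0)

    def test_negation_gives_minus_one(self):
        ls = np.arange(20, dtype=float)
        frame = self._frame(ls)
        frame["framingham_risk"] = -ls
        out = score_correlations(frame)
        row = out[(out["pair"] == "LS vs FS") & (out["method"] == "spearman")]
        assert row["estimate"].iloc[0] == pytest.approx(-1.0)

    def test_simulated_ls_fs_dependence_recovered(self, scored_cohort):
        # smoking links the LS and the Framingham model, so the full-score
        # correlation is positive and weakens when smoking is excluded
        out = score_correlations(scored_cohort).set_index(["pair", "method"])
        full = out.loc[("LS vs FS", "spearman"), "estimate"]
        reduced = out.loc[("LS (no smoking) vs FS", "spearman"), "estimate"]
        assert 0.05 < full < 0.35
        assert reduced < full
        assert out.loc[("LS vs FS", "spearman"), "p_value"] < 1e-10

    def test_too_few_pairs_warn_and_null(self):
        frame = self._frame(np.array([1.0, 2.0]))
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = score_correlations(frame)
        assert out["estimate"].isna().all()
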