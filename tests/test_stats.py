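"""Aggregation, chi-square, two-way ANOVA, stars, kinetics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from nucleoshuttle.stats import (
    DegenerateMarginError,
    aggregate,
    anova_two_way,
    chisq_test,
    kinetics_summary,
    significance_stars,
)


def chisq_oracle(obs):
    """Independent brute-force Pearson statistic from the margins."""
    obs = np.asarray(obs, dtype=float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    stat = ((obs - expected) ** 2 / expected).sum()
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df


def anova_ss_oracle(frame, response, fa, fb):
    """Textbook balanced two-way SS decomposition by direct arithmetic."""
    grand = frame[response].mean()
    a_levels = frame[fa].unique()
    b_levels = frame[fb].unique()
    n_cell = len(frame) / (len(a_levels) * len(b_levels))
    ss_a = sum(
        len(b_levels) * n_cell * (frame[frame[fa] == a][response].mean() - grand) ** 2
        for a in a_levels
    )
    ss_b = sum(
        len(a_levels) * n_cell * (frame[frame[fb] == b][response].mean() - grand) ** 2
        for b in b_levels
    )
    ss_ab, ss_e = 0.0, 0.0
    for a in a_levels:
        for b in b_levels:
            cell = frame[(frame[fa] == a) & (frame[fb] == b)][response]
            ss_ab += n_cell * (
                cell.mean()
                - frame[frame[fa] == a][response].mean()
                - frame[frame[fb] == b][response].mean()
                + grand
            ) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    return ss_a, ss_b, ss_ab, ss_e


class TestAggregate:
    def test_equal_replicate_means(self):
        df = pd.DataFrame(
            {
                "displayed_ratio": [0.5, 0.5, 0.5],
                "replicate_id": ["r1", "r2", "r3"],
                "genotype": ["WT"] * 3,
            }
        )
        row = aggregate(df, ["genotype"]).iloc[0]
        assert row["grand_mean"] == 0.5 and row["sem"] == 0.0

    def test_sem_of_spread_replicates(self):
        df = pd.DataFrame(
            {
                "displayed_ratio": [0.0, 1.0, 2.0],
                "replicate_id": ["r1", "r2", "r3"],
                "genotype": ["WT"] * 3,
            }
        )
        row = aggregate(df, ["genotype"]).iloc[0]
        assert row["grand_mean"] == pytest.approx(1.0)
        assert row["sem"] == pytest.approx(1.0 / np.sqrt(3.0))

    def test_replicates_weigh_equally_despite_cell_counts(self):
        """10 cells at 0 vs 1000 cells at 1: replicate means average to 0.5."""
        df = pd.DataFrame(
            {
                "displayed_ratio": [0.0] * 10 + [1.0] * 1000,
                "replicate_id": ["r1"] * 10 + ["r2"] * 1000,
                "genotype": ["WT"] * 1010,
            }
        )
        row = aggregate(df, ["genotype"]).iloc[0]
        assert row["grand_mean"] == 0.5
        assert row["n_cells"] == 1010 and row["n_replicates"] == 2

    def test_single_replicate_warns_and_reports_nan_sem(self):
        df = pd.DataFrame(
            {
                "displayed_ratio": [0.3, 0.4],
                "replicate_id": ["r1", "r1"],
                "genotype": ["WT"] * 2,
            }
        )
        with pytest.warns(UserWarning, match="single replicate"):
            row = aggregate(df, ["genotype"]).iloc[0]
        assert row["grand_mean"] == pytest.approx(0.35)
        assert np.isnan(row["sem"])


class TestChiSquare:
    def test_homogeneous_table(self):
        res = chisq_test([[10, 10], [10, 10]])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_closed_form_2x2(self):
        """N(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) = 6.6667 for [[20,10],[10,20]]."""
        res = chisq_test([[20, 10], [10, 20]])
        closed = 60 * (20 * 20 - 10 * 10) ** 2 / (30 * 30 * 30 * 30)
        assert res.statistic == pytest.approx(closed)
        assert res.statistic == pytest.approx(6.6667, abs=5e-5)
        assert res.df == 1

    @pytest.mark.parametrize("shape", [(2, 3), (3, 4)])
    def test_oracle_equivalence(self, shape):
        rng = np.random.default_rng(42)
        obs = rng.integers(1, 50, size=shape)
        res = chisq_test(obs)
        stat, df = chisq_oracle(obs)
        assert res.statistic == pytest.approx(stat, rel=1e-12)
        assert res.df == df

    def test_permutation_invariance(self):
        obs = np.array([[5, 9, 2], [7, 3, 11]])
        base = chisq_test(obs).statistic
        assert chisq_test(obs[::-1]).statistic == pytest.approx(base)
        assert chisq_test(obs[:, ::-1]).statistic == pytest.approx(base)

    def test_proportional_rows_give_zero(self):
        res = chisq_test([[2, 4, 6], [5, 10, 15]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_zero_margin_is_named_error(self):
        with pytest.raises(DegenerateMarginError, match="column"):
            chisq_test([[5, 0], [7, 0]])
        with pytest.raises(DegenerateMarginError, match="row"):
            chisq_test([[0, 0], [7, 3]])


class TestAnovaTwoWay:
    def test_textbook_decomposition(self):
        frame = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 4.0, 2.0, 3.0, 4.0, 5.0],
                "A": ["a", "a", "b", "b"] * 2,
                "B": ["x", "y"] * 4,
            }
        )
        res = anova_two_way(frame, "y", "A", "B")
        ss_a, ss_b, ss_ab, ss_e = anova_ss_oracle(frame, "y", "A", "B")
        assert res.table.loc["A", "sum_sq"] == pytest.approx(ss_a)  # 8
        assert res.table.loc["B", "sum_sq"] == pytest.approx(ss_b)  # 2
        assert res.table.loc["interaction", "sum_sq"] == pytest.approx(ss_ab, abs=1e-9)
        assert res.table.loc["residual", "sum_sq"] == pytest.approx(ss_e)  # 2
        assert res.table.loc["A", "F"] == pytest.approx(16.0)
        # df sum to total
        assert res.table["df"].sum() == len(frame) - 1
        # SS decomposition sums to total SS
        total_ss = ((frame["y"] - frame["y"].mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total_ss)

    def test_zero_variance_convention(self):
        frame = pd.DataFrame(
            {
                "y": [2.0] * 8,
                "A": ["a", "a", "b", "b"] * 2,
                "B": ["x", "y"] * 4,
            }
        )
        res = anova_two_way(frame, "y", "A", "B")
        for term in ("A", "B", "interaction"):
            assert res.table.loc[term, "F"] == 0.0
            assert res.table.loc[term, "p"] == 1.0

    def test_interaction_dropped_without_replication(self):
        frame = pd.DataFrame(
            {
                "y": [1.0, 2.0, 3.0, 5.0],
                "A": ["a", "a", "b", "b"],
                "B": ["x", "y", "x", "y"],
            }
        )
        with pytest.warns(UserWarning, match="interaction"):
            res = anova_two_way(frame, "y", "A", "B")
        assert res.interaction_dropped
        assert "interaction" not in res.table.index

    def test_single_level_factor_rejected(self):
        frame = pd.DataFrame(
            {"y": [1.0, 2.0], "A": ["a", "a"], "B": ["x", "y"]}
        )
        with pytest.raises(ValueError, match="levels"):
            anova_two_way(frame, "y", "A", "B")

    def test_detects_pure_genotype_effect(self):
        """A strong genotype shift with no time effect lands on the right term."""
        rng = np.random.default_rng(7)
        rows = []
        for g, shift in (("WT", 0.0), ("KO", 3.0)):
            for t in (0.0, 2.0, 8.0):
                for r in range(3):
                    rows.append(
                        {"displayed_ratio": shift + rng.normal(0, 1.0),
                         "genotype": g, "timepoint": t}
                    )
        res = anova_two_way(pd.DataFrame(rows), "displayed_ratio", "genotype", "timepoint")
        assert res.table.loc["genotype", "p"] < 0.05
        assert res.table.loc["timepoint", "p"] > res.table.loc["genotype", "p"]


class TestSignificanceStars:
    @pytest.mark.parametrize(
        "p,stars",
        [
            (0.04, "*"),
            (0.0005, "***"),
            (0.2, ""),
            (0.05, "*"),
            (0.01, "**"),
            (0.001, "***"),
            (0.010001, "*"),
        ],
    )
    def test_thresholds(self, p, stars):
        assert significance_stars(p) == stars

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            significance_stars(1.5)
        with pytest.raises(ValueError):
            significance_stars(-0.1)

    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0))
    def test_monotone_step_function(self, p1, p2):
        lo, hi = sorted((p1, p2))
        assert len(significance_stars(lo)) >= len(significance_stars(hi))


class TestKinetics:
    def test_crossing_rule(self):
        res = kinetics_summary([(0, 0.5), (1, -0.3), (2, -0.2), (4, 0.4)])
        assert res.release_time == 1 and res.recovery_time == 4
        assert not res.no_release and not res.no_recovery

    def test_all_positive_flags_no_release(self):
        res = kinetics_summary([(0, 0.5), (2, 0.3), (4, 0.6)])
        assert res.no_release and res.release_time is None

    def test_release_without_recovery_flagged(self):
        res = kinetics_summary([(0, 0.5), (2, -0.3), (4, -0.6)])
        assert res.release_time == 2 and res.no_recovery

    def test_accepts_aggregate_frame(self):
        df = pd.DataFrame({"timepoint": [0, 1, 4], "grand_mean": [0.2, -0.1, 0.3]})
        res = kinetics_summary(df)
        assert res.release_time == 1 and res.recovery_time == 4

    def test_requires_two_timepoints(self):
        with pytest.raises(ValueError):
            kinetics_summary([(0, 0.5)])
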