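"""Psychometric indices and the statistical battery, cross-checked against
scipy, pingouin and statsmodels as independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from hyperflow.stats import (
    compare_dependent_correlations,
    compute_indices,
    friedman_conover,
    rm_anova,
    rm_anova_oneway,
    spearman_ci,
)

from oracles import friedman_chi2_textbook, spearman_textbook


def _ratings(rows: list[list[int]]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=[f"Q{i}" for i in range(1, 10)])


class TestIndices:
    def test_uniform_ratings(self):
        out = compute_indices(_ratings([[4] * 9]))
        assert out.iloc[0][["flow_index", "team_index", "team_flow_index"]].tolist() == [
            4.0,
            4.0,
            4.0,
        ]

    def test_hand_computed_means(self):
        out = compute_indices(_ratings([[7, 7, 7, 7, 7, 7, 1, 2, 3]]))
        row = out.iloc[0]
        assert row["flow_index"] == 7.0
        assert row["team_index"] == pytest.approx(2.0)
        assert row["team_flow_index"] == pytest.approx(4.5)  # mean of the two
        alt = compute_indices(
            _ratings([[7, 7, 7, 7, 7, 7, 1, 2, 3]]), team_flow_from_q1_q9=True
        )
        assert alt.iloc[0]["team_flow_index"] == pytest.approx(48 / 9)

    def test_invalid_rows_excluded(self):
        bad = _ratings([[4] * 9, [8] + [4] * 8, [np.nan] + [4] * 8])
        out = compute_indices(bad)
        assert len(out) == 1 and out.attrs["excluded"] == 2

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            compute_indices(pd.DataFrame({"Q1": [4]}))


class TestFriedmanConover:
    def test_identical_rows_chi2_zero(self, rng):
        base = rng.normal(size=(6, 1))
        res = friedman_conover(np.tile(base, (1, 3)))
        assert res.statistic == 0.0 and res.p == 1.0
        assert not res.posthoc["significant"].any()

    def test_worked_table_matches_textbook_and_scipy(self):
        values = np.array(
            [[1.0, 2.0, 3.0], [2.0, 3.0, 1.0], [1.0, 3.0, 2.0], [1.0, 2.0, 3.0]]
        )
        res = friedman_conover(values)
        assert res.statistic == pytest.approx(friedman_chi2_textbook(values))
        chi2_ref, p_ref = sp_stats.friedmanchisquare(*values.T)
        assert res.statistic == pytest.approx(chi2_ref)
        assert res.p == pytest.approx(p_ref)

    def test_detects_planted_shift(self):
        detected = 0
        n_seeds = 30
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            # monotone shift of 1 SD per condition step
            x = r.normal(size=(15, 3)) + np.array([0.0, 1.0, 2.0])
            detected += friedman_conover(x).p < 0.05
        assert detected >= 0.8 * n_seeds

    def test_missing_cells_rejected(self):
        x = np.ones((4, 3))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="complete"):
            friedman_conover(x)


class TestRmAnova:
    def test_identical_condition_values_null(self, rng):
        base = rng.normal(size=(8, 1))
        res = rm_anova_oneway(np.tile(base, (1, 3)))
        assert res.statistic == 0.0 and res.p == 1.0

    def test_df_formula_3x15(self, rng):
        res = rm_anova_oneway(rng.normal(size=(15, 3)))
        assert res.df == (2, 28)  # (k-1), (k-1)(n-1)

    def test_oneway_matches_pingouin(self, rng):
        import pingouin as pg

        vals = rng.normal(size=(12, 3))
        vals[:, 0] += 0.7
        mine = rm_anova_oneway(vals)
        df = pd.DataFrame(
            {
                "y": vals.ravel(),
                "cond": np.tile(np.arange(3), 12),
                "subj": np.repeat(np.arange(12), 3),
            }
        )
        ref = pg.rm_anova(data=df, dv="y", within="cond", subject="subj", effsize="np2")
        assert mine.statistic == pytest.approx(float(ref["F"][0]))
        assert mine.p == pytest.approx(float(ref["p_unc"][0]))
        assert mine.effect_size == pytest.approx(float(ref["np2"][0]))

    def test_threeway_matches_statsmodels(self, rng):
        from statsmodels.stats.anova import AnovaRM

        vals = rng.normal(size=(8, 3, 2, 2))
        vals[:, 0, :, :] += 0.5
        vals[:, :, 1, 0] -= 0.4
        mine = rm_anova(vals, ["condition", "rg1", "rg2"])
        rows = []
        for s in range(8):
            for c in range(3):
                for a in range(2):
                    for b in range(2):
                        rows.append((s, c, a, b, vals[s, c, a, b]))
        df = pd.DataFrame(rows, columns=["subj", "condition", "rg1", "rg2", "y"])
        ref = AnovaRM(
            df, depvar="y", subject="subj", within=["condition", "rg1", "rg2"]
        ).fit()
        table = ref.anova_table
        name_map = {
            "condition": "condition",
            "rg1": "rg1",
            "rg2": "rg2",
            "condition:rg1": "condition x rg1",
            "condition:rg2": "condition x rg2",
            "rg1:rg2": "rg1 x rg2",
            "condition:rg1:rg2": "condition x rg1 x rg2",
        }
        for sm_name, my_name in name_map.items():
            assert mine[my_name].statistic == pytest.approx(
                float(table.loc[sm_name, "F Value"]), rel=1e-9
            ), sm_name
            assert mine[my_name].df == (
                int(table.loc[sm_name, "Num DF"]),
                int(table.loc[sm_name, "Den DF"]),
            )

    def test_posthoc_bonferroni_attached(self, rng):
        vals = rng.normal(size=(10, 3))
        vals[:, 1] += 2.0
        res = rm_anova_oneway(vals, posthoc_factor="condition")
        assert len(res.posthoc) == 3
        assert res.posthoc["p_adj"].max() <= 1.0

    def test_unbalanced_rejected(self):
        vals = np.ones((5, 3))
        vals[2, 1] = np.nan
        with pytest.raises(ValueError, match="unbalanced|incomplete"):
            rm_anova_oneway(vals)


class TestSpearman:
    def test_perfect_monotone(self):
        res = spearman_ci(np.arange(10.0), np.arange(10.0) ** 3, n_boot=200)
        assert res.statistic == pytest.approx(1.0)

    def test_antitone(self):
        x = np.arange(8.0)
        res = spearman_ci(x, -x, n_boot=200)
        assert res.statistic == pytest.approx(-1.0)

    def test_worked_table_matches_rank_formula(self, rng):
        x = rng.normal(size=12)
        y = x + rng.normal(size=12)
        res = spearman_ci(x, y, n_boot=200, seed=1)
        assert res.statistic == pytest.approx(spearman_textbook(x, y))
        assert res.ci[0] <= res.statistic <= res.ci[1]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_ci(np.ones(10), np.arange(10.0))


class TestCompareDependentCorrelations:
    def test_self_comparison_null(self, rng):
        x = rng.normal(size=15)
        y = x + rng.normal(size=15)
        res = compare_dependent_correlations(x, y, x, y, n_boot=400, seed=0)
        assert res.statistic == 0.0
        assert res.ci[0] <= 0.0 <= res.ci[1]
        assert res.p == pytest.approx(1.0)

    def test_planted_difference_detected(self):
        found = 0
        n_seeds = 12
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            shared = r.normal(size=20)
            y1 = shared + 0.4 * r.normal(size=20)  # strong correlation
            y2 = r.normal(size=20)  # none
            res = compare_dependent_correlations(
                shared, y1, shared, y2, n_boot=300, seed=seed
            )
            found += res.statistic > 0
        assert found >= 0.75 * n_seeds

    def test_mismatched_lengths_rejected(self, rng):
        with pytest.raises(ValueError):
            compare_dependent_correlations(
                rng.normal(size=10), rng.normal(size=10),
                rng.normal(size=9), rng.normal(size=9),
            )
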