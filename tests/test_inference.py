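import numpy as np
import pandas as pd
import pytest
from scipy import stats

from wmhnet.cohort import CELLS
from wmhnet.inference import (
    EFFECTS,
    PAIRS,
    fdr_correct,
    posthoc_pairwise,
    run_analysis,
    two_way_anova,
)


def balanced_cells(per_cell):
    return [c for c in CELLS for _ in range(per_cell)]


def balanced_ss_oracle(y, cells):
    """Closed-form sums of squares for a balanced 2x2 design."""
    y = np.asarray(y, float)
    cells = np.asarray(cells)
    grand = y.mean()
    m = {c: y[cells == c].mean() for c in CELLS}
    n_cell = len(y) // 4
    a_low = (m["lw-no"] + m["lw-o"]) / 2
    a_high = (m["hw-no"] + m["hw-o"]) / 2
    b_no = (m["lw-no"] + m["hw-no"]) / 2
    b_o = (m["lw-o"] + m["hw-o"]) / 2
    ss_a = 2 * n_cell * ((a_low - grand) ** 2 + (a_high - grand) ** 2)
    ss_b = 2 * n_cell * ((b_no - grand) ** 2 + (b_o - grand) ** 2)
    ss_ab = 0.0
    for cell in CELLS:
        a_mean = a_high if cell.startswith("hw") else a_low
        b_mean = b_o if cell.endswith("-o") else b_no
        ss_ab += n_cell * (m[cell] - a_mean - b_mean + grand) ** 2
    ss_resid = sum(((y[cells == c] - m[c]) ** 2).sum() for c in CELLS)
    return ss_a, ss_b, ss_ab, ss_resid


class TestTwoWayAnova:
    def test_balanced_matches_closed_form_oracle(self):
        rng = np.random.default_rng(0)
        cells = balanced_cells(4)  # 16 subjects
        y = rng.normal(size=16) + np.where(np.array(cells) == "hw-o", 1.2, 0.0)
        ss_a, ss_b, ss_ab, ss_resid = balanced_ss_oracle(y, cells)
        df_denom = 16 - 4
        result = two_way_anova(y, cells).set_index("effect")
        mse = ss_resid / df_denom
        assert result.loc["wmh", "F"] == pytest.approx(ss_a / mse, abs=1e-10)
        assert result.loc["obesity", "F"] == pytest.approx(ss_b / mse, abs=1e-10)
        assert result.loc["interaction", "F"] == pytest.approx(ss_ab / mse, abs=1e-10)

    def test_type3_matches_statsmodels_on_unbalanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(1)
        cells = (
            ["lw-no"] * 6 + ["lw-o"] * 3 + ["hw-no"] * 8 + ["hw-o"] * 5
        )
        y = rng.normal(size=len(cells)) + np.where(
            np.array(cells) == "hw-o", 1.0, 0.0
        )
        frame = pd.DataFrame(
            {
                "y": y,
                "w": ["hw" if c.startswith("hw") else "lw" for c in cells],
                "o": ["o" if c.endswith("-o") else "no" for c in cells],
            }
        )
        model = smf.ols("y ~ C(w, Sum) * C(o, Sum)", data=frame).fit()
        reference = sm.stats.anova_lm(model, typ=3)
        result = two_way_anova(y, cells, ss_type=3).set_index("effect")
        assert result.loc["wmh", "F"] == pytest.approx(
            reference.loc["C(w, Sum)", "F"], rel=1e-10
        )
        assert result.loc["obesity", "F"] == pytest.approx(
            reference.loc["C(o, Sum)", "F"], rel=1e-10
        )
        assert result.loc["interaction", "F"] == pytest.approx(
            reference.loc["C(w, Sum):C(o, Sum)", "F"], rel=1e-10
        )

    def test_type2_matches_statsmodels_on_unbalanced_design(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(2)
        cells = ["lw-no"] * 5 + ["lw-o"] * 7 + ["hw-no"] * 4 + ["hw-o"] * 6
        y = rng.normal(size=len(cells))
        frame = pd.DataFrame(
            {
                "y": y,
                "w": ["hw" if c.startswith("hw") else "lw" for c in cells],
                "o": ["o" if c.endswith("-o") else "no" for c in cells],
            }
        )
        reference = sm.stats.anova_lm(
            smf.ols("y ~ C(w) * C(o)", data=frame).fit(), typ=2
        )
        result = two_way_anova(y, cells, ss_type=2).set_index("effect")
        assert result.loc["wmh", "F"] == pytest.approx(
            reference.loc["C(w)", "F"], rel=1e-10
        )
        assert result.loc["obesity", "F"] == pytest.approx(
            reference.loc["C(o)", "F"], rel=1e-10
        )

    def test_type1_and_type3_agree_when_balanced(self):
        rng = np.random.default_rng(3)
        cells = balanced_cells(5)
        y = rng.normal(size=20)
        t3 = two_way_anova(y, cells, ss_type=3).set_index("effect")["F"]
        t2 = two_way_anova(y, cells, ss_type=2).set_index("effect")["F"]
        np.testing.assert_allclose(t3.to_numpy(), t2.to_numpy(), atol=1e-10)

    def test_denominator_df_is_n_minus_4(self):
        rng = np.random.default_rng(4)
        cells = (
            ["lw-no"] * 53 + ["lw-o"] * 38 + ["hw-no"] * 54 + ["hw-o"] * 37
        )
        result = two_way_anova(rng.normal(size=182), cells)
        assert set(result["df1"]) == {1}
        assert set(result["df2"]) == {178}

    def test_empty_cell_rejected(self):
        cells = ["lw-no"] * 4 + ["lw-o"] * 4 + ["hw-no"] * 4
        with pytest.raises(ValueError, match="empty cell"):
            two_way_anova(np.zeros(12), cells)

    def test_unknown_cell_rejected(self):
        with pytest.raises(ValueError, match="unknown cell"):
            two_way_anova(np.zeros(8), ["bogus"] * 8)

    def test_zero_residual_variance(self):
        cells = balanced_cells(2)
        y = np.where(np.array(cells) == "hw-o", 1.0, 0.0)
        with pytest.warns(UserWarning, match="zero residual variance"):
            result = two_way_anova(y, cells).set_index("effect")
        assert result.loc["interaction", "p"] == 0.0

    def test_all_zero_values_not_significant(self):
        cells = balanced_cells(3)
        with pytest.warns(UserWarning, match="zero residual variance"):
            result = two_way_anova(np.zeros(12), cells)
        assert (result["p"] == 1.0).all()

    def test_vectorized_over_nodes_matches_per_node(self):
        rng = np.random.default_rng(5)
        cells = ["lw-no"] * 5 + ["lw-o"] * 3 + ["hw-no"] * 4 + ["hw-o"] * 6
        y = rng.normal(size=(18, 3))
        stacked = two_way_anova(y, cells)
        for node in range(3):
            single = two_way_anova(y[:, node], cells)
            got = stacked[stacked["node"] == node].reset_index(drop=True)
            np.testing.assert_allclose(got["F"], single["F"], rtol=1e-8)


class TestFdrCorrect:
    def test_single_p_identity(self):
        np.testing.assert_allclose(fdr_correct([0.01]), [0.01])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            fdr_correct([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_equal_ps_unchanged(self):
        np.testing.assert_allclose(fdr_correct([0.05] * 5), [0.05] * 5)

    def test_empty_input(self):
        assert fdr_correct([]).size == 0

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_correct([0.5, 1.2])

    def test_matches_hand_rolled_bh(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        m = p.size
        order = np.argsort(p)
        q_sorted = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
        expected = np.empty(m)
        expected[order] = np.minimum(q_sorted, 1.0)
        np.testing.assert_allclose(fdr_correct(p), expected, atol=1e-12)

    def test_q_dominates_p_and_preserves_ranking(self):
        rng = np.random.default_rng(7)
        p = rng.uniform(size=40)
        q = fdr_correct(p)
        assert np.all(q >= p - 1e-15)
        assert np.all((q >= 0) & (q <= 1))
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)


class TestPosthocPairwise:
    def _values_cells(self, groups):
        values = np.concatenate([np.asarray(v, float) for v in groups.values()])
        cells = [c for c, v in groups.items() for _ in v]
        return values, cells

    def test_identical_groups_t_zero(self):
        values, cells = self._values_cells(
            {c: [1.0, 2.0, 3.0] for c in CELLS}
        )
        result = posthoc_pairwise(values, cells)
        np.testing.assert_allclose(result["T"], 0.0, atol=1e-12)
        np.testing.assert_allclose(result["p"], 1.0)

    def test_hand_pooled_t(self):
        # {1,2,3} vs {4,5,6}: pooled s^2 = 1, T = -3 / sqrt(2/3) = -3.674
        values, cells = self._values_cells(
            {
                "lw-no": [1.0, 2.0, 3.0],
                "lw-o": [4.0, 5.0, 6.0],
                "hw-no": [0.0, 0.0, 1.0],
                "hw-o": [0.0, 1.0, 0.0],
            }
        )
        result = posthoc_pairwise(values, cells).set_index("pair")
        row = result.loc["lw-no vs lw-o"]
        assert row["T"] == pytest.approx(-3.674, abs=5e-4)
        assert row["df"] == 4

    def test_pooled_df_for_unequal_groups(self):
        rng = np.random.default_rng(8)
        values, cells = self._values_cells(
            {
                "lw-no": rng.normal(size=54),
                "lw-o": rng.normal(size=37),
                "hw-no": rng.normal(size=53),
                "hw-o": rng.normal(size=38),
            }
        )
        result = posthoc_pairwise(values, cells).set_index("pair")
        assert result.loc["lw-no vs hw-no", "df"] == 105
        assert result.loc["lw-no vs lw-o", "df"] == 89
        assert len(result) == 6

    def test_sign_convention(self):
        values, cells = self._values_cells(
            {
                "lw-no": [10.0, 11.0, 12.0],
                "lw-o": [1.0, 2.0, 3.0],
                "hw-no": [1.0, 2.0, 3.0],
                "hw-o": [1.0, 2.0, 3.0],
            }
        )
        result = posthoc_pairwise(values, cells).set_index("pair")
        assert result.loc["lw-no vs lw-o", "T"] > 0

    def test_t_squared_equals_one_way_f(self):
        rng = np.random.default_rng(9)
        g1, g2 = rng.normal(size=10), rng.normal(1.0, 1.0, size=10)
        values, cells = self._values_cells(
            {"lw-no": g1, "lw-o": g2, "hw-no": rng.normal(size=4),
             "hw-o": rng.normal(size=4)}
        )
        result = posthoc_pairwise(values, cells).set_index("pair")
        t = result.loc["lw-no vs lw-o", "T"]
        f = stats.f_oneway(g1, g2).statistic
        assert t**2 == pytest.approx(f, abs=1e-10)

    def test_small_group_skipped_with_warning(self):
        values, cells = self._values_cells(
            {
                "lw-no": [1.0, 2.0],
                "lw-o": [3.0],
                "hw-no": [1.0, 2.0],
                "hw-o": [4.0, 5.0],
            }
        )
        with pytest.warns(UserWarning, match="skipped"):
            result = posthoc_pairwise(values, cells)
        assert len(result) == 3  # the 3 pairs not involving lw-o
        assert not result["pair"].str.contains("lw-o").any()

    def test_welch_flag_changes_df(self):
        rng = np.random.default_rng(10)
        values, cells = self._values_cells(
            {
                "lw-no": rng.normal(0, 1, size=20),
                "lw-o": rng.normal(0, 5, size=5),
                "hw-no": rng.normal(size=5),
                "hw-o": rng.normal(size=5),
            }
        )
        pooled = posthoc_pairwise(values, cells).set_index("pair")
        welch = posthoc_pairwise(values, cells, equal_var=False).set_index("pair")
        assert pooled.loc["lw-no vs lw-o", "df"] == 23
        assert welch.loc["lw-no vs lw-o", "df"] != 23


class TestRunAnalysis:
    def _toy_inputs(self, seed=0, effect=3.0):
        rng = np.random.default_rng(seed)
        n, nodes = 32, 4
        cells = [c for c in CELLS for _ in range(n // 4)]
        subject_ids = [f"sub-{i:04d}" for i in range(n)]
        values = rng.normal(size=(n, nodes))
        values[np.array(cells) == "hw-o", 0] += effect  # implant at node 1
        centrality = pd.DataFrame(
            {
                "subject_id": np.repeat(subject_ids, nodes),
                "region_id": np.tile(np.arange(1, nodes + 1), n),
                "raw": values.ravel(),
                "adjusted": values.ravel(),
            }
        )
        assignments = pd.DataFrame(
            {
                "subject_id": subject_ids,
                "criterion": "total",
                "cell": cells,
            }
        )
        return centrality, assignments

    def test_implanted_node_found_and_posthoc_gated(self):
        centrality, assignments = self._toy_inputs()
        anova, posthoc = run_analysis(centrality, assignments)
        inter = anova[anova["effect"] == "interaction"].set_index("region_id")
        assert inter["F"].idxmax() == 1
        assert inter.loc[1, "q"] < 0.05
        # post-hoc only for surviving nodes, 6 pairs each
        assert set(posthoc["region_id"]) == set(
            inter.index[inter["q"] < 0.05]
        )
        assert (posthoc.groupby("region_id").size() == 6).all()

    def test_posthoc_all_flag(self):
        centrality, assignments = self._toy_inputs()
        _, posthoc = run_analysis(centrality, assignments, posthoc_all=True)
        assert set(posthoc["region_id"]) == {1, 2, 3, 4}

    def test_no_effect_gives_empty_posthoc(self):
        centrality, assignments = self._toy_inputs(seed=1, effect=0.0)
        anova, posthoc = run_analysis(centrality, assignments)
        assert len(posthoc) == 0
        assert list(posthoc.columns) == [
            "criterion", "region_id", "pair", "n1", "n2", "T", "df", "p", "q",
        ]

    def test_missing_subject_rejected(self):
        centrality, assignments = self._toy_inputs()
        with pytest.raises(ValueError, match="sub-0000"):
            run_analysis(centrality, assignments.iloc[1:])

    def test_fdr_family_is_per_effect_across_nodes(self):
        centrality, assignments = self._toy_inputs()
        anova, _ = run_analysis(centrality, assignments)
        for effect in EFFECTS:
            sub = anova[anova["effect"] == effect]
            np.testing.assert_allclose(
                sub["q"].to_numpy(), fdr_correct(sub["p"].to_numpy()), atol=1e-12
            )

    def test_deterministic_ordering(self):
        centrality, assignments = self._toy_inputs()
        anova, posthoc = run_analysis(centrality, assignments, posthoc_all=True)
        assert list(anova["region_id"].unique()) == [1, 2, 3, 4]
        per_node = posthoc[posthoc["region_id"] == 1]["pair"].tolist()
        assert per_node == [f"{a} vs {b}" for a, b in PAIRS]
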