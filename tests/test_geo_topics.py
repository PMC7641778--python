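import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from searchsurge.data_model import AnalysisWindow
from searchsurge.geo_topics import (
    StatePanel,
    build_panel,
    cumulative_qf,
    group_contrast,
    icc,
    icc_anova_oracle,
    leading_topic_tally,
    rank_states,
    topic_shares,
)

from .conftest import make_series

TOPICS = ["union", "training", "immunity", "militarization"]


def panel_from(values, geos=None, topics=None):
    values = np.asarray(values, dtype=float)
    geos = geos or [f"S{i}" for i in range(values.shape[0])]
    topics = topics or TOPICS[: values.shape[1]]
    return StatePanel(pd.DataFrame(values, index=geos, columns=topics))


class TestCumulativeQF:
    def test_constant_42_days(self):
        w = AnalysisWindow(dt.date(2020, 1, 1), dt.date(2020, 5, 25), dt.date(2020, 7, 5))
        n = (dt.date(2020, 7, 5) - dt.date(2020, 1, 1)).days + 1
        s = make_series(start=dt.date(2020, 1, 1), values=np.full(n, 100.0))
        assert cumulative_qf(s, w) == pytest.approx(4200.0)

    def test_all_zero(self):
        w = AnalysisWindow(dt.date(2020, 1, 1), dt.date(2020, 1, 5), dt.date(2020, 1, 10))
        s = make_series(values=np.zeros(15))
        assert cumulative_qf(s, w) == 0.0

    def test_arithmetic_series(self):
        w = AnalysisWindow(dt.date(2020, 1, 1), dt.date(2020, 1, 2), dt.date(2020, 1, 11))
        s = make_series(values=np.r_[0.0, np.arange(1.0, 11.0)])
        assert cumulative_qf(s, w) == pytest.approx(55.0)

    def test_window_not_covered(self):
        w = AnalysisWindow(dt.date(2020, 1, 1), dt.date(2020, 1, 5), dt.date(2020, 3, 1))
        s = make_series(values=np.ones(10))
        with pytest.raises(ValueError, match="not covered"):
            cumulative_qf(s, w)


class TestRankStates:
    def test_all_equal_fold_one(self):
        p = panel_from(np.full((5, 2), 3.0))
        r = rank_states(p, "union")
        np.testing.assert_allclose(r["fold_vs_mean"], 1.0)

    def test_dc_fold_4_2(self):
        # invert the printed fold: mean 1738.1 with focal QF 7300 -> 4.20-fold
        n, mean, dc = 51, 1738.1, 7300.0
        others = (mean * n - dc) / (n - 1)
        values = np.column_stack([np.r_[dc, np.full(n - 1, others)], np.ones(n)])
        p = panel_from(values, geos=["DC"] + [f"S{i}" for i in range(n - 1)])
        r = rank_states(p, "union")
        assert r.loc["DC", "fold_vs_mean"] == pytest.approx(dc / mean, abs=1e-9)
        assert r.loc["DC", "fold_vs_mean"] == pytest.approx(4.20, abs=0.005)
        assert r.loc["DC", "rank"] == 1

    def test_percent_below_mean_55(self):
        # Arkansas: QF 783 against mean 1740 -> (1 - 783/1740) * 100 = 55%
        n, mean, ar = 51, 1740.0, 783.0
        others = (mean * n - ar) / (n - 1)
        values = np.column_stack([np.r_[ar, np.full(n - 1, others)], np.ones(n)])
        p = panel_from(values, geos=["AR"] + [f"S{i}" for i in range(n - 1)])
        r = rank_states(p, "union")
        assert r.loc["AR", "percent_below_mean"] == pytest.approx(55.0, abs=0.01)

    def test_exclude_focal_convention(self):
        p = panel_from(np.array([[4.0], [1.0], [1.0]]), topics=["union"])
        r = rank_states(p, "union", exclude_focal=True)
        assert r.loc["S0", "fold_vs_mean"] == pytest.approx(4.0)

    def test_ties_share_min_rank(self):
        p = panel_from(np.array([[5.0], [5.0], [1.0]]), topics=["union"])
        r = rank_states(p, "union")
        assert list(r["rank"][:2]) == [1, 1]
        assert r.loc["S2", "rank"] == 3

    def test_common_rescale_invariance(self):
        vals = np.random.default_rng(0).uniform(1, 10, (6, 3))
        r1 = rank_states(panel_from(vals), "union")
        r2 = rank_states(panel_from(vals * 7.5), "union")
        np.testing.assert_allclose(r1["fold_vs_mean"], r2["fold_vs_mean"])
        assert list(r1["rank"]) == list(r2["rank"])

    def test_needs_two_geographies(self):
        with pytest.raises(ValueError):
            rank_states(panel_from(np.ones((1, 2))), "union")


class TestTopicShares:
    def test_fig4_caption_instantiation(self):
        # union 370, training 400, immunity 180, militarization 50 -> union 37%
        p = panel_from(np.array([[370.0, 400.0, 180.0, 50.0]]), geos=["AK"])
        shares = topic_shares(p)
        assert shares.frame.loc["AK", "union"] == pytest.approx(0.37, abs=1e-15)
        assert shares.leading["AK"] == "training"

    def test_single_topic_dominates(self):
        p = panel_from(np.array([[0.0, 9.0, 0.0, 0.0]]))
        shares = topic_shares(p)
        assert shares.frame.iloc[0]["training"] == 1.0
        assert shares.frame.iloc[0]["union"] == 0.0

    def test_equal_topics(self):
        p = panel_from(np.full((3, 4), 2.0))
        shares = topic_shares(p)
        np.testing.assert_allclose(shares.frame.to_numpy(), 0.25)

    def test_row_rescale_invariance(self):
        vals = np.random.default_rng(1).uniform(1, 5, (4, 4))
        s1 = topic_shares(panel_from(vals)).frame.to_numpy()
        vals2 = vals * np.array([[1.0], [3.0], [0.5], [10.0]])
        s2 = topic_shares(panel_from(vals2)).frame.to_numpy()
        np.testing.assert_allclose(s1, s2)

    def test_all_zero_row_errors(self):
        with pytest.raises(ValueError, match="all-zero"):
            topic_shares(panel_from(np.array([[0.0, 0.0]])))

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(min_value=0.01, max_value=1e4), min_size=4, max_size=4),
            min_size=1,
            max_size=8,
        )
    )
    def test_shares_sum_to_one_property(self, rows):
        shares = topic_shares(panel_from(np.array(rows)))
        np.testing.assert_allclose(shares.frame.sum(axis=1), 1.0, atol=1e-12)


class TestLeadingTopicTally:
    def test_all_training(self):
        p = panel_from(np.array([[1.0, 5.0, 1.0, 1.0]] * 3))
        tally = leading_topic_tally(topic_shares(p))
        assert tally["counts"] == {"union": 0, "training": 3, "immunity": 0,
                                   "militarization": 0}
        assert tally["mean_leading_share"]["training"] == pytest.approx(5 / 8)

    def test_tie_flagged_and_excluded(self):
        p = panel_from(np.array([[0.5, 0.5, 0.0, 0.0]]))
        shares = topic_shares(p)
        tally = leading_topic_tally(shares)
        assert tally["n_tied"] == 1
        assert sum(tally["counts"].values()) == 0
        assert tally["ties"]["S0"] == ["union", "training"]

    def test_counts_plus_ties_cover_geographies(self, small_panel):
        collection, _, _ = small_panel
        window = AnalysisWindow(dt.date(2019, 6, 1), dt.date(2020, 5, 25), dt.date(2020, 7, 5))
        panel = build_panel(collection, window)
        tally = leading_topic_tally(topic_shares(panel))
        assert sum(tally["counts"].values()) + tally["n_tied"] == len(panel.geographies)

    def test_injected_leaders_recovered(self, small_panel, small_config):
        # ground truth: leader = topic with max expected share per geography
        collection, _, truth = small_panel
        panel = build_panel(collection, small_config.window)
        shares = topic_shares(panel)
        for geo, exp in truth["expected_topic_shares"].items():
            assert shares.leading[geo] == max(exp, key=exp.get)


class TestICC:
    def test_identical_within_row_is_one(self):
        vals = np.array([[i + 1.0] * 4 for i in range(5)])
        p = panel_from(vals)
        assert icc(p, rank_normalize=False) == pytest.approx(1.0)

    def test_iid_cells_near_zero(self):
        rng = np.random.default_rng(7)
        p = panel_from(rng.normal(10, 1, (200, 4)).clip(min=0))
        assert abs(icc(p, rank_normalize=False)) < 0.1

    def test_toy_matrix_matches_oracle(self):
        vals = np.array(
            [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [10.0, 9.0, 11.0], [0.5, 1.0, 0.8]]
        )
        assert icc(panel_from(vals, topics=["a", "b", "c"]), rank_normalize=False) == \
            pytest.approx(icc_anova_oracle(vals), abs=1e-12)

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.lists(st.floats(min_value=0, max_value=100), min_size=4, max_size=4),
            min_size=5,
            max_size=5,
        ).filter(lambda rows: np.ptp(np.asarray(rows)) > 1e-6)
    )
    def test_random_5x4_matches_oracle(self, rows):
        vals = np.asarray(rows)
        assert icc(panel_from(vals), rank_normalize=False) == pytest.approx(
            icc_anova_oracle(vals), abs=1e-12
        )

    def test_rank_normalized_in_range(self, small_panel, small_config):
        collection, _, _ = small_panel
        panel = build_panel(collection, small_config.window)
        val = icc(panel, rank_normalize=True)
        assert -1.0 <= val <= 1.0

    def test_degenerate_errors(self):
        with pytest.raises(ValueError):
            icc(panel_from(np.ones((3, 3))), rank_normalize=False)
        with pytest.raises(ValueError):
            icc(panel_from(np.ones((1, 4))))


class TestGroupContrast:
    def test_arithmetic(self):
        vals = np.array([[1.0], [2.0], [3.0], [4.0]])
        out = group_contrast(panel_from(vals, topics=["union"]), k=1, B=200, seed=0)
        assert out["percent_lower"] == pytest.approx(75.0)

    def test_identical_groups_zero(self):
        vals = np.full((6, 2), 5.0)
        out = group_contrast(panel_from(vals), k=3, B=200, seed=0)
        assert out["percent_lower"] == pytest.approx(0.0)
        assert out["ci"][0] <= 0.0 <= out["ci"][1]

    def test_k_too_large(self):
        with pytest.raises(ValueError, match="too large"):
            group_contrast(panel_from(np.ones((4, 2))), k=3)

    def test_deterministic(self):
        vals = np.random.default_rng(3).uniform(1, 10, (12, 4))
        a = group_contrast(panel_from(vals), k=3, B=500, seed=11)
        b = group_contrast(panel_from(vals), k=3, B=500, seed=11)
        assert a == b


class TestBuildPanel:
    def test_incomplete_panel_errors(self):
        s1 = make_series(geography="AA", topic="union", values=np.ones(30))
        s2 = make_series(geography="BB", topic="training", values=np.ones(30))
        w = AnalysisWindow(dt.date(2020, 1, 1), dt.date(2020, 1, 10), dt.date(2020, 1, 20))
        with pytest.raises(ValueError, match="missing"):
            build_panel([s1, s2], w)

    def test_panel_values(self, small_panel, small_config):
        collection, _, truth = small_panel
        panel = build_panel(collection, small_config.window)
        s = collection[0]
        expected = float(np.sum(np.asarray(
            truth["series"][f"{s.geography}/{s.topic}"]["observed_post"]
        )))
        assert panel.frame.loc[s.geography, s.topic] == pytest.approx(expected)
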