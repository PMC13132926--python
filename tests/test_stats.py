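"""Robust trimmed-means statistics and classical RM ANOVA."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from _oracles import naive_kms_two_groups, naive_trimmed_mean, naive_winsorized_variance
from tswp.stats import (
    akp_effect,
    bw_trimmed_anova,
    kms_effect,
    rm_anova_gg,
    trim_scale_constant,
    trimmed_mean,
    winsorized_variance,
)


def _long(groups, rng=None):
    """groups: dict group -> (n x K) array; returns long-format frame."""
    rows = []
    for g, X in groups.items():
        for i, row in enumerate(np.atleast_2d(X)):
            for w, v in enumerate(row):
                rows.append(dict(participant_id=f"{g}{i}", group=g,
                                 condition=f"w{w}", value=float(v)))
    return pd.DataFrame(rows)


class TestTrimmedStats:
    def test_hand_fixture_1_to_10(self):
        ts = trimmed_mean(np.arange(1, 11), 0.2)
        assert ts.g == 2
        assert ts.mt == pytest.approx(5.5)

    def test_winsorized_variance_1_to_5(self):
        assert winsorized_variance([1, 2, 3, 4, 5], 0.2) == pytest.approx(1.0)

    def test_constant_sample(self):
        ts = trimmed_mean([7.0] * 9, 0.2)
        assert ts.mt == 7.0 and ts.winsorized_variance == 0.0

    def test_trim_zero_reduces_to_arithmetic_mean(self):
        x = np.random.default_rng(0).lognormal(1, 1, 31)
        ts = trimmed_mean(x, 0.0)
        assert ts.mt == pytest.approx(ts.ma) == pytest.approx(x.mean())

    @pytest.mark.parametrize("trim", [0.1, 0.2, 0.25])
    def test_matches_naive_oracle(self, trim):
        x = np.random.default_rng(3).normal(10, 4, 27)
        assert trimmed_mean(x, trim).mt == pytest.approx(naive_trimmed_mean(x, trim))
        assert winsorized_variance(x, trim) == pytest.approx(
            naive_winsorized_variance(x, trim)
        )

    def test_se_formula(self):
        x = np.random.default_rng(4).normal(0, 1, 40)
        ts = trimmed_mean(x, 0.2)
        assert ts.se_trimmed == pytest.approx(
            np.sqrt(ts.winsorized_variance) / (0.6 * np.sqrt(40))
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            trimmed_mean([1.0], 0.5)
        with pytest.raises(ValueError):
            trimmed_mean([], 0.2)


class TestBwTrimmedAnova:
    def test_constant_cells_give_zero_statistics(self):
        groups = {"A": np.full((6, 3), 5.0), "B": np.full((8, 3), 5.0)}
        tab = bw_trimmed_anova(_long(groups))
        assert np.allclose(tab["statistic"], 0.0)

    def test_trim_zero_between_equals_welch_t_squared(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(0, 1, 14), rng.normal(0.6, 2.5, 23)
        groups = {"A": a[:, None], "B": b[:, None]}
        tab = bw_trimmed_anova(_long(groups), trim=0.0).set_index("effect")
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert tab.loc["group", "statistic"] == pytest.approx(t**2)
        assert tab.loc["group", "p"] == pytest.approx(p)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(12)
        groups = {"A": rng.normal(0, 1, (9, 2)), "B": rng.normal(0.5, 2, (13, 2))}
        df = _long(groups)
        tab1 = bw_trimmed_anova(df)
        tab2 = bw_trimmed_anova(df.sample(frac=1.0, random_state=1))
        pd.testing.assert_frame_equal(tab1, tab2)

    def test_insufficient_group_after_trimming(self):
        # n = 5 at trim 0.45 leaves h = 5 - 2*2 = 1 < 2 central values
        groups = {"A": np.random.default_rng(0).normal(0, 1, (5, 2)),
                  "B": np.random.default_rng(1).normal(0, 1, (12, 2))}
        with pytest.raises(ValueError, match="insufficient"):
            bw_trimmed_anova(_long(groups), trim=0.45)

    def test_incomplete_profile_names_participant(self):
        df = _long({"A": np.random.default_rng(0).normal(0, 1, (6, 2)),
                    "B": np.random.default_rng(1).normal(0, 1, (6, 2))})
        df = df.drop(df[(df.participant_id == "A2") & (df.condition == "w1")].index)
        with pytest.raises(ValueError, match="A2"):
            bw_trimmed_anova(df)

    def test_reports_all_three_effects_with_df(self):
        rng = np.random.default_rng(13)
        groups = {g: rng.normal(i, 1 + i, (10 + 3 * i, 4)) for i, g in enumerate("ABC")}
        tab = bw_trimmed_anova(_long(groups)).set_index("effect")
        assert set(tab.index) == {"group", "condition", "group x condition"}
        assert tab.loc["group", "df1"] == 2
        assert tab.loc["condition", "df1"] == 3
        assert tab.loc["group x condition", "df1"] == 6
        assert ((tab["p"] >= 0) & (tab["p"] <= 1)).all()


class TestEffectSizes:
    def test_akp_identical_samples_zero(self):
        x = np.random.default_rng(1).normal(0, 1, 30)
        assert akp_effect(x, x.copy()) == pytest.approx(0.0)

    def test_akp_one_winsorized_sd_gap_hits_scale_constant(self):
        """A trimmed-mean gap of exactly one pooled winsorized SD scores the
        20%-trim scaling constant (~0.642), evaluated from the normal
        integral rather than hard-coded."""
        x = np.random.default_rng(2).normal(0, 1, 60)
        shift = np.sqrt(winsorized_variance(x, 0.2))
        d = akp_effect(x + shift, x, 0.2)
        assert d == pytest.approx(trim_scale_constant(0.2))
        assert trim_scale_constant(0.2) == pytest.approx(0.642, abs=5e-4)

    def test_akp_sign_follows_difference(self):
        x = np.random.default_rng(3).normal(0, 1, 40)
        assert akp_effect(x, x + 1.0) < 0

    def test_kms_identical_groups_zero(self):
        x = np.random.default_rng(4).normal(0, 1, 25)
        assert kms_effect([x, x.copy()]) == pytest.approx(0.0)

    def test_kms_matches_independent_formula(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 2000), rng.normal(1, 1, 2000)
        assert kms_effect([a, b], trim=0.0) == pytest.approx(naive_kms_two_groups(a, b))

    def test_kms_affine_invariance(self):
        rng = np.random.default_rng(6)
        gs = [rng.normal(0, 1, 30), rng.normal(1, 2, 40), rng.normal(-1, 1.5, 25)]
        base = kms_effect(gs)
        scaled = kms_effect([3.5 * g - 7 for g in gs])
        assert scaled == pytest.approx(base)

    def test_kms_degenerate_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            kms_effect([np.full(10, 1.0), np.full(10, 2.0)])


def _hand_rm_ss(table):
    """Independent sums-of-squares decomposition for a subjects x levels
    table, by plain loops."""
    n, k = table.shape
    grand = table.mean()
    ss_within = sum(n * (table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_subj = sum(k * (table[i, :].mean() - grand) ** 2 for i in range(n))
    ss_tot = ((table - grand) ** 2).sum()
    ss_err = ss_tot - ss_within - ss_subj
    return ss_within, ss_err


class TestRmAnovaGG:
    def test_two_level_epsilon_is_one(self):
        rng = np.random.default_rng(7)
        rows = [dict(s=i, w=w, y=rng.normal(w * 0.5, 1)) for i in range(10) for w in range(2)]
        tab = rm_anova_gg(pd.DataFrame(rows), dv="y", within="w", subject="s")
        assert tab["epsilon"].iloc[0] == 1.0

    def test_matches_hand_sums_of_squares(self):
        rng = np.random.default_rng(8)
        table = rng.normal(0, 1, (6, 3)) + np.array([0.0, 0.4, 0.9])
        rows = [dict(s=i, w=w, y=table[i, w]) for i in range(6) for w in range(3)]
        tab = rm_anova_gg(pd.DataFrame(rows), dv="y", within="w", subject="s")
        ss_w, ss_e = _hand_rm_ss(table)
        f_hand = (ss_w / 2) / (ss_e / 10)
        assert tab["statistic"].iloc[0] == pytest.approx(f_hand)
        assert tab["effect_size"].iloc[0] == pytest.approx(ss_w / (ss_w + ss_e))
        assert 0 < tab["epsilon"].iloc[0] <= 1

    def test_constant_data_zero_f(self):
        rows = [dict(s=i, w=w, y=4.0) for i in range(5) for w in range(3)]
        tab = rm_anova_gg(pd.DataFrame(rows), dv="y", within="w", subject="s")
        assert tab["statistic"].iloc[0] == 0.0
        assert tab["effect_size"].iloc[0] == 0.0

    def test_mixed_design_reports_three_effects(self):
        rng = np.random.default_rng(9)
        rows = []
        for i in range(16):
            g = "G1" if i < 8 else "G2"
            for w in range(3):
                rows.append(dict(s=i, g=g, w=w, y=rng.normal((w + 1) * (1 + (g == "G2")), 1)))
        tab = rm_anova_gg(pd.DataFrame(rows), dv="y", within="w", subject="s", between="g")
        assert set(tab["effect"]) == {"g", "w", "g x w"}
        within = tab.set_index("effect").loc["w"]
        assert 0 < within["epsilon"] <= 1

    def test_incomplete_case_names_participant(self):
        rows = [dict(s=i, w=w, y=1.0 * w * i) for i in range(4) for w in range(3)]
        rows = [r for r in rows if not (r["s"] == 2 and r["w"] == 1)]
        with pytest.raises(ValueError, match="2"):
            rm_anova_gg(pd.DataFrame(rows), dv="y", within="w", subject="s")
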