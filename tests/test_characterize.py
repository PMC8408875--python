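"""Transforms, responder summaries, CVs, Levene and interaction tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import postmeal as pm
from postmeal.exceptions import InsufficientDataError, InvalidParameterError


class TestTransforms:
    @pytest.mark.parametrize(
        "x,expected",
        [(0.0, 0.0), (np.e - 1, 1.0), (0.48, np.log(1.48))],
    )
    def test_ln_plus_one(self, x, expected):
        assert pm.ln_plus_one(x) == pytest.approx(expected)

    def test_ln_plus_one_rejects_negative(self):
        with pytest.raises(InvalidParameterError):
            pm.ln_plus_one(-0.1)

    @pytest.mark.parametrize(
        "baseline,followup,decimals,printed",
        [
            # cohort means as printed: IL-6 and GlycA 6-h rises
            (0.48, 1.29, 0, 169),
            (1.32, 1.38, 1, 4.5),
            # glucose peaks and TG maximum vs fasting
            (4.91, 7.01, 1, 42.7),
            (4.91, 6.47, 1, 31.7),
            (1.05, 2.11, 1, 100.9),
        ],
    )
    def test_percent_change_matches_printed_values(self, baseline, followup, decimals, printed):
        pct = pm.percent_change(baseline, followup)
        assert pm.format_percent(pct, decimals) == printed

    def test_percent_change_identity_and_domain(self):
        assert pm.percent_change(2.0, 2.0) == 0.0
        with pytest.raises(InvalidParameterError):
            pm.percent_change(0.0, 1.0)

    @settings(deadline=None)
    @given(
        baseline=st.floats(0.1, 10),
        followup=st.floats(0.0, 20),
        c=st.floats(0.01, 100),
    )
    def test_percent_change_scale_invariant(self, baseline, followup, c):
        assert pm.percent_change(baseline, followup) == pytest.approx(
            pm.percent_change(c * baseline, c * followup), rel=1e-9
        )


class TestResponderSummary:
    def test_hand_example(self):
        v0 = np.array([1.0, 1.0, 1.0])
        v6 = np.array([1.2, 0.8, 1.0])
        s = pm.responder_summary(v0, v6)
        assert s.fraction_rising == pytest.approx(1 / 3)
        assert s.responder_mean_rise == pytest.approx(0.2)
        assert s.responder_pct_rise == pytest.approx(20.0)

    def test_printed_responder_means(self):
        # responders rising from 0.46 to 1.33 on average: +0.87 units (189%)
        s = pm.responder_summary(np.array([0.46, 0.46]), np.array([1.33, 1.33]))
        assert s.responder_mean_rise == pytest.approx(0.87)
        assert pm.format_percent(s.responder_pct_rise, 0) == 189

    def test_all_decliners(self):
        s = pm.responder_summary(np.array([1.0, 2.0]), np.array([0.5, 1.5]))
        assert s.fraction_rising == 0.0
        assert s.responder_mean_rise is None

    def test_riser_decliner_unchanged_fractions_sum_to_one(self, rng):
        v0 = rng.uniform(0.5, 2.0, 100)
        v6 = v0 + rng.choice([-0.1, 0.0, 0.1], 100)
        rise = pm.responder_summary(v0, v6).fraction_rising
        decline = pm.responder_summary(-v0 + 5, -v6 + 5).fraction_rising  # sign trick
        unchanged = np.mean(v6 == v0)
        assert rise + decline + unchanged == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            pm.responder_summary(np.array([np.nan]), np.array([1.0]))


class TestCV:
    def test_printed_glyca_fasting_cv(self):
        x = 1.32 + 0.18 * np.array([-1.0, 1.0]) / np.sqrt(2)
        cv = pm.cross_sectional_cv(x)
        assert pm.format_percent(cv.cv_pct, 1) == 13.6

    def test_printed_il6_fasting_cv(self):
        x = 0.48 + 0.28 * np.array([-1.0, 1.0]) / np.sqrt(2)
        assert pm.format_percent(pm.cross_sectional_cv(x).cv_pct, 1) == 58.3

    def test_constant_vector(self):
        assert pm.cross_sectional_cv(np.full(5, 2.0)).cv_pct == 0.0

    def test_scale_invariance(self, rng):
        x = rng.uniform(1, 3, 50)
        assert pm.cross_sectional_cv(x).cv_pct == pytest.approx(
            pm.cross_sectional_cv(7.3 * x).cv_pct
        )

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(InvalidParameterError):
            pm.cross_sectional_cv(np.array([-1.0, 1.0]))


class TestLevene:
    def test_identical_deviation_multisets_give_zero(self):
        g1 = np.array([1.0, 2.0, 3.0])
        g2 = np.array([11.0, 12.0, 13.0])
        res = pm.levene_test(g1, g2)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_shift_invariance(self, rng):
        g1, g2 = rng.normal(0, 1, 40), rng.normal(0, 3, 40)
        a = pm.levene_test(g1, g2)
        b = pm.levene_test(g1 + 100, g2 - 7)
        assert a.statistic == pytest.approx(b.statistic)

    def test_power_against_ninefold_variance(self):
        """N(0,1) vs N(0,9), n = 200/group: near-certain rejection."""
        rng = np.random.default_rng(21)
        reject = 0
        reps = 500
        for _ in range(reps):
            res = pm.levene_test(rng.normal(0, 1, 200), rng.normal(0, 3, 200))
            reject += res.p_value < 0.05
        assert reject / reps > 0.99

    def test_degrees_of_freedom(self):
        res = pm.levene_test(np.arange(5.0), np.arange(7.0), np.arange(4.0))
        assert (res.df1, res.df2) == (2, 13)

    def test_small_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            pm.levene_test(np.array([1.0]), np.array([1.0, 2.0]))


class TestCorrelationMatrix:
    def test_exact_linear_relation(self):
        f = pd.DataFrame({"x": [1.0, 2, 3, 4]}, index=list("abcd"))
        m = pd.DataFrame({"y": [2.0, 4, 6, 8]}, index=list("abcd"))
        out = pm.correlation_matrix(f, m)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert bool(out["significant"].iloc[0])

    def test_independent_variables_near_zero(self, rng):
        idx = [f"p{i}" for i in range(1000)]
        f = pd.DataFrame({"x": rng.standard_normal(1000)}, index=idx)
        m = pd.DataFrame({"y": rng.standard_normal(1000)}, index=idx)
        assert abs(pm.correlation_matrix(f, m)["r"].iloc[0]) < 0.1

    def test_affine_invariance(self, rng):
        idx = [f"p{i}" for i in range(50)]
        x = rng.standard_normal(50)
        y = 0.5 * x + rng.standard_normal(50)
        a = pm.correlation_matrix(
            pd.DataFrame({"x": x}, index=idx), pd.DataFrame({"y": y}, index=idx)
        )
        b = pm.correlation_matrix(
            pd.DataFrame({"x": 3 * x - 1}, index=idx),
            pd.DataFrame({"y": -2 * y + 5}, index=idx),
        )
        assert abs(a["r"].iloc[0]) == pytest.approx(abs(b["r"].iloc[0]))

    def test_planted_tg_coupling_dominates_glucose(self, small_cohort, small_cohort_features):
        g6 = small_cohort.marker_wide("glyca")[["value_6h"]]
        out = pm.correlation_matrix(
            small_cohort_features[["tg_at_6h", "glu_max1"]], g6
        ).set_index("feature")
        assert out.loc["tg_at_6h", "r"] > out.loc["glu_max1", "r"]

    def test_too_few_pairs_rejected(self):
        f = pd.DataFrame({"x": [1.0, 2]}, index=list("ab"))
        m = pd.DataFrame({"y": [1.0, 2]}, index=list("ab"))
        with pytest.raises(InsufficientDataError):
            pm.correlation_matrix(f, m)


def make_long(values_by_group):
    """Build a long participant x time table from per-group trajectories."""
    rows = []
    pid = 0
    for group, trajectories in values_by_group.items():
        for traj in trajectories:
            for t, v in zip([0, 4, 6], traj):
                rows.append({"participant_id": f"s{pid}", "time_h": t, "value": v, "group": group})
            pid += 1
    return pd.DataFrame(rows)


class TestRMInteraction:
    def test_identical_group_profiles_give_zero_interaction(self, rng):
        trajectories = [list(rng.uniform(1, 2, 3)) for _ in range(12)]
        long = make_long({"m": trajectories, "f": [list(t) for t in trajectories]})
        res = pm.rm_interaction_test(long)
        assert res["F"] == pytest.approx(0.0, abs=1e-10)
        assert res["p_value"] == pytest.approx(1.0)

    def test_matches_hand_computed_mixed_anova(self):
        """2 groups x 3 times, n = 4/group, against explicit sums of squares."""
        data = {
            "a": [[3, 4, 7], [2, 4, 6], [3, 5, 8], [4, 6, 9]],
            "b": [[4, 4, 5], [3, 3, 4], [5, 5, 5], [4, 5, 6]],
        }
        long = make_long(data)
        res = pm.rm_interaction_test(long)

        # classical two-way mixed ANOVA decomposition, computed directly
        y = np.array(data["a"] + data["b"], dtype=float)  # 8 subjects x 3 times
        groups = np.array([0] * 4 + [1] * 4)
        grand = y.mean()
        n_per, k = 4, 3
        cell = np.array([y[groups == g].mean(axis=0) for g in (0, 1)])
        group_mean = y.mean(axis=1)  # per subject
        g_mean = np.array([group_mean[groups == g].mean() for g in (0, 1)])
        t_mean = y.mean(axis=0)
        ss_inter = n_per * np.sum(
            (cell - g_mean[:, None] - t_mean[None, :] + grand) ** 2
        )
        df_inter = (2 - 1) * (k - 1)
        # error: within-subject residual after subject and time-by-group effects
        resid = y - group_mean[:, None] - cell[groups] + g_mean[groups][:, None]
        ss_err = np.sum(resid**2)
        df_err = (2 * n_per - 2) * (k - 1)
        f_oracle = (ss_inter / df_inter) / (ss_err / df_err)
        assert res["F"] == pytest.approx(f_oracle, rel=1e-9)
        assert (res["df1"], res["df2"]) == (df_inter, df_err)

    def test_planted_sex_specific_rise_detected(self):
        """A 1-SD group difference in the 6-h rise at n = 200 is detected
        (p < 0.01) in nearly every replicate."""
        rng = np.random.default_rng(77)
        hits = 0
        reps = 60
        for _ in range(reps):
            base = rng.normal(1.0, 0.2, 200)
            rise = rng.normal(0.5, 0.2, 200)
            sexes = np.repeat([0, 1], 100)
            v6 = base + rise + 0.2 * sexes  # 1 SD extra rise in one group
            v4 = base + 0.5 * rise + rng.normal(0, 0.05, 200)
            rows = []
            for i in range(200):
                for t, v in zip([0, 4, 6], [base[i], v4[i], v6[i]]):
                    rows.append(
                        {"participant_id": f"s{i}", "time_h": t, "value": v,
                         "group": "f" if sexes[i] else "m"}
                    )
            res = pm.rm_interaction_test(pd.DataFrame(rows))
            hits += res["p_value"] < 0.01
        assert hits / reps >= 0.95

    def test_incomplete_participants_dropped_and_counted(self, rng):
        trajectories = [list(rng.uniform(1, 2, 3)) for _ in range(10)]
        long = make_long({"m": trajectories, "f": trajectories})
        long = long.drop(long[(long["participant_id"] == "s0") & (long["time_h"] == 6)].index)
        res = pm.rm_interaction_test(long)
        assert res["n_dropped"] == 1
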