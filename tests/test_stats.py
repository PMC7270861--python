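"""Group assignment, outliers, ANOVA vs brute-force oracle, contrasts."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from anova_oracle import (
    mixed_anova_oracle,
    random_balanced_design,
    rm_anova_oracle,
)
from walkbeat.simulate import CohortSpec, truth_table
from walkbeat.stats import (
    assign_groups,
    baseline_table,
    compliance_rate,
    group_contrast_at_session,
    mixed_anova,
    partial_eta_sq,
    remove_outliers,
    rm_anova_within_group,
)
from walkbeat.types import ValidationError


class TestAssignGroups:
    def test_fixed_threshold(self):
        ga = assign_groups(pd.Series({"a": 50.0, "b": 100.0}), threshold=90)
        assert ga.groups["a"] == "low" and ga.groups["b"] == "high"

    def test_tie_goes_low(self):
        ga = assign_groups(pd.Series({"a": 90.0, "b": 100.0}), threshold=90)
        assert ga.groups["a"] == "low"

    def test_median_split_even_halves(self):
        gains = pd.Series(np.arange(10, dtype=float), index=[f"p{i}" for i in range(10)])
        ga = assign_groups(gains, threshold="median")
        assert (ga.groups == "high").sum() == 5
        assert (ga.groups == "low").sum() == 5

    def test_published_threshold_reproduces_simulator_labels(self):
        tt = truth_table(CohortSpec(seed=3))
        per_patient = tt.groupby("patient").agg(
            gain=("total_gain", "first"), group=("group", "first")
        )
        ga = assign_groups(per_patient["gain"], threshold=90)
        assert (ga.groups == per_patient["group"]).all()

    def test_too_few_patients(self):
        with pytest.raises(ValidationError):
            assign_groups(pd.Series({"a": 5.0}))


class TestCompliance:
    @pytest.mark.parametrize(
        "attended,expected_pct", [(9, 100.0), (0, 0.0), (8, 100 * 8 / 9)]
    )
    def test_rates(self, attended, expected_pct):
        assert compliance_rate(attended) == pytest.approx(expected_pct)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValidationError):
            compliance_rate(5, expected=0)


class TestRemoveOutliers:
    def test_gross_outlier_removed(self):
        kept, removed = remove_outliers([1, 2, 3, 4, 1000])
        assert list(removed) == [4]
        assert 1000 not in kept

    def test_all_equal_nothing_removed(self):
        kept, removed = remove_outliers([5.0] * 6)
        assert len(removed) == 0 and len(kept) == 6

    def test_in_fence_identity(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0]
        kept, removed = remove_outliers(vals)
        assert len(removed) == 0
        assert np.array_equal(kept, vals)

    def test_minimum_size(self):
        with pytest.raises(ValidationError):
            remove_outliers([1.0, 2.0, 3.0])


def _long_df(rows):
    return pd.DataFrame(rows, columns=["patient", "group", "session", "value"])


class TestMixedAnova:
    def test_identical_values_zero_f(self):
        rows = [
            (f"{g}{i}", g, t, 5.0)
            for g in ("low", "high")
            for i in range(3)
            for t in range(3)
        ]
        res = mixed_anova(_long_df(rows))
        assert all(r.F == 0.0 for r in res.values())

    def test_toy_design_matches_oracle(self):
        rng = np.random.default_rng(42)
        rows = random_balanced_design(rng)
        res = mixed_anova(_long_df(rows))
        oracle = mixed_anova_oracle(rows)
        for effect in ("group", "time", "interaction"):
            F_o, dfm, dfe = oracle[effect]
            assert res[effect].F == pytest.approx(F_o, abs=1e-9)
            assert res[effect].df_main == dfm
            assert res[effect].df_error == dfe

    def test_partial_eta_sq_printed_identity(self):
        # df 4, 212, F 5.172 -> 0.089 to two decimals
        assert partial_eta_sq(4, 212, 5.172) == pytest.approx(0.089, abs=0.0005)

    def test_unbalanced_rejected_with_patients_named(self):
        rows = [
            ("lowA", "low", 0, 1.0),
            ("lowA", "low", 1, 2.0),
            ("lowB", "low", 0, 1.5),  # missing session 1
            ("highA", "high", 0, 2.0),
            ("highA", "high", 1, 2.5),
            ("highB", "high", 0, 2.1),
            ("highB", "high", 1, 2.2),
        ]
        with pytest.raises(ValidationError, match="lowB"):
            mixed_anova(_long_df(rows))

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_property_matches_oracle(self, seed):
        rng = np.random.default_rng(seed)
        rows = random_balanced_design(rng, with_effects=bool(seed % 2))
        res = mixed_anova(_long_df(rows))
        oracle = mixed_anova_oracle(rows)
        for effect in ("group", "time", "interaction"):
            assert res[effect].F == pytest.approx(oracle[effect][0], abs=1e-9)
            r = res[effect]
            if r.F > 0:
                assert r.partial_eta_sq == pytest.approx(
                    partial_eta_sq(r.df_main, r.df_error, r.F), abs=1e-12
                )

    def test_against_pingouin(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        rows = random_balanced_design(rng)
        df = _long_df(rows)
        res = mixed_anova(df)
        pg_res = pg.mixed_anova(
            data=df, dv="value", within="session", subject="patient", between="group"
        ).set_index("Source")
        assert res["interaction"].F == pytest.approx(
            float(pg_res.loc["Interaction", "F"]), rel=1e-6
        )
        assert res["group"].F == pytest.approx(
            float(pg_res.loc["group", "F"]), rel=1e-6
        )


class TestRmAnova:
    def test_identical_values_zero_f(self):
        rows = [(f"p{i}", "low", t, 3.0) for i in range(3) for t in range(4)]
        res = rm_anova_within_group(_long_df(rows))
        assert res.F == 0.0

    def test_toy_matches_oracle(self):
        rng = np.random.default_rng(5)
        rows = [
            (f"p{i}", "low", t, float(rng.normal(t * 0.5, 1)))
            for i in range(3)
            for t in range(3)
        ]
        res = rm_anova_within_group(_long_df(rows))
        F_o, dfm, dfe = rm_anova_oracle([(p, t, v) for p, _, t, v in rows])
        assert res.F == pytest.approx(F_o, abs=1e-9)
        assert (res.df_main, res.df_error) == (dfm, dfe)

    def test_simulator_hr_peak_time_effect_by_group(self):
        """High group's truth HR_peak rises across sessions; low group's not."""
        tt = truth_table(CohortSpec(seed=21))
        tt["hr_peak_true"] = (
            tt["rest_hr_true"] + tt["b_true"] * 360 + tt["a_true"] * 360**2
        )
        rng = np.random.default_rng(0)
        tt["value"] = tt["hr_peak_true"] + rng.normal(0, 0.6, len(tt))
        ps = {}
        for g, sub in tt.groupby("group"):
            sub = sub.rename(columns={"session": "session"})[
                ["patient", "group", "session", "value"]
            ]
            ps[g] = rm_anova_within_group(sub).p
        assert ps["high"] < 0.05
        assert ps["low"] >= 0.05


class TestContrasts:
    def test_identical_groups(self):
        stat, p = group_contrast_at_session([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "t")
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_pooled_t_hand_value(self):
        stat, p = group_contrast_at_session([1, 2, 3], [4, 5, 6], "t")
        assert stat == pytest.approx(-3.674, abs=0.001)
        assert p == pytest.approx(0.0214, abs=0.0005)

    def test_mann_whitney_disjoint(self):
        stat, _ = group_contrast_at_session([1, 2], [3, 4], "mann_whitney")
        assert stat == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValidationError):
            group_contrast_at_session([1.0, 1.0], [2.0, 2.0], "t")


class TestBaselineTable:
    def test_fisher_diabetes_contrast(self):
        from scipy.stats import fisher_exact

        _, p = fisher_exact([[11, 34], [1, 43]])
        assert p < 0.01
        data = pd.DataFrame(
            {
                "group": ["low"] * 45 + ["high"] * 44,
                "diabetes": [1] * 11 + [0] * 34 + [1] * 1 + [0] * 43,
            }
        )
        tab = baseline_table(data).set_index("variable")
        assert tab.loc["diabetes", "p"] == pytest.approx(p, abs=1e-9)
        assert tab.loc["diabetes", "p"] < 0.01

    def test_equal_counts_p_one(self):
        data = pd.DataFrame(
            {"group": ["low"] * 10 + ["high"] * 10, "flag": ([1] * 5 + [0] * 5) * 2}
        )
        tab = baseline_table(data).set_index("variable")
        assert tab.loc["flag", "p"] == pytest.approx(1.0)

    def test_normal_column_mean_sd_path(self, rng):
        data = pd.DataFrame(
            {
                "group": ["low"] * 40 + ["high"] * 40,
                "distance": rng.normal(500, 90, 80),
            }
        )
        tab = baseline_table(data).set_index("variable")
        assert tab.loc["distance", "test"] == "t"
        assert "(" in tab.loc["distance", "low"]

    def test_skewed_column_median_iqr_path(self, rng):
        data = pd.DataFrame(
            {
                "group": ["low"] * 40 + ["high"] * 40,
                "skewed": np.exp(rng.normal(0, 1, 80)),
            }
        )
        tab = baseline_table(data).set_index("variable")
        assert tab.loc["skewed", "test"] == "mann_whitney"
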