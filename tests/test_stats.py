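"""Outlier removal, matched-field exclusion, ANOVA and summaries."""

import numpy as np
import pandas as pd
import pytest

from capspec.stats import (
    matched_field_exclusion,
    power_heatmap_table,
    rout_flags_by_period,
    rout_outliers,
    summarize_groups,
    two_way_anova,
)


class TestRout:
    def test_single_gross_outlier_flagged_exactly(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(1.0, 0.01, 19), [100.0]])
        mask = rout_outliers(x, 0.01)
        assert list(np.flatnonzero(mask.flags)) == [19]

    def test_q_zero_limit_flags_nothing(self):
        x = np.concatenate([np.zeros(19), [1e6]])
        assert not rout_outliers(x, 0.0).flags.any()

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError, match="10"):
            rout_outliers(np.arange(5.0), 0.01)

    def test_clean_normal_false_positive_rate(self):
        rng = np.random.default_rng(7)
        frac = np.mean(
            [rout_outliers(rng.normal(0, 1, 40), 0.01).flags.mean() for _ in range(200)]
        )
        assert frac <= 0.02  # at most 2 x Q on average

    def test_five_sigma_point_detected(self):
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(200):
            x = rng.normal(0, 1, 40)
            x[0] = 5.0
            hits += rout_outliers(x, 0.01).flags[0]
        assert hits / 200 >= 0.95


def _cohort_table(n_fov=10, values=None):
    rows = []
    rng = np.random.default_rng(0)
    for f in range(n_fov):
        for p in (1, 2, 3):
            rows.append(
                {
                    "fov_id": f"f{f}",
                    "animal_id": f"a{f % 3}",
                    "group_label": "control" if f % 2 == 0 else "FIP",
                    "imaging_period": p,
                    "value": rng.normal(1.0, 0.1) if values is None else values,
                }
            )
    return pd.DataFrame(rows)


class TestMatchedFieldExclusion:
    def test_no_flags_table_unchanged(self):
        t = _cohort_table()
        out = matched_field_exclusion(t, np.zeros(len(t), bool))
        pd.testing.assert_frame_equal(out, t)

    def test_flag_in_one_period_removes_all_periods(self):
        t = _cohort_table()
        flags = (t["fov_id"] == "f3") & (t["imaging_period"] == 2)
        out = matched_field_exclusion(t, flags)
        assert not (out["fov_id"] == "f3").any()
        assert len(out) == len(t) - 3

    def test_three_distinct_flagged_fovs_leave_21_of_30(self):
        t = _cohort_table(10)
        flags = pd.Series(False, index=t.index)
        for f, p in [("f1", 1), ("f4", 2), ("f7", 3)]:
            flags |= (t["fov_id"] == f) & (t["imaging_period"] == p)
        out = matched_field_exclusion(t, flags)
        assert len(out) == 21

    def test_idempotent(self):
        t = _cohort_table()
        flags = (t["fov_id"] == "f0") & (t["imaging_period"] == 1)
        once = matched_field_exclusion(t, flags)
        twice = matched_field_exclusion(once, np.zeros(len(once), bool))
        pd.testing.assert_frame_equal(once, twice)

    def test_rout_flags_by_period_alignment(self):
        t = _cohort_table(12)
        t.loc[
            (t["fov_id"] == "f5") & (t["imaging_period"] == 2), "value"
        ] = 50.0
        flags = rout_flags_by_period(t, q=0.01)
        assert flags.sum() == 1
        out = matched_field_exclusion(t, flags)
        assert not (out["fov_id"] == "f5").any()


def _brute_force_two_way(df):
    """Textbook balanced two-way ANOVA from raw sums of squares."""
    groups = sorted(df["group_label"].unique())
    periods = sorted(df["imaging_period"].unique())
    grand = df["value"].mean()
    n_cell = len(df) // (len(groups) * len(periods))
    ss_a = sum(
        len(periods) * n_cell * (df[df.group_label == g]["value"].mean() - grand) ** 2
        for g in groups
    )
    ss_b = sum(
        len(groups) * n_cell * (df[df.imaging_period == p]["value"].mean() - grand) ** 2
        for p in periods
    )
    ss_ab = 0.0
    ss_e = 0.0
    for g in groups:
        for p in periods:
            cell = df[(df.group_label == g) & (df.imaging_period == p)]["value"]
            ss_ab += n_cell * (
                cell.mean()
                - df[df.group_label == g]["value"].mean()
                - df[df.imaging_period == p]["value"].mean()
                + grand
            ) ** 2
            ss_e += ((cell - cell.mean()) ** 2).sum()
    df_a = len(groups) - 1
    df_b = len(periods) - 1
    df_ab = df_a * df_b
    df_e = len(df) - len(groups) * len(periods)
    mse = ss_e / df_e
    return ss_a / df_a / mse, ss_b / df_b / mse, ss_ab / df_ab / mse


class TestTwoWayAnova:
    def _toy(self):
        rows = []
        data = {
            ("control", 1): [1, 2],
            ("control", 2): [3, 4],
            ("control", 3): [5, 6],
            ("FIP", 1): [2, 3],
            ("FIP", 2): [4, 5],
            ("FIP", 3): [6, 7],
        }
        for (g, p), vals in data.items():
            for i, v in enumerate(vals):
                rows.append(
                    {
                        "fov_id": f"{g}{p}{i}",
                        "group_label": g,
                        "imaging_period": p,
                        "value": float(v),
                    }
                )
        return pd.DataFrame(rows)

    def test_balanced_toy_matches_brute_force(self):
        df = self._toy()
        res = two_way_anova(df)
        f_a, f_b, f_ab = _brute_force_two_way(df)
        assert res.f_group == pytest.approx(f_a, rel=1e-9)
        assert res.f_period == pytest.approx(f_b, rel=1e-9)
        # zero interaction SS: both routes must agree it vanishes
        assert res.f_interaction == pytest.approx(f_ab, abs=1e-9)

    def test_random_balanced_table_matches_brute_force(self):
        rng = np.random.default_rng(5)
        df = self._toy()
        df["value"] = rng.normal(0, 1, len(df))
        res = two_way_anova(df)
        f_a, f_b, f_ab = _brute_force_two_way(df)
        assert res.f_group == pytest.approx(f_a, rel=1e-9)
        assert res.f_period == pytest.approx(f_b, rel=1e-9)
        assert res.f_interaction == pytest.approx(f_ab, rel=1e-9)

    def test_identical_values_give_null_result(self):
        df = _cohort_table(6, values=2.5)
        res = two_way_anova(df)
        assert res.f_group == 0.0 and res.p_group == 1.0
        assert (res.posthoc["p_adjusted"] == 1.0).all()

    def test_bonferroni_multiplies_by_three(self):
        df = self._toy()
        res = two_way_anova(df)
        assert np.allclose(
            res.posthoc["p_adjusted"],
            np.minimum(1.0, res.posthoc["p_raw"] * 3),
        )

    def test_empty_cell_names_the_cell(self):
        df = self._toy()
        df = df[~((df.group_label == "FIP") & (df.imaging_period == 2))]
        with pytest.raises(ValueError, match="FIP.*2"):
            two_way_anova(df)


class TestSummaries:
    def test_mean_and_sem_closed_form(self):
        df = pd.DataFrame(
            {
                "fov_id": ["a", "b", "c"],
                "group_label": ["control"] * 3,
                "imaging_period": [1, 1, 1],
                "value": [1.0, 2.0, 3.0],
            }
        )
        df2 = df.copy()
        df2["group_label"] = "FIP"
        out = summarize_groups(pd.concat([df, df2]))
        row = out[out.group_label == "control"].iloc[0]
        assert row["mean"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(0.57735, abs=1e-5)

    def test_constant_cell_sem_zero(self):
        df = _cohort_table(4, values=1.0)
        out = summarize_groups(df)
        assert (out["sem"] == 0).all()

    def test_single_observation_warns_nan_sem(self):
        df = pd.DataFrame(
            {
                "fov_id": ["a"],
                "group_label": ["control"],
                "imaging_period": [1],
                "value": [1.0],
            }
        )
        with pytest.warns(UserWarning, match="n=1"):
            out = summarize_groups(df)
        assert np.isnan(out["sem"].iloc[0])


class TestHeatmapTable:
    def test_two_fovs_three_periods(self):
        t = _cohort_table(2)
        pivot = power_heatmap_table(t)
        assert pivot.shape == (2, 3)

    def test_missing_cell_marked_nan(self):
        t = _cohort_table(2).iloc[:-1]
        pivot = power_heatmap_table(t)
        assert pivot.shape == (2, 3)
        assert pivot.isna().sum().sum() == 1

    def test_duplicate_entry_rejected(self):
        t = _cohort_table(2)
        t = pd.concat([t, t.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            power_heatmap_table(t)

    def test_rows_ordered_by_animal_then_fov(self):
        t = _cohort_table(6).sample(frac=1.0, random_state=0)
        pivot = power_heatmap_table(t)
        assert list(pivot.index) == sorted(pivot.index)
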