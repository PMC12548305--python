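import numpy as np
import pandas as pd
import pytest
from scipy import stats

import optofear as of
from optofear.behavior_stats import (
    comparisons_to_frame,
    extinction_filter,
    planned_ttest,
    pool_controls_check,
    stage_means,
    t_to_p,
    timecourse_compare,
)


class TestTtoP:
    def test_zero_t_gives_one(self):
        assert t_to_p(0.0, 12) == 1.0

    def test_df_below_one_rejected(self):
        with pytest.raises(of.InvalidParameterError):
            t_to_p(1.0, 0)

    def test_symmetric_and_decreasing_in_magnitude(self):
        assert t_to_p(2.0, 10) == t_to_p(-2.0, 10)
        ts = np.linspace(0.1, 5.0, 30)
        ps = [t_to_p(t, 10) for t in ts]
        assert np.all(np.diff(ps) < 0)

    def test_limits_to_normal_for_large_df(self):
        t = 1.7
        normal = 2 * stats.norm.sf(t)
        assert t_to_p(t, 10**6) == pytest.approx(normal, rel=1e-4)


class TestPlannedTtest:
    def test_identical_groups(self):
        c = planned_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert c.t == 0.0
        assert c.p == 1.0

    def test_hand_computed_example(self):
        # pooled var = 1, diff = -2, t = -2/sqrt(2/3) = -2.449, df = 4
        c = planned_ttest([1, 2, 3], [3, 4, 5])
        assert c.t == pytest.approx(-2.449, abs=5e-4)
        assert c.df == 4
        assert c.p == pytest.approx(0.0705, abs=5e-4)

    def test_matches_scipy_student_t(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 9), rng.normal(0.5, 1, 13)
        c = planned_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert c.t == pytest.approx(ref.statistic)
        assert c.p == pytest.approx(ref.pvalue)

    def test_df_is_pooled(self):
        c = planned_ttest(np.arange(7.0), np.arange(7.0) + 0.5)
        assert c.df == 12

    def test_degenerate_zero_variance_unequal_means(self):
        with pytest.raises(of.InvalidParameterError):
            planned_ttest([1.0, 1.0], [2.0, 2.0])

    def test_matches_permutation_oracle(self):
        """Student-t p agrees with a label-permutation null on small groups.

        The permutation null of an 8-vs-8 comparison and the Student t
        differ systematically by a few thousandths in the tail; agreement to
        0.005 absolute is the attainable level for this check.
        """
        rng = np.random.default_rng(7)
        a = np.array([50.0, 53.0, 47.3, 41.1, 45.5, 40.1, 50.6, 63.4])
        b = np.array([53.1, 51.8, 62.9, 61.6, 59.1, 48.7, 57.7, 65.0])
        c = planned_ttest(a, b)
        pooled = np.concatenate([a, b])
        n_perm = 100_000
        idx = np.argsort(rng.random((n_perm, pooled.size)), axis=1)
        perm = pooled[idx]
        pa, pb = perm[:, : a.size], perm[:, a.size:]
        va = pa.var(axis=1, ddof=1) * (a.size - 1)
        vb = pb.var(axis=1, ddof=1) * (b.size - 1)
        sp = np.sqrt((va + vb) / (a.size + b.size - 2) * (1 / a.size + 1 / b.size))
        t_perm = (pa.mean(axis=1) - pb.mean(axis=1)) / sp
        p_perm = np.mean(np.abs(t_perm) >= abs(c.t) - 1e-12)
        assert abs(c.p - p_perm) < 0.005


class TestStageMeans:
    @staticmethod
    def table(rows):
        return pd.DataFrame(rows, columns=["animal_id", "group", "stage", "percent_freezing"])

    def test_cs_1_4_average(self):
        rows = [("r1", "ChR2", f"CS{k}", v) for k, v in zip(range(1, 5), (80, 60, 40, 20))]
        out = stage_means(self.table(rows), {"CS_1_4": ["CS1", "CS2", "CS3", "CS4"]})
        assert out.loc[0, "percent_freezing"] == 50.0

    def test_single_epoch_stage_passthrough(self):
        out = stage_means(
            self.table([("r1", "ChR2", "baseline", 33.0)]), {"baseline": ["baseline"]}
        )
        assert out.loc[0, "percent_freezing"] == 33.0

    def test_missing_epoch_excludes_animal(self, caplog):
        rows = [("r1", "ChR2", "CS1", 50.0), ("r1", "ChR2", "CS2", 60.0),
                ("r2", "ChR2", "CS1", 70.0)]
        with caplog.at_level("WARNING", logger="optofear"):
            out = stage_means(self.table(rows), {"CS_1_2": ["CS1", "CS2"]})
        assert list(out["animal_id"]) == ["r1"]
        assert "r2" in caplog.text

    def test_unknown_epoch_lists_vocabulary(self):
        with pytest.raises(of.InvalidParameterError, match="vocabulary"):
            stage_means(self.table([("r1", "ChR2", "CS1", 50.0)]), {"x": ["CS9"]})


class TestExtinctionFilter:
    def test_criterion_reached_on_day_three(self):
        rec, = extinction_filter({"r1": (80, 70, 59)})
        assert rec.days_to_criterion == 3
        assert rec.included

    def test_seven_days_above_threshold_excluded(self):
        rec, = extinction_filter({"r1": (80, 75, 70, 68, 65, 62, 60)})
        assert rec.days_to_criterion is None
        assert not rec.included

    def test_strictly_below_sixty(self):
        rec, = extinction_filter({"r1": (59.9,)})
        assert rec.days_to_criterion == 1
        assert rec.included
        rec, = extinction_filter({"r2": (60.0,)})
        assert not rec.included

    def test_late_criterion_day_excluded(self):
        rec, = extinction_filter({"r1": (80, 80, 80, 80, 80, 80, 80, 55)})
        assert rec.days_to_criterion == 8
        assert not rec.included

    def test_empty_records_rejected(self):
        with pytest.raises(of.InvalidParameterError):
            extinction_filter({})


class TestPoolControls:
    def test_identical_controls_pooled(self):
        spec = of.FreezingEffectSpec(stage_sd=5.0, laser_stage_delta=20.0, seed=0)
        table = of.gen_freezing_dataset(spec, "ABA")
        comparisons, pooled_table, pooled = pool_controls_check(table)
        assert pooled
        assert set(pooled_table["group"]) == {"ChR2", "pooled_control"}
        # no animal lost in pooling
        assert len(pooled_table) == len(table)
        assert pooled_table["animal_id"].nunique() == table["animal_id"].nunique()

    def test_divergent_controls_not_pooled(self):
        # oracle: means 10 vs 90 at sd 5 with n = 8/8 is overwhelmingly significant
        rng = np.random.default_rng(0)
        rows = []
        for group, mu in (("control_GFP", 10.0), ("control_nolaser", 90.0)):
            for i in range(8):
                rows.append((f"{group}_{i}", group, "CS", float(np.clip(rng.normal(mu, 5), 0, 100))))
        rows += [(f"ChR2_{i}", "ChR2", "CS", 50.0 + i) for i in range(8)]
        table = pd.DataFrame(rows, columns=["animal_id", "group", "stage", "percent_freezing"])
        comparisons, out, pooled = pool_controls_check(table)
        assert not pooled
        assert comparisons[0].p < 0.05
        assert set(out["group"]) == {"ChR2", "control_GFP", "control_nolaser"}

    def test_missing_control_group_rejected(self):
        table = pd.DataFrame(
            [("r1", "control_GFP", "CS", 10.0), ("r2", "control_GFP", "CS", 12.0)],
            columns=["animal_id", "group", "stage", "percent_freezing"],
        )
        with pytest.raises(of.InvalidParameterError, match="control_nolaser"):
            pool_controls_check(table)


class TestTimecourseCompare:
    @staticmethod
    def pooled_table(delta, seed):
        # pool by construction: this class tests the timecourse machinery,
        # not the pooling decision (which is tested above)
        spec = of.FreezingEffectSpec(laser_stage_delta=delta, seed=seed)
        table = of.gen_freezing_dataset(spec, "ABA")
        table.loc[table["group"] != "ChR2", "group"] = "pooled_control"
        return table

    def test_effect_found_at_laser_stage(self):
        table = self.pooled_table(delta=25.0, seed=2)
        comparisons = timecourse_compare(table, ["baseline_laser"])
        assert comparisons[0].p < 0.05
        assert comparisons[0].mean_a < comparisons[0].mean_b  # ChR2 freezes less

    def test_holm_correction_never_below_raw(self):
        table = self.pooled_table(delta=20.0, seed=3)
        stages = list(table["stage"].unique())
        raw = timecourse_compare(table, stages, correction="none")
        holm = timecourse_compare(table, stages, correction="holm")
        for r, h in zip(raw, holm):
            assert h.p_corrected >= r.p - 1e-12

    def test_unknown_stage_rejected(self):
        table = self.pooled_table(delta=0.0, seed=4)
        with pytest.raises(of.InvalidParameterError, match="vocabulary"):
            timecourse_compare(table, ["no_such_stage"])

    def test_frame_export_columns(self):
        table = self.pooled_table(delta=20.0, seed=5)
        frame = comparisons_to_frame(timecourse_compare(table, ["baseline_laser", "CS"]))
        assert list(frame["stage"]) == ["baseline_laser", "CS"]
        assert {"t", "df", "p"} <= set(frame.columns)
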