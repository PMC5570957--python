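"""Screening layer: layout, scheduler, effect estimation, hit calling, time courses."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import fretscreen as fs
from fretscreen.screening import (
    CompoundEffect,
    PlateLayout,
    aging_trajectory,
    dose_response,
    schedule,
    summarize_well,
    two_group_timecourse,
    welch_test,
)
from fretscreen.simulate import NO_QC


def cohort_df(peaks, well="B2", role="compound", day=12, group=None, conc=None):
    df = pd.DataFrame(
        {
            "well": well,
            "role": role,
            "compound": "x" if role == "compound" else "",
            "age_day": day,
            "qc": "analyzed",
            "peak_pct": np.asarray(peaks, dtype=float),
            "slope_pct_s": np.asarray(peaks, dtype=float) / 10.0,
        }
    )
    if group is not None:
        df["group"] = group
    if conc is not None:
        df["concentration_uM"] = conc
    return df


class TestPhaseBin:
    @pytest.mark.parametrize(
        "day,phase",
        [(2, "early"), (5, "early"), (6, "early"), (7, "mid"), (8, "mid"),
         (9, "late"), (18, "late")],
    )
    def test_day_phase_mapping(self, day, phase):
        assert fs.phase_bin(day) == phase


class TestPlateLayout:
    def test_default_library_plate_geometry(self):
        layout = PlateLayout.default_library([f"c{i}" for i in range(54)])
        assert len(layout.compound_wells()) == 54
        assert layout.control_wells() == [f"{r}11" for r in "BCDEFG"]
        # edge wells carry only assay medium
        for well in ("A1", "A12", "H5", "B1", "G12"):
            assert layout.role(well) == "medium_only"
        assert layout.concentration("B2") == 20.0
        assert layout.vehicle == "0.4% DMSO"

    def test_too_many_compounds_rejected(self):
        with pytest.raises(ValueError):
            PlateLayout.default_library([f"c{i}" for i in range(55)])

    def test_library_series_holds_107(self):
        plates = PlateLayout.library_series([f"c{i}" for i in range(107)])
        assert len(plates) == 2
        assert sum(len(p.compound_wells()) for p in plates) == 107

    def test_yaml_roundtrip(self, tmp_path):
        layout = PlateLayout.default_library(["a", "b", "c"])
        layout.to_yaml(tmp_path / "layout.yaml")
        restored = PlateLayout.from_yaml(tmp_path / "layout.yaml")
        assert restored.roles == layout.roles
        assert restored.compounds == layout.compounds


class TestScheduler:
    def test_exact_blocks_of_nine(self):
        layout = PlateLayout.default_library([f"c{i}" for i in range(18)])
        plan = [p for p in schedule(layout, controls_every=9) if p.kind == "well"]
        roles = [p.role for p in plan]
        assert roles == ["compound"] * 9 + ["vehicle_control"] + ["compound"] * 9 + [
            "vehicle_control"
        ]

    def test_107_wells_get_12_control_visits(self):
        plates = PlateLayout.library_series([f"c{i}" for i in range(107)])
        plan = [p for p in schedule(plates, controls_every=9) if p.kind == "well"]
        comp = [p.well for p in plan if p.role == "compound"]
        assert len(comp) == 107 and len(set((p.plate, w) for p, w in
                                            [(x, x.well) for x in plan if x.role == "compound"])) == 107
        assert sum(1 for p in plan if p.role == "vehicle_control") == 12

    def test_strict_alternation(self):
        layout = PlateLayout.default_library(["a", "b", "c"])
        roles = [p.role for p in schedule(layout, controls_every=1) if p.kind == "well"]
        assert roles == ["compound", "vehicle_control"] * 3

    def test_medium_only_never_scheduled(self):
        layout = PlateLayout.default_library([f"c{i}" for i in range(20)])
        for item in schedule(layout):
            assert item.kind == "wash" or layout.role(item.well) != "medium_only"

    def test_wash_events_every_n_worms(self):
        layout = PlateLayout.default_library([f"c{i}" for i in range(4)])
        plan = schedule(layout, controls_every=9, wash_every_n_worms=7, worms_per_well=5)
        washes = sum(1 for p in plan if p.kind == "wash")
        total_worms = 5 * sum(1 for p in plan if p.kind == "well")
        assert washes == total_worms // 7

    def test_controls_every_must_be_positive(self):
        layout = PlateLayout.default_library(["a"])
        with pytest.raises(ValueError):
            schedule(layout, controls_every=0)

    def test_no_controls_rejected(self):
        layout = PlateLayout({"B2": "compound"}, {"B2": "a"})
        with pytest.raises(ValueError):
            schedule(layout)


class TestWellSummary:
    def test_mean_and_sem_arithmetic(self):
        s = summarize_well(cohort_df([10.0, 20.0, 30.0]))
        assert s.mean_peak == pytest.approx(20.0)
        assert s.sem_peak == pytest.approx(10.0 / np.sqrt(3.0))
        assert s.n_analyzed == 3 and not s.empty

    def test_all_discarded_gives_empty_summary(self):
        df = cohort_df([np.nan, np.nan])
        df["qc"] = "tail_entry"
        s = summarize_well(df)
        assert s.empty and s.n_analyzed == 0
        assert s.n_discarded == {"tail_entry": 2}

    def test_cv0_cohort_mean_is_exact(self, timing):
        rng = np.random.default_rng(0)
        peaks = fs.draw_peak_cohort(10, rng, mean_amplitude=0.3, cv=0.0)
        s = summarize_well(cohort_df(peaks))
        unit_peak, _ = fs.unit_metrics()
        assert s.mean_peak == pytest.approx(0.3 * unit_peak, rel=1e-12)


class TestWelch:
    def test_matches_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a = rng.normal(10, 2, rng.integers(3, 30))
            b = rng.normal(11, 3, rng.integers(3, 30))
            t, df, p = welch_test(a, b)
            ref = stats.ttest_ind(a, b, equal_var=False)
            assert t == pytest.approx(ref.statistic, rel=1e-12)
            assert p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_identical_groups_p_one(self):
        a = np.array([5.0, 5.0, 5.0])
        t, df, p = welch_test(a, a)
        assert t == 0.0 and p == 1.0


class TestCompoundEffect:
    def test_identical_groups_no_effect(self):
        rng = np.random.default_rng(2)
        x = rng.normal(30, 5, 20)
        eff = fs.compound_effect(x, x.copy())
        assert eff.effect_pct == pytest.approx(0.0, abs=1e-12)
        assert eff.classification == "none"

    def test_cv0_ratio_recovers_multiplier(self):
        """A +55.6% configured multiplier is recovered as a +55.6% effect."""
        rng = np.random.default_rng(3)
        control = fs.draw_peak_cohort(10, rng, cv=0.0)
        treated = fs.draw_peak_cohort(10, rng, cv=0.0, effect=0.556)
        eff = fs.compound_effect(treated, control)
        assert eff.effect_pct == pytest.approx(55.6, rel=1e-9)

    def test_negative_effect_arithmetic(self):
        eff = fs.compound_effect(np.array([6.0, 6.0, 6.0]), np.array([10.0, 10.0, 10.0]))
        assert eff.effect_pct == pytest.approx(-40.0)

    def test_age_mismatch_rejected(self):
        treated = cohort_df([10, 12, 14], day=12)
        control = cohort_df([10, 12, 14], well="B11", role="vehicle_control", day=7)
        with pytest.raises(ValueError):
            fs.compound_effect(treated, control)

    def test_nonpositive_control_mean_rejected(self):
        with pytest.raises(ValueError):
            fs.compound_effect(np.array([1.0, 2.0]), np.array([-1.0, 1.0]))

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            fs.compound_effect(np.array([1.0]), np.array([2.0, 3.0]))

    def test_dual_action_requires_both_metrics_up(self):
        rng = np.random.default_rng(4)
        control = cohort_df(rng.normal(20, 2, 20), well="B11", role="vehicle_control")
        treated = cohort_df(rng.normal(32, 2, 20))
        eff = fs.compound_effect(treated, control)
        assert eff.classification == "positive" and eff.dual_action


class TestCallHits:
    def _effect(self, e, p):
        return CompoundEffect(
            compound=f"c{e}", effect_pct=e, effect_slope_pct=np.nan, p_value=p,
            p_slope=np.nan, classification=CompoundEffect.classify(e, p, 0.05),
            dual_action=False, n_treated=10, n_control=10,
        )

    def test_all_p_one_everything_none(self):
        effects = [self._effect(e, 1.0) for e in (-30.0, 0.0, 40.0)]
        summary = fs.call_hits(effects)
        assert summary.counts == {"positive": 0, "negative": 0, "none": 3}
        assert sum(summary.fractions.values()) == pytest.approx(1.0)

    def test_classification_coherence(self):
        rng = np.random.default_rng(5)
        effects = [self._effect(float(rng.normal(0, 30)), float(rng.uniform(0, 0.2)))
                   for _ in range(50)]
        summary = fs.call_hits(effects, alpha=0.05)
        for e in summary.positives:
            assert e.effect_pct > 0 and e.p_value < 0.05
        for e in summary.negatives:
            assert e.effect_pct < 0 and e.p_value < 0.05
        for e in summary.no_effect:
            assert e.p_value >= 0.05 or e.effect_pct == 0

    def test_bh_adjustment_demotes_marginal_hits(self):
        """One marginal raw hit among many clear nulls does not survive BH."""
        effects = ([self._effect(30.0, 0.001), self._effect(25.0, 0.04)]
                   + [self._effect(5.0, 0.9) for _ in range(8)])
        raw = fs.call_hits([CompoundEffect(**vars(e)) for e in effects], 0.05, "none")
        adj = fs.call_hits(effects, 0.05, "bh")
        assert raw.counts["positive"] == 2
        assert adj.counts["positive"] == 1
        for e in adj.positives + adj.negatives + adj.no_effect:
            assert e.p_adj is not None


class TestAgingTrajectory:
    def test_null_distribution_rejection_rate(self):
        rng = np.random.default_rng(6)
        rejections = 0
        reps = 100
        for _ in range(reps):
            rec = pd.concat(
                [cohort_df(rng.normal(25, 6, 12), day=d) for d in (3, 7, 12, 18)]
            )
            res = aging_trajectory(rec)
            rejections += res.anova_p_peak < 0.05
        assert rejections / reps <= 0.12   # ~alpha with binomial slack

    def test_rise_then_fall_profile_recovered(self):
        """Responses rise into mid adulthood and decline late; contrasts detect both."""
        rng = np.random.default_rng(7)
        rec = fs.simulate_aging_cohorts(
            {3: 0.25, 7: 0.40, 18: 0.15}, n_per_day=40, cv=0.3, rng=rng
        )
        res = aging_trajectory(rec, contrasts=[(7, 3), (18, 7)])
        per_day = res.per_day.set_index("age_day")
        assert per_day.loc[7, "mean_peak"] > per_day.loc[3, "mean_peak"]
        assert per_day.loc[18, "mean_peak"] < per_day.loc[7, "mean_peak"]
        assert res.anova_p_peak < 1e-6
        pair = res.pairwise.set_index(["day_a", "day_b"])
        assert pair.loc[(7, 3), "p_peak"] < 0.001
        assert pair.loc[(18, 7), "p_peak"] < 0.001
        assert list(per_day["phase"]) == ["early", "mid", "late"]
        # Day-18 responses decline by more than half from the mid-phase maximum
        assert per_day.loc[18, "mean_peak"] < 0.5 * per_day.loc[7, "mean_peak"]

    def test_single_day_rejected(self):
        rec = cohort_df(np.arange(10.0), day=5)
        with pytest.raises(ValueError):
            aging_trajectory(rec)

    def test_underpowered_days_excluded(self):
        rng = np.random.default_rng(8)
        rec = pd.concat(
            [cohort_df(rng.normal(25, 5, 12), day=3),
             cohort_df(rng.normal(25, 5, 12), day=7),
             cohort_df([20.0], day=9)]
        )
        res = aging_trajectory(rec)
        assert res.excluded_days == [9]
        assert set(res.per_day["age_day"]) == {3, 7}


class TestTwoGroupTimecourse:
    def test_null_rarely_flags_any_day(self):
        rng = np.random.default_rng(9)
        plates_with_flag = 0
        reps = 40
        for _ in range(reps):
            frames = []
            for d in (3, 7, 12):
                frames.append(cohort_df(rng.normal(25, 6, 15), day=d, group="control"))
                frames.append(cohort_df(rng.normal(25, 6, 15), day=d, group="treated"))
            res = two_group_timecourse(pd.concat(frames))
            plates_with_flag += res.per_day["significant"].any()
        # Bonferroni keeps the family-wise rate at ~alpha
        assert plates_with_flag / reps <= 0.15

    def test_late_phase_effect_flagged_only_late(self):
        rng = np.random.default_rng(10)
        hits_late, hits_early = 0, 0
        reps = 20
        for _ in range(reps):
            frames = []
            for d in (3, 7, 12, 14):
                frames.append(cohort_df(rng.normal(25, 6, 30), day=d, group="control"))
                bump = 1.4 if d >= 9 else 1.0
                frames.append(cohort_df(rng.normal(25 * bump, 6 * bump, 30), day=d,
                                        group="treated"))
            res = two_group_timecourse(pd.concat(frames))
            flagged = set(res.per_day.loc[res.per_day["significant"], "age_day"])
            hits_late += {12, 14} <= flagged
            hits_early += bool(flagged & {3, 7})
        assert hits_late / reps >= 0.8
        assert hits_early / reps <= 0.2

    def test_single_day_degenerates_to_two_group(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(25, 4, 15), rng.normal(32, 4, 15)
        rec = pd.concat([cohort_df(a, day=12, group="control"),
                         cohort_df(b, day=12, group="treated")])
        res = two_group_timecourse(rec)
        _, _, p_ref = welch_test(b, a)
        assert res.per_day.loc[0, "p_bonferroni"] == pytest.approx(p_ref)  # factor 1
        assert len(res.anova) == 0

    def test_incomplete_day_dropped(self):
        rng = np.random.default_rng(12)
        rec = pd.concat([
            cohort_df(rng.normal(25, 4, 10), day=3, group="control"),
            cohort_df(rng.normal(25, 4, 10), day=3, group="treated"),
            cohort_df(rng.normal(25, 4, 10), day=7, group="control"),
        ])
        res = two_group_timecourse(rec)
        assert res.dropped_days == [7]


class TestDoseResponse:
    def test_null_doses_rarely_flagged(self):
        rng = np.random.default_rng(13)
        flags = 0
        reps = 50
        for _ in range(reps):
            rec = pd.concat([cohort_df(rng.normal(25, 5, 15), conc=c)
                             for c in (0.0, 10.0, 20.0, 40.0)])
            res = dose_response(rec)
            flags += int(res.per_dose["significant"].sum())
        assert flags / (reps * 3) <= 0.10

    def test_single_active_dose_flagged(self):
        rng = np.random.default_rng(14)
        rec = pd.concat([
            cohort_df(rng.normal(25, 5, 25), conc=0.0),
            cohort_df(rng.normal(25, 5, 25), conc=10.0),
            cohort_df(rng.normal(37, 5, 25), conc=20.0),
            cohort_df(rng.normal(25, 5, 25), conc=40.0),
        ])
        res = dose_response(rec)
        by_dose = res.per_dose.set_index("concentration_uM")
        assert bool(by_dose.loc[20.0, "significant"])
        assert not bool(by_dose.loc[10.0, "significant"])
        assert not bool(by_dose.loc[40.0, "significant"])
        assert res.anova_p < 0.01

    def test_missing_vehicle_rejected(self):
        rec = cohort_df(np.arange(10.0), conc=20.0)
        with pytest.raises(ValueError):
            dose_response(rec)

    def test_vehicle_plus_one_dose_matches_two_group_test(self):
        rng = np.random.default_rng(15)
        a, b = rng.normal(25, 4, 15), rng.normal(30, 4, 15)
        rec = pd.concat([cohort_df(a, conc=0.0), cohort_df(b, conc=20.0)])
        res = dose_response(rec)
        _, _, p_ref = welch_test(b, a)
        assert res.per_dose.set_index("concentration_uM").loc[20.0, "p_vs_vehicle"] == \
            pytest.approx(p_ref)
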