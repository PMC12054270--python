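"""Cohort generator: marginal moments, missingness rates, event times."""

import numpy as np
import pytest
from dataclasses import replace
from scipy.special import logit

import nestmi as nm
from nestmi.panel import Mechanism, col
from nestmi.simgen import MarModel, MarSpec, dichotomize_at_quantile


class TestDichotomize:
    def test_rank_arithmetic(self):
        out = dichotomize_at_quantile(np.arange(1.0, 11.0), 0.2)
        assert out.sum() == 2
        assert out[-2:].tolist() == [1.0, 1.0]

    def test_symmetric_half(self):
        latent = np.concatenate([-np.arange(1, 51), np.arange(1, 51)])
        assert dichotomize_at_quantile(latent, 0.5).mean() == 0.5

    def test_threshold_matches_normal_quantile(self):
        latent = np.random.default_rng(5).standard_normal(10_000)
        out = dichotomize_at_quantile(latent, 0.3)
        threshold = latent[out == 0].max()
        assert abs(threshold - 0.5244) < 0.05

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dichotomize_at_quantile(np.ones(10), 0.5)


class TestFullPanel:
    def test_independence_case(self):
        spec = nm.default_cohort_spec(10_000)
        spec = replace(
            spec,
            within_corr={v: 0.0 for v in spec.variables},
            between_corr=0.0,
            covariate_corr=0.0,
        )
        panel = nm.generate_full_panel(spec, seed=2)
        sub = panel.data[[col("BMI", 1), col("SBP", 1), col("TC", 3), col("BMI", 4)]]
        corr = sub.corr().to_numpy()
        off = corr[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 3 / np.sqrt(10_000))

    def test_means_match_generating_parameters(self):
        spec = nm.default_cohort_spec(10_000)
        panel = nm.generate_full_panel(spec, seed=3)
        for v in ("BMI", "SBP", "TC"):
            for t in panel.times():
                mu, sd = spec.means[v][t - 1], spec.sds[v][t - 1]
                assert abs(panel.data[col(v, t)].mean() - mu) < 3 * sd / np.sqrt(10_000)

    def test_smoking_prevalence(self):
        spec = nm.default_cohort_spec(10_000)
        panel = nm.generate_full_panel(spec, seed=4)
        se = np.sqrt(0.22 * 0.78 / 10_000)
        for t in panel.times():
            assert abs(panel.data[col("SMK", t)].mean() - 0.22) < 3 * se + 1e-4

    def test_default_correlation_is_positive_definite(self):
        R = nm.default_cohort_spec(10).correlation_matrix()
        assert np.all(np.linalg.eigvalsh(R) > 0)

    def test_non_pd_assembly_names_blocks(self):
        spec = nm.default_cohort_spec(10)
        spec = replace(spec, between_corr=0.9, within_corr={v: 0.05 for v in spec.variables})
        with pytest.raises(ValueError, match="between_corr"):
            spec.validate()

    def test_decreasing_means_rejected(self):
        spec = nm.default_cohort_spec(10)
        bad = dict(spec.means)
        bad["BMI"] = (27.0, 26.0, 27.0, 27.0, 27.0)
        with pytest.raises(ValueError, match="non-decreasing"):
            replace(spec, means=bad).validate()


class TestMarMissingness:
    def test_degenerate_intercept_yields_no_missingness(self, small_panel):
        spec = MarSpec(
            item_models={"BMI": MarModel(intercepts=(-50.0,) * 4)},
            wave_model=MarModel(intercepts=(-50.0,) * 4),
        )
        mask = nm.generate_mar_missingness(small_panel, spec, seed=1)
        assert mask.counts()["MAR"] == 0

    def test_intercept_only_rate(self):
        panel = nm.generate_full_panel(nm.default_cohort_spec(20_000), seed=6)
        spec = MarSpec(
            item_models={"BMI": MarModel(intercepts=(float(logit(0.05)),) * 4)},
            wave_model=MarModel(intercepts=(-50.0,) * 4),
        )
        mask = nm.generate_mar_missingness(panel, spec, seed=2)
        group = np.arange(panel.n_subjects) < panel.n_subjects // 2
        n_half = group.sum()
        for t in range(2, 6):
            rate = (mask.codes[col("BMI", t)].to_numpy()[group] == Mechanism.MAR).mean()
            assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / n_half)

    def test_default_rates_match_study_conditions(self):
        """Cohort-wide item rates ~5/3/8/9% and waves ~5/4/8/11% at t=2..5."""
        panel = nm.generate_full_panel(nm.default_cohort_spec(20_000), seed=7)
        mask = nm.generate_mar_missingness(panel, nm.default_mar_spec(), seed=3)
        n = panel.n_subjects
        wave_expect = (0.05, 0.04, 0.08, 0.11)
        item_expect = (0.05, 0.03, 0.08, 0.09)
        for j, t in enumerate(range(2, 6)):
            wave = (mask.codes[col("SBP", t)].to_numpy() == Mechanism.MAR).mean()
            assert abs(wave - wave_expect[j]) < 3 * np.sqrt(wave_expect[j] / n) + 0.005
            bmi = (mask.codes[col("BMI", t)].to_numpy() == Mechanism.MAR).mean()
            # BMI carries the item rate on top of wave non-attendance
            target = wave_expect[j] + item_expect[j] * (1 - wave_expect[j])
            assert abs(bmi - target) < 3 * np.sqrt(target / n) + 0.01

    def test_unknown_variable_rejected(self, small_panel):
        spec = MarSpec(
            item_models={"XYZ": MarModel(intercepts=(-1.0,) * 4)},
            wave_model=MarModel(intercepts=(-50.0,) * 4),
        )
        with pytest.raises(ValueError, match="unknown variable"):
            nm.generate_mar_missingness(small_panel, spec, seed=1)


class TestMnarNonattendance:
    def test_zero_probability_yields_no_cells(self, small_panel):
        sc = nm.MnarScenario(scenario_id=1, nonattend_prob=0.0)
        mask = nm.generate_mnar_nonattendance(small_panel, sc, seed=1)
        assert mask.counts()["MNAR"] == 0

    def test_rule_mode_wave_rates(self):
        panel = nm.generate_full_panel(nm.default_cohort_spec(20_000), seed=8)
        sc = nm.MnarScenario(scenario_id=1)
        mask = nm.generate_mnar_nonattendance(panel, sc, seed=2)
        group = np.arange(panel.n_subjects) >= panel.n_subjects // 2
        n_half = int(group.sum())
        for j, t in enumerate(range(2, 6)):
            expected = sc.percentile_schedule[j] * 0.8
            rate = (mask.codes[col("SBP", t)].to_numpy()[group] == Mechanism.MNAR).mean()
            se = np.sqrt(0.16 * sc.percentile_schedule[j] / n_half)
            assert abs(rate - expected) < 3 * se

    def test_scenario3_flags_both_tails_only(self, small_panel):
        sc = nm.MnarScenario(scenario_id=3, nonattend_prob=0.8)
        mask = nm.generate_mnar_nonattendance(small_panel, sc, seed=3)
        comp = nm.build_composite(small_panel)
        group = np.arange(small_panel.n_subjects) >= small_panel.n_subjects // 2
        for j, t in enumerate(range(2, 6)):
            flagged = mask.codes[col("SBP", t)].to_numpy() == Mechanism.MNAR
            scores = comp.loc[:, t].to_numpy()
            gscores = scores[group]
            frac = sc.percentile_schedule[j] / 2
            lo = np.quantile(gscores, frac + 0.05)
            hi = np.quantile(gscores, 1 - frac - 0.05)
            hit = scores[flagged]
            assert np.all((hit <= lo) | (hit >= hi))

    def test_first_time_point_always_observed(self, masked_panel):
        panel, mask = masked_panel
        for v in panel.variables:
            assert (mask.codes[col(v, 1)] == Mechanism.OBS).all()

    def test_schedule_length_checked(self, small_panel):
        sc = nm.MnarScenario(scenario_id=1, percentile_schedule=(0.1, 0.2))
        with pytest.raises(ValueError, match="length"):
            nm.generate_mnar_nonattendance(small_panel, sc, seed=1)


class TestEventTimes:
    def test_single_interval_closed_form(self):
        spec = nm.default_cohort_spec(20_000)
        panel = nm.generate_full_panel(spec, seed=9)
        surv = nm.SurvivalSpec(
            interval_hazards=(0.05,), covariate_log_hrs=(0.0, 0.0), log_hr_truth=0.0,
            interval_length=5.0,
        )
        ev = nm.generate_event_times(panel, surv, seed=4)
        expect = 1 - np.exp(-0.05 * 5)
        assert abs(ev.event_indicator.mean() - expect) < 3 * np.sqrt(expect * (1 - expect) / 20_000)

    def test_hazard_ratio_arithmetic(self):
        assert np.isclose(0.85**5 / 0.85**0, 0.4437, atol=1e-4)
        g1 = np.log(0.85)
        assert np.isclose(np.exp(g1 * 5) / np.exp(g1 * 0), 0.85**5)

    def test_default_cumulative_mortality_near_40pct(self):
        panel = nm.generate_full_panel(nm.default_cohort_spec(20_000), seed=10)
        ev = nm.generate_event_times(panel, nm.default_survival_spec(), seed=5)
        assert 0.3 < ev.event_indicator.mean() < 0.5

    def test_km_matches_piecewise_survivor_when_null(self):
        """With no covariate effects the KM curve tracks the closed form."""
        from lifelines import KaplanMeierFitter

        panel = nm.generate_full_panel(nm.default_cohort_spec(5_000), seed=11)
        hazards = (0.02, 0.03, 0.04, 0.05, 0.06)
        surv = nm.SurvivalSpec(
            interval_hazards=hazards, covariate_log_hrs=(0.0, 0.0), log_hr_truth=0.0
        )
        ev = nm.generate_event_times(panel, surv, seed=6)
        km = KaplanMeierFitter().fit(ev.event_time, ev.event_indicator)
        for t_idx in range(1, 6):
            boundary = 5.0 * t_idx - 1e-9
            s_true = np.exp(-5.0 * sum(hazards[:t_idx]))
            s_km = float(km.survival_function_at_times(boundary).iloc[0])
            var = km.confidence_interval_survival_function_
            # Greenwood SE from the symmetric-ish CI half-width on this scale
            lo = float(
                km.confidence_interval_survival_function_.iloc[:, 0]
                .asof(boundary)
            )
            hi = float(
                km.confidence_interval_survival_function_.iloc[:, 1]
                .asof(boundary)
            )
            se = (hi - lo) / (2 * 1.96)
            assert abs(s_km - s_true) < 3 * se

    def test_negative_hazard_rejected(self, small_panel):
        with pytest.raises(ValueError, match="positive"):
            nm.generate_event_times(
                small_panel, nm.SurvivalSpec(interval_hazards=(-0.1,) * 5), seed=1
            )


class TestTruncateAfterEvent:
    def test_censored_subject_untouched(self, small_panel, survival_setup):
        surv, events = survival_setup
        mask = nm.MissingnessMask.all_observed(small_panel)
        out = nm.truncate_after_event(mask, events, small_panel)
        codes = out.codes.to_numpy()
        censored = events.event_indicator == 0
        assert (codes[censored] == Mechanism.OBS).all()

    def test_death_during_second_interval(self, small_panel, survival_setup):
        surv, events = survival_setup
        mask = nm.MissingnessMask.all_observed(small_panel)
        out = nm.truncate_after_event(mask, events, small_panel)
        died_interval2 = (events.event_indicator == 1) & (events.event_time > 5) & (
            events.event_time < 10
        )
        idx = np.flatnonzero(died_interval2)
        assert idx.size > 0
        for t in (3, 4, 5):
            assert (out.codes[col("BMI", t)].to_numpy()[idx] == Mechanism.DEATH).all()
        for t in (1, 2):
            assert (out.codes[col("BMI", t)].to_numpy()[idx] == Mechanism.OBS).all()

    def test_idempotent(self, small_panel, survival_setup):
        surv, events = survival_setup
        mask = nm.MissingnessMask.all_observed(small_panel)
        once = nm.truncate_after_event(mask, events, small_panel)
        twice = nm.truncate_after_event(once, events, small_panel)
        assert once.codes.equals(twice.codes)
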