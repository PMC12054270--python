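"""Chained-equations engine: predictor layouts, elementary draws, chains."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import nestmi as nm
from nestmi.fcs import (
    FcsConfig,
    _irls_logistic,
    draw_linear_bayes,
    draw_linear_boot,
    draw_logistic_abayes,
    fcs_predictors,
    impute_chained,
    nelson_aalen_cumhaz,
)
from nestmi.panel import Mechanism, MissingnessMask, col
from nestmi.simgen import EventTable

VARS = ("SMK", "BMI", "SBP", "DBP", "TC", "BG")


class TestPredictorLayout:
    def test_lfcs_row_for_bmi_t3(self):
        preds = fcs_predictors("LFCS", "BMI", 3, VARS, 5)
        assert preds == ["BMI_1", "BMI_2", "BMI_4", "BMI_5", "age", "sex"]
        with_cox = fcs_predictors("LFCS", "BMI", 3, VARS, 5, cox_mode=True)
        assert with_cox[-2:] == ["death", "H0"]

    def test_xfcs_row_excludes_target_itself(self):
        preds = fcs_predictors("XFCS", "BMI", 3, VARS, 5)
        assert preds == ["SMK_3", "SBP_3", "DBP_3", "TC_3", "BG_3", "age", "sex"]
        assert "BMI_3" not in preds

    def test_afcs_row_unions_both_information_sets(self):
        preds = fcs_predictors("AFCS", "BMI", 3, VARS, 5)
        assert set(preds) >= {"BMI_1", "BMI_2", "BMI_4", "BMI_5"}
        for v in VARS:
            if v != "BMI":
                assert {col(v, t) for t in range(1, 6)} <= set(preds)
        assert "BMI_3" not in preds
        assert len(preds) == 4 + 25 + 2

    @pytest.mark.parametrize("structure", ["AFCS", "LFCS", "XFCS"])
    def test_zero_diagonal(self, structure):
        mat = nm.build_predictor_matrix(structure, VARS, 5, cox_mode=True)
        diag = np.diag(mat.loc[:, mat.index].to_numpy())
        assert (diag == 0).all()

    def test_unknown_structure_rejected(self):
        with pytest.raises(ValueError, match="unknown FCS structure"):
            fcs_predictors("YFCS", "BMI", 1, VARS, 5)


class TestLinearDraws:
    def test_noiseless_limit_reproduces_line(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(50, 2))
        beta = np.array([1.0, 2.0, -3.0])
        y = beta[0] + X @ beta[1:]
        Xm = rng.normal(size=(10, 2))
        out = draw_linear_boot(y, X, Xm, seed=1)
        assert np.allclose(out, beta[0] + Xm @ beta[1:], atol=1e-8)

    def test_bootstrap_predictive_moments(self):
        """Intercept-only draws have mean ~ ybar and variance ~ s2(1 + 1/n)."""
        rng = np.random.default_rng(1)
        n = 100
        y = rng.normal(10.0, 2.0, n)
        X = np.empty((n, 0))
        draws = np.array(
            [draw_linear_boot(y, X, np.empty((1, 0)), seed=s)[0] for s in range(4000)]
        )
        s2 = y.var(ddof=1)
        target_var = s2 * (1 + 1 / n)
        assert abs(draws.mean() - y.mean()) < 4 * np.sqrt(target_var / 4000)
        assert abs(draws.var(ddof=1) - target_var) < 4 * target_var * np.sqrt(2 / 4000)

    def test_seed_contract(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 2))
        y = X @ [1.0, -1.0] + rng.normal(size=40)
        Xm = rng.normal(size=(5, 2))
        a = draw_linear_boot(y, X, Xm, seed=7)
        b = draw_linear_boot(y, X, Xm, seed=7)
        c = draw_linear_boot(y, X, Xm, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_bayes_matches_boot_in_distribution(self):
        """The two parameter-uncertainty schemes agree for moderate n (KS test)."""
        rng = np.random.default_rng(3)
        n = 500
        X = rng.normal(size=(n, 1))
        y = 2.0 + 1.5 * X[:, 0] + rng.normal(0, 1.0, n)
        Xm = np.zeros((5, 1))
        boot = np.concatenate(
            [draw_linear_boot(y, X, Xm, seed=s) for s in range(1000)]
        )
        bayes = np.concatenate(
            [draw_linear_bayes(y, X, Xm, seed=10_000 + s) for s in range(1000)]
        )
        assert stats.ks_2samp(boot, bayes).pvalue > 0.01

    def test_bayes_ols_cross_check(self):
        """Posterior-mean behaviour matches the statsmodels OLS fit at scale."""
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        X = rng.normal(size=(2000, 2))
        y = 1.0 + X @ [0.5, -0.25] + rng.normal(0, 0.3, 2000)
        fit = sm.OLS(y, sm.add_constant(X)).fit()
        Xm = np.array([[1.0, 1.0]])
        draws = np.array([draw_linear_bayes(y, X, Xm, seed=s)[0] for s in range(2000)])
        pred = float(fit.predict([[1.0, 1.0, 1.0]])[0])
        assert abs(draws.mean() - pred) < 4 * draws.std(ddof=1) / np.sqrt(2000)

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="observed cases"):
            draw_linear_boot(np.ones(3), np.ones((3, 2)), np.ones((1, 2)), seed=0)


class TestLogisticDraw:
    def test_marginal_rate_recovered(self):
        rng = np.random.default_rng(5)
        n = 400
        X = rng.normal(size=(n, 1))  # no real effect
        y = (rng.random(n) < 0.3).astype(float)
        draws = np.concatenate(
            [draw_logistic_abayes(y, X, rng.normal(size=(25, 1)), seed=s) for s in range(200)]
        )
        p = y.mean()
        assert abs(draws.mean() - p) < 4 * np.sqrt(p * (1 - p) / len(draws)) + 0.02

    def test_separated_data_fallback_is_finite(self):
        X = np.concatenate([-np.ones(20), np.ones(20)])[:, None]
        y = (X[:, 0] > 0).astype(float)
        out = draw_logistic_abayes(y, X, X, seed=1)
        assert set(np.unique(out)) <= {0.0, 1.0}

    def test_single_class_imputes_constant(self):
        out = draw_logistic_abayes(np.ones(30), np.zeros((30, 1)), np.zeros((7, 1)), seed=2)
        assert (out == 1.0).all()

    def test_irls_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        X = rng.normal(size=(800, 2))
        eta = -0.5 + X @ [1.0, -0.7]
        y = (rng.random(800) < 1 / (1 + np.exp(-eta))).astype(float)
        A = np.column_stack([np.ones(800), X])
        beta, _, converged = _irls_logistic(A, y, ridge=0.0)
        ref = sm.Logit(y, A).fit(disp=0).params
        assert converged
        assert np.allclose(beta, ref, atol=1e-4)


class TestNelsonAalen:
    def test_hand_computed_increments(self):
        ev = EventTable(
            table=pd.DataFrame({"event_time": [1.0, 2.0, 3.0], "event_indicator": [1, 1, 0]})
        )
        h0 = nelson_aalen_cumhaz(ev).h0.to_numpy()
        assert np.allclose(h0, [1 / 3, 1 / 3 + 1 / 2, 5 / 6])

    def test_no_events_zero_hazard(self):
        ev = EventTable(
            table=pd.DataFrame({"event_time": [4.0, 6.0], "event_indicator": [0, 0]})
        )
        assert (nelson_aalen_cumhaz(ev).h0 == 0).all()

    def test_replication_invariance(self):
        base = pd.DataFrame({"event_time": [1.0, 2.0, 3.0, 5.0], "event_indicator": [1, 0, 1, 0]})
        doubled = pd.concat([base, base], ignore_index=True)
        h1 = nelson_aalen_cumhaz(EventTable(table=base)).h0.to_numpy()
        h2 = nelson_aalen_cumhaz(EventTable(table=doubled)).h0.to_numpy()
        assert np.allclose(h2, np.concatenate([h1, h1]))

    def test_negative_times_rejected(self):
        ev = EventTable(table=pd.DataFrame({"event_time": [-1.0], "event_indicator": [1]}))
        with pytest.raises(ValueError, match="negative"):
            nelson_aalen_cumhaz(ev)


class TestChainedImputation:
    def test_no_missing_cells_identity(self, small_panel):
        mask = MissingnessMask.all_observed(small_panel)
        out = impute_chained(small_panel, mask, FcsConfig(), seed=0)
        assert out.data.equals(small_panel.data)

    def test_observed_cells_never_modified(self, masked_panel):
        panel, mask = masked_panel
        out = impute_chained(panel, mask, FcsConfig(structure="LFCS"), seed=1)
        obs = ~mask.is_missing()
        a = out.data.to_numpy()[obs]
        b = panel.data.to_numpy()[obs]
        assert np.array_equal(a, b)

    def test_binary_cells_stay_binary_and_continuous_finite(self, masked_panel):
        panel, mask = masked_panel
        out = impute_chained(panel, mask, FcsConfig(structure="AFCS"), seed=2)
        assert np.isfinite(out.data.to_numpy()).all()
        for t in panel.times():
            assert set(np.unique(out.data[col("SMK", t)])) <= {0.0, 1.0}

    def test_zero_iterations_is_initial_fill(self, masked_panel):
        """n_iterations=0 leaves the marginal random fill in place (documented)."""
        panel, mask = masked_panel
        out = impute_chained(panel, mask, FcsConfig(n_iterations=0), seed=3)
        miss = mask.is_missing()
        vals = out.data.to_numpy()[miss]
        pool = panel.data.to_numpy()[~miss]
        assert np.isin(vals, pool).all()

    def test_seed_reproducibility(self, masked_panel):
        panel, mask = masked_panel
        a = impute_chained(panel, mask, FcsConfig(), seed=4)
        b = impute_chained(panel, mask, FcsConfig(), seed=4)
        c = impute_chained(panel, mask, FcsConfig(), seed=5)
        assert a.data.equals(b.data)
        assert not a.data.equals(c.data)

    def test_mcar_deletion_recovers_mean(self, small_panel):
        """Imputed-value mean tracks the deleted-value mean over 50 chains."""
        rng = np.random.default_rng(7)
        mask = MissingnessMask.all_observed(small_panel)
        target = col("BMI", 3)
        rows = np.flatnonzero(rng.random(small_panel.n_subjects) < 0.2)
        ci = list(mask.codes.columns).index(target)
        mask.codes.iloc[rows, ci] = int(Mechanism.MAR)
        truth = small_panel.data[target].iloc[rows].mean()
        means = [
            impute_chained(small_panel, mask, FcsConfig(structure="LFCS"), seed=s)
            .data[target]
            .iloc[rows]
            .mean()
            for s in range(50)
        ]
        means = np.array(means)
        assert abs(means.mean() - truth) < 3 * means.std(ddof=1) / np.sqrt(50) + 0.25

    def test_lfcs_and_afcs_beat_xfcs_under_mcar(self, small_panel):
        """Longitudinal information wins when within-variable correlation is high."""
        rng = np.random.default_rng(8)
        mask = MissingnessMask.all_observed(small_panel)
        target = col("BMI", 3)
        rows = np.flatnonzero(rng.random(small_panel.n_subjects) < 0.2)
        ci = list(mask.codes.columns).index(target)
        mask.codes.iloc[rows, ci] = int(Mechanism.MAR)
        truth = small_panel.data[target].iloc[rows].to_numpy()
        rmse = {}
        for structure in ("LFCS", "AFCS", "XFCS"):
            errs = []
            for s in range(50):
                out = impute_chained(
                    small_panel, mask, FcsConfig(structure=structure), seed=s
                )
                errs.append(np.sqrt(np.mean((out.data[target].iloc[rows] - truth) ** 2)))
            rmse[structure] = np.mean(errs)
        assert rmse["LFCS"] < rmse["XFCS"]
        assert rmse["AFCS"] < rmse["XFCS"]
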