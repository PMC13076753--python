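"""Double-ML engine: folds, nuisances, Stage-2 inference, IPTW."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from psadose.cohort import VariableRoles
from psadose.dml import (
    NuisanceFit,
    assign_folds,
    coefficient_table,
    estimate_ate_iptw,
    fit_linear_cate,
    fit_nuisances,
    predict_cate,
)
from psadose.experiments import coverage_study

ROLES = VariableRoles()


def _oracle_nuisances(n, m, e, seed=0):
    return NuisanceFit(
        m_hat=np.asarray(m, float) * np.ones(n),
        e_hat=np.asarray(e, float) * np.ones(n),
        folds=np.zeros(n, dtype=int),
        k=2,
        learner="oracle",
        seed=seed,
    )


class TestFolds:
    @pytest.mark.parametrize("n,k", [(10, 2), (17, 5), (100, 7)])
    def test_partition_and_balance(self, n, k):
        t = (np.arange(n) % 3 == 0).astype(int)
        folds = assign_folds(t, k, seed=0)
        sizes = np.bincount(folds, minlength=k)
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1

    def test_stratification_spreads_treated(self):
        t = np.r_[np.ones(10, int), np.zeros(90, int)]
        folds = assign_folds(t, 5, seed=1)
        per_fold_treated = [t[folds == f].sum() for f in range(5)]
        assert max(per_fold_treated) - min(per_fold_treated) <= 1

    def test_deterministic(self):
        t = np.random.default_rng(0).integers(0, 2, 50)
        assert (assign_folds(t, 4, 9) == assign_folds(t, 4, 9)).all()

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            assign_folds(np.array([0, 1]), 1, 0)


class TestFitNuisances:
    def test_randomized_treatment_mean_propensity_near_half(self):
        rng = np.random.default_rng(3)
        n = 3000
        tab = pd.DataFrame(
            {
                "psaid_reduction": rng.normal(1.5, 1.0, n),
                "high_dose": rng.integers(0, 2, n),
                "age": rng.normal(50, 10, n),
                "bmi": rng.normal(29, 6, n),
            }
        )
        nuis = fit_nuisances(tab, ROLES, k=5, learner="linear", seed=0)
        assert abs(nuis.e_hat.mean() - 0.5) < 0.03

    def test_constant_outcome_predicted_exactly(self):
        rng = np.random.default_rng(4)
        tab = pd.DataFrame(
            {
                "psaid_reduction": 2.0,
                "high_dose": rng.integers(0, 2, 200),
                "age": rng.normal(50, 10, 200),
            }
        )
        nuis = fit_nuisances(tab, ROLES, k=3, learner="linear", seed=0)
        assert np.allclose(nuis.m_hat, 2.0, atol=1e-6)

    def test_propensity_increases_with_baseline_severity(self, confounded_cohort):
        nuis = fit_nuisances(confounded_cohort, ROLES, k=5, learner="linear", seed=0)
        decile = pd.qcut(confounded_cohort["psaid_baseline"], 10, labels=False)
        means = pd.Series(nuis.e_hat).groupby(decile.to_numpy()).mean()
        assert means.iloc[-1] > means.iloc[0]
        assert stats.spearmanr(np.arange(10), means).statistic > 0.8

    def test_propensities_clipped(self, confounded_cohort):
        nuis = fit_nuisances(confounded_cohort, ROLES, k=5, learner="gbt", seed=0)
        assert nuis.e_hat.min() >= 0.01 and nuis.e_hat.max() <= 0.99

    def test_single_class_fold_aborts(self):
        tab = pd.DataFrame(
            {
                "psaid_reduction": np.arange(10.0),
                "high_dose": [1] + [0] * 9,
                "age": np.arange(10.0),
            }
        )
        with pytest.raises(ValueError, match="treatment class"):
            fit_nuisances(tab, ROLES, k=5, learner="linear", seed=0)


class TestLinearCate:
    def test_oracle_constant_effect_recovered_exactly(self):
        # no noise, true nuisances: beta must equal the constant effect
        rng = np.random.default_rng(5)
        n = 64
        x = rng.normal(0, 1, n)
        e = 0.4
        t = (rng.random(n) < e).astype(float)
        c = 0.7
        y = 2.0 * x + c * t
        tab = pd.DataFrame({"psaid_reduction": y, "high_dose": t})
        nuis = NuisanceFit(
            m_hat=2.0 * x + c * e, e_hat=np.full(n, e), folds=np.zeros(n, int),
            k=2, learner="oracle", seed=0,
        )
        model = fit_linear_cate(tab, nuis)
        assert model.beta[0] == pytest.approx(c, abs=1e-10)

    def test_eight_row_toy_matches_moment_ratio(self):
        y_res = np.array([1.0, -1.0, 2.0, 0.0, 1.0, -2.0, 0.0, 1.0])
        t_res = np.array([0.5, -0.5, 0.5, -0.5, 0.5, -0.5, 0.5, -0.5])
        tab = pd.DataFrame({"psaid_reduction": y_res, "high_dose": t_res + 0.5})
        nuis = _oracle_nuisances(8, m=0.0, e=0.5)
        model = fit_linear_cate(tab, nuis)
        brute = np.sum(t_res * y_res) / np.sum(t_res**2)
        assert model.beta[0] == pytest.approx(brute, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(6)
        n = 180
        tab = pd.DataFrame(
            {
                "psaid_reduction": rng.normal(0, 1, n),
                "high_dose": rng.integers(0, 2, n).astype(float),
                "m1": rng.normal(0, 1, n),
                "m2": rng.random(n),
            }
        )
        e = np.clip(rng.random(n), 0.2, 0.8)
        nuis = NuisanceFit(
            m_hat=rng.normal(0, 0.1, n), e_hat=e, folds=np.zeros(n, int),
            k=2, learner="oracle", seed=0,
        )
        model = fit_linear_cate(tab, nuis, effect_modifiers=["m1", "m2"])
        t_res = tab["high_dose"].to_numpy() - e
        phi = np.column_stack([np.ones(n), tab["m1"], tab["m2"]])
        D = t_res[:, None] * phi
        y_res = tab["psaid_reduction"].to_numpy() - nuis.m_hat
        brute = np.linalg.solve(D.T @ D, D.T @ y_res)
        assert np.allclose(model.beta, brute, atol=1e-8)

    def test_intercept_only_equals_score_estimator(self, confounded_cohort):
        # two routes to the partially linear ATE: OLS and the closed-form
        # moment ratio sum(T_res * Y_res) / sum(T_res^2)
        nuis = fit_nuisances(confounded_cohort, ROLES, k=5, learner="linear", seed=3)
        model = fit_linear_cate(confounded_cohort, nuis, roles=ROLES)
        y_res = confounded_cohort[ROLES.y].to_numpy() - nuis.m_hat
        t_res = confounded_cohort[ROLES.t].to_numpy() - nuis.e_hat
        assert model.beta[0] == pytest.approx(
            np.sum(t_res * y_res) / np.sum(t_res**2), abs=1e-10
        )

    def test_missing_modifier_rejected(self):
        tab = pd.DataFrame(
            {"psaid_reduction": [1.0, 2.0], "high_dose": [0, 1], "m": [np.nan, 1.0]}
        )
        with pytest.raises(ValueError, match="missing"):
            fit_linear_cate(tab, _oracle_nuisances(2, 0.0, 0.5), effect_modifiers=["m"])

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(7)
        n = 60
        tab = pd.DataFrame(
            {
                "psaid_reduction": rng.normal(0, 1, n),
                "high_dose": rng.integers(0, 2, n).astype(float),
                "m1": rng.normal(0, 1, n),
            }
        )
        tab["m2"] = 2.0 * tab["m1"]
        nuis = _oracle_nuisances(n, 0.0, 0.5)
        with pytest.warns(UserWarning, match="collinear"):
            model = fit_linear_cate(tab, nuis, effect_modifiers=["m1", "m2"])
        assert len(model.beta) == 2

    def test_fold_seed_stability(self, confounded_cohort):
        nuis_a = fit_nuisances(confounded_cohort, ROLES, k=5, learner="linear", seed=1)
        nuis_b = fit_nuisances(confounded_cohort, ROLES, k=5, learner="linear", seed=999)
        ate_a = fit_linear_cate(confounded_cohort, nuis_a, roles=ROLES)
        ate_b = fit_linear_cate(confounded_cohort, nuis_b, roles=ROLES)
        assert abs(ate_a.beta[0] - ate_b.beta[0]) < 3 * ate_a.se[0]


class TestPredictCate:
    def test_intercept_only_constant(self):
        tab = pd.DataFrame({"psaid_reduction": [0.0, 1.0], "high_dose": [0.0, 1.0]})
        model = fit_linear_cate(tab, _oracle_nuisances(2, 0.0, 0.5))
        model.beta[0] = 0.24
        assert predict_cate(model, {"anything": 1}) == pytest.approx(0.24)

    def test_bmi_step_reproduces_subgroup_effect(self):
        # beta = (0.14, 0.38) on 1[BMI>32.5]: a BMI-35 patient gets 0.52
        rng = np.random.default_rng(8)
        n = 50
        tab = pd.DataFrame(
            {
                "psaid_reduction": rng.normal(0, 1, n),
                "high_dose": rng.integers(0, 2, n).astype(float),
                "bmi_high": rng.integers(0, 2, n).astype(float),
            }
        )
        model = fit_linear_cate(
            tab, _oracle_nuisances(n, 0.0, 0.5), effect_modifiers=["bmi_high"]
        )
        model.beta = np.array([0.14, 0.38])
        assert predict_cate(model, {"bmi_high": 1.0}) == pytest.approx(0.52)
        assert predict_cate(model, {"bmi_high": 0.0}) == pytest.approx(0.14)

    def test_mean_prediction_equals_average_cate(self, confounded_cohort):
        nuis = fit_nuisances(confounded_cohort, ROLES, k=5, learner="linear", seed=2)
        model = fit_linear_cate(
            confounded_cohort, nuis, effect_modifiers=["bmi_high"], roles=ROLES
        )
        preds = predict_cate(model, confounded_cohort)
        assert preds.mean() == pytest.approx(model.average_cate, abs=1e-12)


class TestIPTW:
    def test_four_row_toy_hand_computation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        t = np.array([1, 1, 0, 0])
        e = np.array([0.8, 0.4, 0.8, 0.4])
        ate, se = estimate_ate_iptw(y, t, e)
        w1 = 1.0 / e[:2]
        mu1 = np.sum(w1 * y[:2]) / np.sum(w1)
        w0 = 1.0 / (1.0 - e[2:])
        mu0 = np.sum(w0 * y[2:]) / np.sum(w0)
        assert ate == pytest.approx(mu1 - mu0, abs=1e-12)
        assert se > 0

    def test_single_arm_rejected(self):
        with pytest.raises(ValueError):
            estimate_ate_iptw(np.ones(3), np.ones(3), np.full(3, 0.5))


class TestCoefficientTable:
    def _model(self):
        tab = pd.DataFrame(
            {
                "psaid_reduction": np.random.default_rng(9).normal(0, 1, 120),
                "high_dose": np.random.default_rng(10).integers(0, 2, 120).astype(float),
                "m1": np.random.default_rng(11).normal(0, 1, 120),
            }
        )
        return fit_linear_cate(tab, _oracle_nuisances(120, 0.0, 0.5), ["m1"])

    def test_sorted_ascending_by_p(self):
        out = coefficient_table(self._model())
        assert out["p_value"].is_monotonic_increasing

    def test_pvalues_match_normal_cdf(self):
        model = self._model()
        expected = 2 * (1 - stats.norm.cdf(np.abs(model.beta / model.se)))
        assert np.allclose(model.pvalues, expected, atol=1e-12)

    def test_ci_halfwidth(self):
        out = coefficient_table(self._model())
        half = (out["ci_high"] - out["ci_low"]) / 2
        assert np.allclose(half, 1.959963984540054 * out["se"], atol=1e-12)


class TestCoverage:
    def test_small_n_ci_coverage_in_band(self):
        # 95% CIs for the average effect should cover the sample truth at a
        # rate compatible with nominal on small confounded replicates
        df = coverage_study(n_reps=100, n_patients=400, base_seed=7000)
        assert 0.88 <= df["covered"].mean() <= 0.99
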