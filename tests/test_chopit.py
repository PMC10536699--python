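"""CHOPIT likelihood, fitting, threshold prediction and screening."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.miscmodels.ordinal_model import OrderedModel

from anchorinv.chopit import (
    ChopitParams,
    fit_chopit,
    fit_chopit_arrays,
    loglik_arrays,
    predict_thresholds,
    predict_thresholds_table,
    screen_threshold_covariates,
    self_category_probs,
    simulate_chopit,
)
from anchorinv.dataset import INDICATORS, SurveyDataset, self_col
from anchorinv.synthetic import (
    PopulationSpec,
    VignetteDesign,
    inject_noninvariance,
    simulate_survey,
    thresholds_from_gamma,
)


def _params(nv=5, J=5, omega=0.5):
    gamma = np.zeros((4, nv))
    gamma[0, 0] = -1.5
    if nv > 1:
        gamma[:, 1:] = 0.1
    return ChopitParams(
        beta=np.full(nv - 1, 0.25),
        omega=omega,
        gamma=gamma,
        theta=np.linspace(-2, 2, J),
        sigma=np.full(J, 0.9),
    )


class TestLikelihood:
    def test_symmetric_probit_half_probability(self):
        """One respondent, first threshold at the latent mean, no random
        effect: P(lowest category) = 1/2."""
        gamma = np.zeros((4, 1))
        gamma[0, 0] = 0.0
        p = ChopitParams(beta=np.empty(0), omega=0.0, gamma=gamma,
                         theta=[0.0], sigma=[1.0])
        ll = loglik_arrays(
            p, np.empty((1, 0)), np.ones((1, 1)), np.array([1.0]),
            np.full((1, 1), np.nan),
        )
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_category_probabilities_normalize(self):
        rng = np.random.default_rng(0)
        p = _params()
        X = rng.integers(0, 2, (40, 4)).astype(float)
        V = np.column_stack([np.ones(40), X])
        probs = self_category_probs(p, X, V)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)

    def test_quadrature_stable_between_15_and_31_nodes(self):
        rng = np.random.default_rng(1)
        p = _params(omega=0.8)
        n = 200
        X = rng.integers(0, 2, (n, 4)).astype(float)
        V = np.column_stack([np.ones(n), X])
        y, Z = simulate_chopit(p, X, V, seed=2)
        ll15 = loglik_arrays(p, X, V, y, Z, quadrature_nodes=15)
        ll31 = loglik_arrays(p, X, V, y, Z, quadrature_nodes=31)
        assert abs(ll15 - ll31) / n < 1e-4

    def test_nonfinite_parameter_rejected(self):
        p = _params()
        p.beta[0] = np.inf
        with pytest.raises(ValueError, match="beta"):
            loglik_arrays(p, np.zeros((1, 4)), np.ones((1, 5)), np.array([2.0]))

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            loglik_arrays(_params(), np.empty((0, 4)), np.empty((0, 5)),
                          np.empty(0))


class TestThresholds:
    def test_zero_slopes_give_identical_rows(self):
        gamma = np.zeros((4, 3))
        gamma[0, 0] = -1.0
        V = np.column_stack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        tau = thresholds_from_gamma(gamma, V)
        assert np.allclose(tau, tau[0])
        assert np.allclose(tau[0], [-1.0, 0.0, 1.0, 2.0])

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(3)
        gamma = rng.normal(0, 0.3, (4, 4))
        V = np.column_stack([np.ones(10), rng.normal(0, 1, (10, 3))])
        tau = thresholds_from_gamma(gamma, V)
        for i in range(10):
            t1 = gamma[0] @ V[i]
            expected = [t1]
            for k in range(1, 4):
                expected.append(expected[-1] + np.exp(gamma[k] @ V[i]))
            assert np.allclose(tau[i], expected)
        assert np.all(np.diff(tau, axis=1) > 0)


class TestFitting:
    def test_matches_plain_ordered_probit_without_vignettes(self):
        """With no random effect, constant thresholds and no vignette data
        the model collapses to an ordered probit; the independent
        statsmodels fit must agree."""
        rng = np.random.default_rng(5)
        n = 800
        X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)]).astype(float)
        gamma = np.zeros((4, 1))
        gamma[0, 0] = -1.2
        true = ChopitParams(beta=np.array([0.5, -0.3]), omega=0.0, gamma=gamma,
                            theta=[0.0], sigma=[1.0])
        y, _ = simulate_chopit(true, X, np.ones((n, 1)), seed=6)
        fit = fit_chopit_arrays(X, np.ones((n, 1)), y, np.empty((n, 0)),
                                fix_omega=True, compute_se=False)
        ref = OrderedModel(y, X, distr="probit").fit(method="bfgs", disp=0)
        assert fit.loglik == pytest.approx(ref.llf, abs=1e-3)
        assert np.allclose(fit.params.beta, ref.params[:2], atol=1e-3)

    def test_null_threshold_slope_recovered_within_3se(self):
        rng = np.random.default_rng(7)
        n = 1000
        X = rng.integers(0, 2, (n, 1)).astype(float)
        V = np.column_stack([np.ones(n), X])
        gamma = np.zeros((4, 2))
        gamma[0, 0] = -1.5  # the covariate's threshold effect is truly zero
        true = ChopitParams(beta=np.array([0.3]), omega=0.4, gamma=gamma,
                            theta=np.linspace(-2, 2, 5), sigma=np.full(5, 0.9))
        y, Z = simulate_chopit(true, X, V, seed=8)
        fit = fit_chopit_arrays(X, V, y, Z)
        est = fit.params.gamma[0, 1]
        se = fit.se["gamma1[x0]"]
        assert abs(est) < 3 * se

    def test_loglik_at_mle_not_below_truth(self):
        rng = np.random.default_rng(9)
        n = 300
        true = _params(nv=3, omega=0.5)
        X = rng.integers(0, 2, (n, 2)).astype(float)
        V = np.column_stack([np.ones(n), X])
        y, Z = simulate_chopit(true, X, V, seed=10)
        fit = fit_chopit_arrays(X, V, y, Z, compute_se=False)
        assert fit.loglik >= loglik_arrays(true, X, V, y, Z) - 1e-6

    def test_survey_level_fit_and_prediction(self, survey):
        fit = fit_chopit(survey, indicator="autonomy", include_sets=(5,),
                         compute_se=False)
        assert fit.converged
        assert np.all(np.diff(fit.thresholds, axis=1) > 0)
        tab = predict_thresholds_table({"autonomy": fit}, survey)
        assert tab.shape == (len(survey.df), 4)
        assert {"thr_autonomy_k1", "thr_autonomy_k4"} <= set(tab.columns)

    def test_survey_level_loglik_finite_and_level_checked(self, survey):
        from anchorinv.chopit import chopit_loglik

        fit = fit_chopit(survey, indicator="autonomy", include_sets=(5,),
                         compute_se=False)
        ll = chopit_loglik(fit.params, survey, "autonomy", include_sets=(5,))
        assert np.isfinite(ll)
        assert ll == pytest.approx(fit.loglik, abs=1e-6)
        bad = ChopitParams(beta=fit.params.beta, omega=fit.params.omega,
                           gamma=fit.params.gamma, theta=[0.0], sigma=[1.0])
        with pytest.raises(ValueError, match="levels"):
            chopit_loglik(bad, survey, "autonomy", include_sets=(5,))

    def test_too_few_categories_rejected(self, survey):
        df = survey.df.copy()
        df[self_col("choice")] = 3.0
        with pytest.raises(ValueError, match="categories"):
            fit_chopit(SurveyDataset(df), indicator="choice", compute_se=False)


class TestScreening:
    def _data(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.integers(1, 6, n).astype(float)
        df = pd.DataFrame({"resp_id": range(n), "group": ["g1"] * (n // 2) + ["g2"] * (n - n // 2)})
        for s in INDICATORS:
            df[self_col(s)] = rng.integers(1, 6, n).astype(float)
        df[self_col("attention")] = y
        return SurveyDataset(df), y, rng

    def test_constant_threshold_never_selected(self):
        data, y, rng = self._data()
        thr = pd.DataFrame(
            {"thr_flat_k1": np.ones(len(data.df)),
             "thr_noise_k1": rng.normal(size=len(data.df))},
            index=data.df["resp_id"],
        )
        kept, paths = screen_threshold_covariates(thr, data, alpha=1e-4)
        assert "thr_flat_k1" not in kept
        assert not (paths["threshold"] == "thr_flat_k1").any()

    def test_noisy_copy_of_indicator_selected_strongly(self):
        data, y, rng = self._data()
        noisy = y + 0.75 * rng.standard_normal(len(y))  # r ~ 0.8
        thr = pd.DataFrame({"thr_att_k2": noisy}, index=data.df["resp_id"])
        kept, paths = screen_threshold_covariates(thr, data, alpha=0.05)
        assert kept == ["thr_att_k2"]
        best = paths[(paths["threshold"] == "thr_att_k2")
                     & (paths["indicator"] == "attention")]["pvalue"].min()
        assert best < 1e-10

    def test_dif_on_communication_selects_communication_thresholds(self):
        """Gender-driven communication thresholds should surface through the
        communication self-reports and not through unrelated indicators."""
        spec = PopulationSpec.default()
        spec = inject_noninvariance(spec, "rcdif", "communication", 1.0,
                                    "english", covariate_row=1)  # gender row
        spec = inject_noninvariance(spec, "rcdif", "communication", 1.0,
                                    "arabic", covariate_row=1)
        data = simulate_survey(spec, VignetteDesign.default(), (400, 300), seed=11)
        fit = fit_chopit(data, indicator="communication", include_sets=(3,),
                         compute_se=False)
        thr = predict_thresholds_table({"communication": fit}, data)
        kept, paths = screen_threshold_covariates(thr, data, alpha=0.01)
        assert any(c.startswith("thr_communication") for c in kept)
        comm_paths = paths[paths["threshold"].isin(kept)]
        assert (comm_paths["indicator"] == "communication").any()
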