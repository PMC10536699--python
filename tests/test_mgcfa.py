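"""Multi-group CFA: moments, fitting, indices, decisions, reliability."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.optimize import approx_fprime

from anchorinv.mgcfa import (
    CfaModelSpec,
    DecisionRules,
    GroupMoments,
    baseline_chisq,
    composite_reliability,
    composite_reliability_from_standardized,
    decide_configural,
    decide_level,
    fit_covariate_model,
    fit_indices,
    fit_mgcfa,
    implied_moments,
    invariance_sequence,
    lrt_difference,
    moments_from_data,
    standard_errors,
)
from anchorinv.mgcfa import _fit_function, _ParamTable, _start_values

INDS = tuple("abcdefg")
LAM = np.array([0.55, 0.60, 0.65, 0.70, 0.65, 0.75, 0.60])
TAU = np.array([3.6, 4.2, 3.9, 3.8, 4.0, 3.8, 4.0])
PSI = np.full(7, 0.5)


def population_groups(lam2=None, tau2=None, ns=(145, 91), ecov=None):
    mu1, s1 = implied_moments(LAM, TAU, PSI, ecov)
    mu2, s2 = implied_moments(
        LAM if lam2 is None else lam2, TAU if tau2 is None else tau2, PSI, ecov
    )
    return [
        GroupMoments("g1", mu1, s1, ns[0], INDS),
        GroupMoments("g2", mu2, s2, ns[1], INDS),
    ]


def sample_groups(rng, ns=(200, 200), lam2=None):
    out = []
    for i, n in enumerate(ns):
        lam = LAM if (i == 0 or lam2 is None) else lam2
        mu, sig = implied_moments(lam, TAU, PSI)
        X = rng.multivariate_normal(mu, sig, size=n)
        out.append(
            GroupMoments(f"g{i+1}", X.mean(0), np.cov(X, rowvar=False, bias=True), n, INDS)
        )
    return out


class TestMoments:
    def test_hand_computed_three_rows(self):
        df = pd.DataFrame(
            {"group": "g", "x": [1.0, 2.0, 3.0], "y": [2.0, 2.0, 5.0]}
        )
        (gm,) = moments_from_data(df, ["x", "y"])
        assert np.allclose(gm.mean, [2.0, 3.0])
        # divisor-n covariance
        assert gm.cov[0, 0] == pytest.approx(2 / 3)
        assert gm.cov[0, 1] == pytest.approx(1.0)
        assert gm.cov[1, 1] == pytest.approx(2.0)

    def test_duplicated_rows_leave_moments_unchanged(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(20, 3)), columns=["a", "b", "c"])
        df["group"] = "g"
        double = pd.concat([df, df], ignore_index=True)
        m1 = moments_from_data(df, ["a", "b", "c"])[0]
        m2 = moments_from_data(double, ["a", "b", "c"])[0]
        assert np.allclose(m1.cov, m2.cov) and np.allclose(m1.mean, m2.mean)

    def test_large_sample_matches_population_algebra(self):
        rng = np.random.default_rng(1)
        mu, sig = implied_moments(LAM, TAU, PSI)
        X = rng.multivariate_normal(mu, sig, size=100_000)
        df = pd.DataFrame(X, columns=list(INDS))
        df["group"] = "g"
        (gm,) = moments_from_data(df, list(INDS))
        assert np.abs(gm.mean - mu).max() < 3 * np.sqrt(sig.max() / 1e5)
        assert np.abs(gm.cov - sig).max() < 0.05

    def test_small_group_and_zero_variance_rejected(self):
        df = pd.DataFrame({"group": "g", "a": [1.0, 2], "b": [3.0, 4]})
        with pytest.raises(ValueError, match="complete rows"):
            moments_from_data(df, ["a", "b"])
        df2 = pd.DataFrame({"group": "g", "a": np.arange(9.0), "b": 1.0})
        with pytest.raises(ValueError, match="zero-variance.*'b'"):
            moments_from_data(df2, ["a", "b"])


class TestFitting:
    def test_gradient_matches_finite_differences(self):
        model = CfaModelSpec(indicators=INDS, error_covariances=(("a", "b"),))
        groups = population_groups(ecov={(0, 1): 0.1})
        table = _ParamTable(model, ["g1", "g2"])
        rng = np.random.default_rng(2)
        x0 = _start_values(table, groups) + 0.05 * rng.standard_normal(len(table))
        _, g = _fit_function(x0, table, groups)
        gn = approx_fprime(
            x0, lambda x: _fit_function(x, table, groups, want_grad=False)[0], 1e-7
        )
        assert np.abs(g - gn).max() / np.abs(gn).max() < 1e-4

    @pytest.mark.parametrize("level", ["configural", "metric", "scalar"])
    def test_population_moment_inversion(self, level):
        """Moments generated from known parameters are recovered exactly at
        every level whose constraints hold in the population."""
        model = CfaModelSpec(indicators=INDS, level=level)
        fit = fit_mgcfa(model, population_groups())
        assert fit.chi2 < 1e-6
        for g in ("g1", "g2"):
            assert np.abs(fit.estimates[g]["lambda"] - LAM).max() < 1e-5
            assert np.abs(fit.estimates[g]["tau"] - TAU).max() < 1e-5
            assert np.abs(fit.estimates[g]["psi"] - PSI).max() < 1e-5

    def test_df_bookkeeping_matches_closed_form(self):
        # two groups, p = 7: moments 2 * 7*10/2 = 70
        for level, df_expected in [("configural", 28), ("metric", 35), ("scalar", 42)]:
            fit = fit_mgcfa(CfaModelSpec(indicators=INDS, level=level), population_groups())
            assert fit.df == df_expected
        fit = fit_mgcfa(
            CfaModelSpec(indicators=INDS, error_covariances=(("a", "b"),)),
            population_groups(ecov={(0, 1): 0.1}),
        )
        assert fit.df == 27  # one extra parameter, shared across groups

    def test_saturated_single_group_three_indicators(self):
        lam3, tau3, psi3 = LAM[:3], TAU[:3], PSI[:3]
        mu, sig = implied_moments(lam3, tau3, psi3)
        gm = GroupMoments("g", mu, sig, 100, INDS[:3])
        fit = fit_mgcfa(CfaModelSpec(indicators=INDS[:3]), [gm])
        assert fit.df == 0
        assert fit.chi2 < 1e-8
        idx = fit_indices(fit)
        assert idx["rmsea"] == 0.0 and idx["df_zero"]

    def test_chi_square_nesting_monotone(self):
        rng = np.random.default_rng(3)
        groups = sample_groups(rng)
        chis = [
            fit_mgcfa(CfaModelSpec(indicators=INDS, level=lv), groups).chi2
            for lv in ("configural", "metric", "scalar")
        ]
        assert chis[0] <= chis[1] + 1e-6 <= chis[2] + 2e-6

    def test_heywood_case_flagged(self):
        # indicator a correlates far more strongly with the others than
        # they do among themselves -> lambda_a^2 exceeds its variance
        cov = np.full((4, 4), 0.40)
        cov[0, :] = cov[:, 0] = 0.75
        np.fill_diagonal(cov, 1.0)
        gm = GroupMoments("g", np.zeros(4), cov, 200, tuple("abcd"))
        fit = fit_mgcfa(CfaModelSpec(indicators=tuple("abcd")), [gm])
        assert fit.heywood

    def test_not_identified_model_rejected_before_optimizing(self):
        mu, sig = implied_moments(LAM[:2], TAU[:2], PSI[:2])
        gm = GroupMoments("g", mu, sig, 50, INDS[:2])
        with pytest.raises(ValueError, match="identified"):
            fit_mgcfa(CfaModelSpec(indicators=INDS[:2]), [gm])


class TestIndicesAndTests:
    def test_exact_fit_limits(self):
        rules_chi, df = 35.0, 35
        # chi2 == df -> RMSEA 0, CFI 1 regardless of baseline
        fit = fit_mgcfa(CfaModelSpec(indicators=INDS), population_groups())
        fit.chi2, fit.df = rules_chi, df
        idx = fit_indices(fit, baseline=(1000.0, 42))
        assert idx["rmsea"] == 0.0 and idx["cfi"] == 1.0

    def test_abic_hand_formula(self):
        fit = fit_mgcfa(CfaModelSpec(indicators=INDS), population_groups())
        idx = fit_indices(fit)
        N, q = fit.N, fit.n_free
        assert idx["abic"] == pytest.approx(
            -2 * fit.loglik + q * np.log((N + 2) / 24), rel=1e-12
        )

    def test_lrt_reference_values(self):
        fit_f = fit_mgcfa(CfaModelSpec(indicators=INDS), population_groups())
        fit_r = fit_mgcfa(CfaModelSpec(indicators=INDS, level="metric"), population_groups())
        d, ddf, p = lrt_difference(fit_r, fit_f)
        assert d == pytest.approx(0.0, abs=1e-6) and ddf == 7
        assert p == pytest.approx(1.0, abs=1e-6)
        assert stats.chi2.sf(3.84, 1) == pytest.approx(0.05, abs=5e-4)
        with pytest.raises(ValueError, match="nested"):
            lrt_difference(fit_f, fit_r)

    def test_decision_rules(self):
        assert decide_configural(0.96, 0.05) == "supported"
        assert decide_configural(0.94, 0.05) == "rejected"
        assert decide_configural(0.96, 0.09) == "rejected"
        # not significant, small deltas -> supported
        assert decide_level(6.77, 8, 0.003, -0.005) == "supported"
        # CFI drop alone triggers rejection
        assert decide_level(1.0, 8, 0.006, -0.005) == "rejected"
        # switched-off criteria are ignored
        rules = DecisionRules(use_cfi=False, use_rmsea=False)
        assert decide_level(1.0, 8, 0.02, 0.02, rules) == "supported"

    def test_sequence_on_invariant_population_supports_all_levels(self):
        report = invariance_sequence(CfaModelSpec(indicators=INDS), population_groups())
        assert report.decisions() == {
            "configural": "supported", "metric": "supported", "scalar": "supported"
        }


class TestCovariateModel:
    def _pop_with_covariates(self, gamma_scale=0.3, ns=(1000, 1000)):
        rng = np.random.default_rng(4)
        gam = gamma_scale * rng.normal(size=(7, 2))
        nu = np.array([0.2, -0.1])
        phi = np.array([[1.0, 0.3], [0.3, 0.8]])
        groups = []
        for i, n in enumerate(ns):
            mu, sig = implied_moments(LAM, TAU, PSI, None, gam, nu, phi)
            groups.append(GroupMoments(f"g{i+1}", mu, sig, n, INDS + ("u", "v")))
        return gam, nu, phi, groups

    def test_population_inversion_with_covariates(self):
        gam, nu, phi, groups = self._pop_with_covariates()
        model = CfaModelSpec(indicators=INDS, covariates=("u", "v"))
        fit = fit_mgcfa(model, groups)
        assert fit.chi2 < 1e-6
        assert np.abs(fit.estimates["g1"]["gamma"] - gam).max() < 1e-5
        assert np.abs(fit.estimates["g1"]["phi"] - phi).max() < 1e-5

    def test_irrelevant_covariate_leaves_loadings(self):
        """A covariate with zero paths in the population does not move the
        loading estimates (population moments)."""
        _, _, _, groups = self._pop_with_covariates(gamma_scale=0.0)
        plain = fit_mgcfa(CfaModelSpec(indicators=INDS),
                          population_groups(ns=(1000, 1000)))
        withcov = fit_mgcfa(CfaModelSpec(indicators=INDS, covariates=("u", "v")), groups)
        for g in ("g1", "g2"):
            assert np.abs(
                withcov.estimates[g]["lambda"] - plain.estimates[g]["lambda"]
            ).max() < 1e-3
            assert np.abs(withcov.estimates[g]["gamma"]).max() < 1e-4

    def test_gamma_recovered_within_3se_from_sampled_data(self):
        rng = np.random.default_rng(5)
        gam = np.array([[0.3], [0.0], [-0.2], [0.1], [0.0], [0.2], [-0.1]])
        n = 1000
        frames = []
        for g in ("g1", "g2"):
            x = rng.normal(0, 1, n)
            eta = rng.normal(0, 1, n)
            Y = TAU + np.outer(eta, LAM) + np.outer(x, gam[:, 0]) + (
                rng.normal(0, 1, (n, 7)) * np.sqrt(PSI)
            )
            df = pd.DataFrame(Y, columns=list(INDS))
            df["x"] = x
            df["group"] = g
            frames.append(df)
        data = pd.concat(frames, ignore_index=True)
        model = CfaModelSpec(indicators=INDS, covariates=("x",))
        fit = fit_covariate_model(model, data)
        se = standard_errors(fit)
        for i in range(7):
            est = fit.estimates["g1"]["gamma"][i, 0]
            s = se[("gamma", "g1", i, 0)]
            assert abs(est - gam[i, 0]) < 3 * s

    def test_collinear_covariates_named_in_error(self):
        df = pd.DataFrame(np.random.default_rng(6).normal(size=(50, 7)), columns=list(INDS))
        df["u"] = np.arange(50.0)
        df["v"] = 2 * df["u"]
        df["group"] = "g"
        model = CfaModelSpec(indicators=INDS, covariates=("u", "v"))
        with pytest.raises(ValueError, match="collinear"):
            fit_covariate_model(model, df)


class TestReliability:
    def test_degenerate_closed_forms(self):
        assert composite_reliability_from_standardized(np.zeros(7), np.ones(7)) == 0.0
        assert composite_reliability_from_standardized(np.ones(7), np.zeros(7)) == 1.0

    def test_equal_loading_arithmetic(self):
        omega = composite_reliability_from_standardized(
            np.full(7, 0.7), np.full(7, 0.51)
        )
        assert omega == pytest.approx(4.9**2 / (4.9**2 + 3.57), rel=1e-12)

    def test_fit_based_reliability_matches_population_value(self):
        fit = fit_mgcfa(CfaModelSpec(indicators=INDS), population_groups())
        lam_std = LAM / np.sqrt(LAM**2 + PSI)
        theta_std = PSI / (LAM**2 + PSI)
        expected = composite_reliability_from_standardized(lam_std, theta_std)
        rel = composite_reliability(fit)
        assert rel["g1"] == pytest.approx(expected, abs=1e-6)
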