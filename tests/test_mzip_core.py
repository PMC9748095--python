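"""ZIP/MZIP likelihoods, gradients, maximum-likelihood fits, Wald inference."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

import mzipmod as m
from mzipmod.core import _negll_grad, DesignSpec, Z_95


def brute_force_loglik(beta, gamma, y, X, Z, marginalized=True):
    """Row-by-row mixture density, no log-sum-exp shortcut (oracle)."""
    total = 0.0
    for i in range(len(y)):
        eta = float(Z[i] @ gamma)
        pi = 1.0 / (1.0 + math.exp(-eta))
        mu = math.exp(float(X[i] @ beta))
        if marginalized:
            mu *= 1.0 + math.exp(eta)  # mu = nu / (1 - pi)
        if y[i] == 0:
            total += math.log(pi + (1.0 - pi) * math.exp(-mu))
        else:
            total += math.log(1.0 - pi) + stats.poisson.logpmf(y[i], mu)
    return total


class TestLoglik:
    def test_single_row_hand_value(self):
        # y=0, pi=0.5, nu=2 => mu=4: contribution log(0.5 + 0.5 e^{-4})
        params = m.MZIPParams(np.array([np.log(2.0)]), np.array([0.0]))
        ll = m.mzip_loglik(params, [0.0], [[1.0]], [[1.0]])
        assert ll == pytest.approx(np.log(0.5 + 0.5 * np.exp(-4.0)), abs=1e-12)

    @pytest.mark.parametrize("marginalized", [True, False])
    def test_matches_brute_force_oracle(self, saturated_instance, marginalized):
        y, X, Z, params, _ = saturated_instance
        fn = m.mzip_loglik if marginalized else m.zip_loglik
        ll = fn(params, y, X, Z)
        oracle = brute_force_loglik(params.beta, params.gamma, y, X, Z, marginalized)
        assert abs(ll - oracle) < 1e-10

    def test_poisson_limit_of_likelihood(self, saturated_instance):
        # gamma -> -inf: the mixture collapses to Poisson(e^{x'beta})
        y, X, Z, params, _ = saturated_instance
        limit = m.MZIPParams(params.beta, np.array([-40.0, 0.0, 0.0, 0.0]))
        ll = m.mzip_loglik(limit, y, X, Z)
        pois = stats.poisson.logpmf(y, np.exp(X @ params.beta)).sum()
        assert ll == pytest.approx(pois, abs=1e-8)

    def test_dimension_mismatch_is_contract_error(self, saturated_instance):
        y, X, Z, params, _ = saturated_instance
        with pytest.raises(m.ContractError):
            m.mzip_loglik(params, y, X[:, :2], Z)
        with pytest.raises(m.ContractError):
            m.mzip_loglik(params, y[:-1], X, Z)

    def test_non_integer_outcomes_accepted(self, saturated_instance):
        # imputed data can carry fractional counts; logGamma(y+1) handles them
        y, X, Z, params, _ = saturated_instance
        yf = y + 0.25 * (y > 0)
        assert np.isfinite(m.mzip_loglik(params, yf, X, Z))

    @given(
        b0=st.floats(-1.5, 2.5), g0=st.floats(-3.0, 3.0),
        y0=st.integers(0, 25),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_loglik_equals_oracle_property(self, b0, g0, y0):
        params = m.MZIPParams(np.array([b0]), np.array([g0]))
        ll = m.mzip_loglik(params, [float(y0)], [[1.0]], [[1.0]])
        oracle = brute_force_loglik(params.beta, params.gamma,
                                    np.array([float(y0)]),
                                    np.array([[1.0]]), np.array([[1.0]]))
        assert ll == pytest.approx(oracle, abs=1e-10)


class TestGradient:
    @pytest.mark.parametrize("marginalized", [True, False])
    def test_analytic_gradient_matches_numeric(self, saturated_instance, marginalized):
        y, X, Z, params, _ = saturated_instance
        theta = np.concatenate([params.beta, params.gamma]) + 0.1

        def f(t):
            return _negll_grad(t, y, X, Z, marginalized, 0.0)[0]

        _, g = _negll_grad(theta, y, X, Z, marginalized, 0.0)
        g_num = optimize.approx_fprime(theta, f, 1e-7)
        assert np.allclose(g, g_num, rtol=1e-4, atol=1e-4)


class TestFit:
    def test_reparameterization_invariance_saturated(self, saturated_instance):
        # on a saturated design the ZIP and MZIP parameterizations span the
        # same mixture family: identical maxima, identical zero submodel
        y, X, Z, params, _ = saturated_instance
        names = ("intercept", "hs_drink", "arm", "hs_drink:arm")
        f1 = m.mzip_fit(y, X, Z, names, names)
        f2 = m.zip_fit(y, X, Z, names, names)
        assert f1.converged and f2.converged
        assert abs(f1.loglik - f2.loglik) < 1e-6
        assert np.max(np.abs(f1.params.gamma - f2.params.gamma)) < 1e-4

    def test_zip_intercept_only_moment_identity(self, saturated_instance):
        # intercept-only ZIP MLE satisfies (1-pi) mu = sample mean
        y, X, Z, *_ = saturated_instance
        ones = np.ones((len(y), 1))
        fit = m.zip_fit(y, ones, ones)
        pi = float(m.structural_zero_prob(fit, ones)[0])
        mu = float(np.exp(fit.params.beta[0]))
        assert (1 - pi) * mu == pytest.approx(y.mean(), abs=1e-6)

    def test_zip_fit_agrees_with_statsmodels(self, big_study):
        # independent cross-check on a non-saturated design with the
        # continuous baseline covariate
        import statsmodels.api as sm

        design = DesignSpec(
            ("intercept", "male", "baseline_drinks", "arm"),
            ("intercept", "male", "baseline_drinks", "arm"),
        )
        df = big_study.head(2000)
        X, Z = design.matrices(df)
        y = df["drinks_4m"].to_numpy(dtype=float)
        ours = m.zip_fit(y, X, Z, design.mean_terms, design.zero_terms)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ref = sm.ZeroInflatedPoisson(
                y, X, exog_infl=Z, inflation="logit"
            ).fit(method="bfgs", maxiter=500, disp=0)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-3)
        # statsmodels orders inflation params first, then count params
        q = Z.shape[1]
        assert np.allclose(ours.params.gamma, ref.params[:q], atol=1e-3)
        assert np.allclose(ours.params.beta, ref.params[q:], atol=1e-3)

    def test_poisson_limit_fit_matches_glm(self):
        # no structural zeros in the generator -> MZIP beta equals a plain
        # Poisson log-linear regression
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        n = 10_000
        df = pd.DataFrame({
            "male": rng.integers(0, 2, n),
            "arm": rng.integers(0, 2, n),
        })
        design = DesignSpec(("intercept", "male", "arm"),
                            ("intercept", "male", "arm"))
        truth = m.MZIPParams(np.log([2.0, 1.4, 0.8]), [-40.0, 0.0, 0.0],
                             design.mean_terms, design.zero_terms)
        y = m.simulate_mzip_outcome(df, design, truth, seed=3).astype(float)
        X, Z = design.matrices(df)
        fit = m.mzip_fit(y, X, Z, design.mean_terms, design.zero_terms)
        glm = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        assert np.max(np.abs(fit.params.beta - glm.params)) < 1e-2

    def test_parameter_recovery_large_n(self):
        # fitted RRs within 5% relative error of generating values at n=20000
        cfg = m.GeneratorConfig(n_participants=20_000, seed=101,
                                p_missing_moderator=0.0)
        df = m.generate_study(cfg)
        truth = cfg.outcome_params_4m
        sample = m.prepare_analysis_sample(df, "4m")
        fit = m.mzip_fit(sample.y, sample.X, sample.Z,
                         sample.design.mean_terms, sample.design.zero_terms)
        assert fit.converged
        rr_hat = np.exp(fit.params.beta)
        rr_true = np.exp(truth.beta)
        assert np.all(np.abs(rr_hat / rr_true - 1.0) < 0.05)

    def test_optimizer_stable_under_perturbed_start(self, saturated_instance):
        y, X, Z, params, _ = saturated_instance
        f1 = m.mzip_fit(y, X, Z)
        rng = np.random.default_rng(0)
        start = f1.coef + rng.normal(0, 0.3, f1.coef.size)
        f2 = m.mzip_fit(y, X, Z, start=start)
        assert abs(f1.loglik - f2.loglik) < 1e-6

    def test_no_zeros_warns_about_weak_identification(self):
        rng = np.random.default_rng(4)
        y = rng.poisson(8.0, 200) + 1.0
        ones = np.ones((200, 1))
        with pytest.warns(UserWarning, match="no zeros"):
            m.mzip_fit(y, ones, ones)

    def test_too_few_observations_rejected(self):
        with pytest.raises(m.ContractError, match="cannot identify"):
            m.mzip_fit([0.0, 1.0], np.ones((2, 1)), np.ones((2, 1)))

    def test_vcov_symmetric_psd(self, saturated_instance):
        y, X, Z, *_ = saturated_instance
        fit = m.mzip_fit(y, X, Z)
        assert np.allclose(fit.vcov, fit.vcov.T)
        assert np.min(np.linalg.eigvalsh(fit.vcov)) > -1e-8


class TestInference:
    def _toy_fit(self, beta, gamma, se=0.1, names=None):
        k = len(beta) + len(gamma)
        names = names or tuple(f"b{i}" for i in range(len(beta)))
        params = m.MZIPParams(np.asarray(beta, float), np.asarray(gamma, float),
                              names, tuple(f"g{i}" for i in range(len(gamma))))
        return m.MZIPFit(params=params, vcov=np.eye(k) * se**2, loglik=-1.0,
                         converged=True, n_obs=100, iterations=1)

    def test_null_coefficient_table_row(self):
        fit = self._toy_fit([0.0], [0.0], se=0.1)
        tab = m.coefficient_table(fit)
        row = tab.iloc[0]
        assert row.ratio == pytest.approx(1.0)
        assert row.ci_low == pytest.approx(np.exp(-Z_95 * 0.1), rel=1e-6)
        assert row.ci_high == pytest.approx(np.exp(Z_95 * 0.1), rel=1e-6)
        assert not row.significant

    def test_normal_quantile_constant(self):
        assert Z_95 == pytest.approx(1.959964, abs=1e-6)

    def test_ci_symmetric_on_log_scale(self, saturated_instance):
        y, X, Z, *_ = saturated_instance
        tab = m.coefficient_table(m.mzip_fit(y, X, Z))
        lo = np.log(tab.ci_low) - np.log(tab.ratio)
        hi = np.log(tab.ci_high) - np.log(tab.ratio)
        assert np.allclose(lo, -hi, atol=1e-10)
        assert ((tab.ci_low <= tab.ratio) & (tab.ratio <= tab.ci_high)).all()

    def test_nonconverged_fit_refused(self):
        fit = self._toy_fit([0.0], [0.0])
        fit.converged = False
        with pytest.raises(m.NotConvergedError):
            m.coefficient_table(fit)

    def test_predict_marginalization_identity(self, saturated_instance):
        # nu = (1 - pi) mu exactly, for every row
        y, X, Z, *_ = saturated_instance
        fit = m.mzip_fit(y, X, Z)
        nu = m.predict_overall_mean(fit, X)
        pi = m.structural_zero_prob(fit, Z)
        mu = m.predict_poisson_mean(fit, X, Z)
        assert np.max(np.abs(nu - (1 - pi) * mu)) < 1e-12

    def test_intercept_only_prediction_constant(self):
        params = m.MZIPParams(np.array([np.log(3.0)]), np.array([0.0]))
        fit = m.MZIPFit(params=params, vcov=np.eye(2), loglik=0.0,
                        converged=True, n_obs=5, iterations=0)
        nu = m.predict_overall_mean(fit, np.ones((7, 1)))
        assert np.allclose(nu, 3.0)

    def test_arm_toggle_is_exactly_loglinear(self, big_study):
        sample = m.prepare_analysis_sample(big_study, "4m")
        fit = m.mzip_fit(sample.y, sample.X, sample.Z,
                         sample.design.mean_terms, sample.design.zero_terms)
        names = list(fit.params.x_names)
        b_arm = fit.params.beta[names.index("arm")]
        b_int = fit.params.beta[names.index("hs_drink:arm")]
        t0 = sample.table.copy()
        t0["arm"] = 0.0
        t1 = sample.table.copy()
        t1["arm"] = 1.0
        X0, _ = sample.design.matrices(t0)
        X1, _ = sample.design.matrices(t1)
        ratio = m.predict_overall_mean(fit, X1) / m.predict_overall_mean(fit, X0)
        expected = np.exp(b_arm + b_int * t0["hs_drink"].to_numpy())
        assert np.allclose(ratio, expected, rtol=1e-12)

    def test_prediction_column_mismatch_named(self, saturated_instance):
        y, X, Z, *_ = saturated_instance
        fit = m.mzip_fit(y, X, Z)
        with pytest.raises(m.ContractError, match="columns"):
            m.predict_overall_mean(fit, X[:, :2])
        with pytest.raises(m.ContractError, match="columns"):
            m.structural_zero_prob(fit, Z[:, :2])


class TestPercentChange:
    @given(ratio=st.floats(0.01, 100.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_magnitude_and_direction(self, ratio):
        pc = m.percent_change(ratio)
        assert pc.percent == pytest.approx(100.0 * abs(ratio - 1.0), rel=1e-12)
        if ratio > 1:
            assert pc.direction == "higher"
        elif ratio < 1:
            assert pc.direction == "lower"

    def test_invalid_ratio_rejected(self):
        with pytest.raises(m.ContractError):
            m.percent_change(-0.5)
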