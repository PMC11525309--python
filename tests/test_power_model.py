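"""Power-curve fitting, prediction bands, and sample-size inversion."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, special, stats

from mspe import (
    EffectSpec,
    PowerModelFit,
    SignificanceRecord,
    analytic_power,
    fit_naive,
    fit_power_model,
    fit_wald_power_model,
    predict_power,
    required_n,
    required_n_lb,
)
from mspe.errors import (
    ExtrapolationError,
    GridError,
    InvalidEffectError,
    InversionError,
    PowerCapError,
    SeparationError,
)
from mspe.study_runner import simulate_bernoulli_decisions


def make_fit(method="probit_sqrt", beta0=-1.644854, beta1=0.1, vcov=None, alpha=0.05):
    vcov = np.zeros((2, 2)) if vcov is None else np.asarray(vcov, dtype=float)
    return PowerModelFit(method=method, alpha=alpha, beta0=beta0, beta1=beta1, vcov=vcov)


class TestAnalyticPower:
    @pytest.mark.parametrize(
        "theta0, psi, sided, n, expected",
        [
            # null effect: power equals the test level
            (0.0, 1.0, "one-sided", 100, 0.05),
            (0.0, 3.0, "two-sided", 1000, 0.05),
            # Phi(-1.6449 + 0.1*20) = Phi(0.3551)
            (0.2, 2.0, "one-sided", 400, 0.6387600),
        ],
    )
    def test_values(self, theta0, psi, sided, n, expected):
        eff = EffectSpec(theta0=theta0, avar_factor=psi, sided=sided, alpha=0.05)
        assert analytic_power(eff, n) == pytest.approx(expected, abs=5e-5)

    def test_invalid_effect(self):
        with pytest.raises(InvalidEffectError):
            EffectSpec(theta0=0.2, avar_factor=0.0)
        with pytest.raises(InvalidEffectError):
            EffectSpec(theta0=0.2, avar_factor=1.0, alpha=1.5)


class TestFitPowerModel:
    def test_probit_sqrt_recovers_generating_curve(self):
        rng = np.random.default_rng(2024)
        n_vals = np.resize(np.arange(51, 601), 50_000)
        rec = simulate_bernoulli_decisions(-1.6449, 0.12, n_vals, rng)
        fit = fit_power_model(rec, method="probit_sqrt", alpha=0.05)
        assert fit.converged
        assert fit.beta0 == pytest.approx(-1.6449, abs=0.05)
        assert fit.beta1 == pytest.approx(0.12, abs=0.005)
        # and within 3 of the fit's own standard errors
        se0, se1 = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.beta0 + 1.6449) < 3 * se0
        assert abs(fit.beta1 - 0.12) < 3 * se1

    def test_ml_matches_generic_optimizer(self):
        """The probit ML fit agrees with a direct likelihood optimization."""
        rng = np.random.default_rng(7)
        n_vals = np.resize(np.arange(51, 601), 5_000)
        rec = simulate_bernoulli_decisions(-1.6449, 0.12, n_vals, rng)
        fit = fit_power_model(rec, method="probit_sqrt")
        g = np.sqrt(rec["n"].to_numpy(dtype=float))
        s = rec["significant"].to_numpy(dtype=float)

        def nll(beta):
            p = np.clip(special.ndtr(beta[0] + beta[1] * g), 1e-12, 1 - 1e-12)
            return -(s * np.log(p) + (1 - s) * np.log1p(-p)).sum()

        res = optimize.minimize(
            nll, [-1.0, 0.1], method="L-BFGS-B",
            options={"ftol": 1e-15, "gtol": 1e-12},
        )
        assert np.abs(res.x - [fit.beta0, fit.beta1]).max() < 1e-6

    def test_dropped_nonconverged_counted(self):
        rec = pd.DataFrame(
            {
                "n": [100, 200, 300, 400, 100, 200],
                "significant": [0, 1, 0, 1, 1, 0],
                "converged": [1, 1, 1, 1, 0, 0],
            }
        )
        fit = fit_power_model(rec, method="logit_n")
        assert fit.dropped_nonconverged == 2
        assert fit.n_records == 4

    def test_all_same_outcome_is_separation(self):
        rec = [SignificanceRecord(n=n, significant=0) for n in (100, 200, 300)]
        with pytest.raises(SeparationError):
            fit_power_model(rec, method="probit_sqrt")

    def test_perfect_ordering_is_separation(self):
        rec = [
            SignificanceRecord(n=n, significant=int(n > 250))
            for n in (100, 150, 200, 300, 350, 400)
        ]
        with pytest.raises(SeparationError, match="[Ww]iden"):
            fit_power_model(rec, method="probit_sqrt")

    def test_asymptotic_anchor(self):
        """Decisions generated from the true z-test at level alpha drive
        beta0 to -q_{1-alpha} and beta1 to |theta0|/psi (within 3 SEs at
        R = 1e5)."""
        eff = EffectSpec(theta0=0.25, avar_factor=2.0, sided="one-sided", alpha=0.05)
        rng = np.random.default_rng(11)
        n_vals = np.resize(np.arange(51, 601), 100_000)
        p = np.array([analytic_power(eff, n) for n in np.arange(51, 601)])
        p = np.resize(p, 100_000)
        s = (rng.random(100_000) < p).astype(int)
        rec = pd.DataFrame({"n": n_vals, "significant": s, "converged": 1})
        fit = fit_power_model(rec, method="probit_sqrt", alpha=0.05)
        se0, se1 = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.beta0 - (-stats.norm.ppf(0.95))) < 3 * se0
        assert abs(fit.beta1 - 0.125) < 3 * se1
        assert abs(fit.intercept_diagnostic()) < 3 * se0


class TestWaldFit:
    def test_recovers_generating_curve(self):
        rng = np.random.default_rng(5)
        n_vals = np.resize(np.arange(51, 601), 50_000)
        rec = simulate_bernoulli_decisions(
            -1.95996, 0.12, n_vals, rng, two_sided=True
        )
        fit = fit_wald_power_model(rec, alpha=0.05)
        assert fit.converged and not fit.boundary
        se0, se1 = np.sqrt(np.diag(fit.vcov))
        assert abs(fit.beta0 + 1.95996) < 3 * se0
        assert abs(fit.beta1 - 0.12) < 3 * se1

    def test_null_curve_predicts_alpha_everywhere(self):
        fit = make_fit("wald_sqrt", beta0=-stats.norm.ppf(0.975), beta1=0.0)
        for n in (10, 100, 1000, 100_000):
            assert predict_power(fit, n).rho_hat == pytest.approx(0.05, abs=1e-9)

    def test_agrees_with_one_sided_probit_at_large_mu(self):
        """The opposite-tail term vanishes: for mu = beta1*sqrt(n) >= 8 the
        two-term curve equals the one-sided probit curve to 1e-6."""
        b0, b1 = -1.95996, 0.3
        for n in (712, 1000, 5000):  # mu = 8.0, 9.5, 21.2
            assert b1 * math.sqrt(n) >= 8
            wald = predict_power(make_fit("wald_sqrt", b0, b1), n).rho_hat
            probit = predict_power(make_fit("probit_sqrt", b0, b1), n).rho_hat
            assert abs(wald - probit) < 1e-6


class TestPredictPower:
    def test_half_power_at_zero_linear_predictor(self):
        fit = make_fit(beta0=-2.0, beta1=0.2)  # eta = 0 at n = 100
        assert predict_power(fit, 100).rho_hat == pytest.approx(0.5, abs=1e-12)

    def test_zero_vcov_gives_degenerate_band(self):
        fit = make_fit(beta0=-1.5, beta1=0.1)
        pred = predict_power(fit, 300)
        assert pred.lb == pred.rho_hat == pred.ub

    def test_band_ordering_and_range(self):
        fit = make_fit(vcov=[[0.01, -2e-4], [-2e-4, 1e-5]])
        for n in (10, 100, 400, 2000):
            pred = predict_power(fit, n)
            assert 0 <= pred.lb <= pred.rho_hat <= pred.ub <= 1

    def test_band_coverage_against_generating_curve(self):
        """95% bands from repeated studies cover the true power at n=300
        about 95% of the time."""
        b0, b1 = -1.6449, 0.12
        truth = float(special.ndtr(b0 + b1 * math.sqrt(300)))
        n_vals = np.arange(51, 601)
        cover = 0
        n_studies = 400
        for ss in np.random.SeedSequence(99).spawn(n_studies):
            rec = simulate_bernoulli_decisions(
                b0, b1, n_vals, np.random.default_rng(ss)
            )
            fit = fit_power_model(rec, method="probit_sqrt")
            pred = predict_power(fit, 300, alpha_rho=0.05)
            cover += pred.lb <= truth <= pred.ub
        assert 0.92 <= cover / n_studies <= 0.98

    def test_monotone_in_n(self):
        # slopes chosen so the curve stays away from saturation at 1,
        # where strict monotonicity is lost to float rounding
        for method in ("probit_sqrt", "logit_sqrt", "probit_n", "logit_n", "wald_sqrt"):
            beta1 = 0.002 if method.endswith("_n") else 0.05
            fit = make_fit(method, beta0=-2.0, beta1=beta1)
            preds = [predict_power(fit, n).rho_hat for n in range(50, 2000, 50)]
            assert np.all(np.diff(preds) > 0)


class TestRequiredN:
    def test_probit_sqrt_closed_form(self):
        fit = make_fit(beta0=-1.644854, beta1=0.1)
        assert required_n(fit, 0.80) == 619  # ceil(618.26)

    def test_effect_spec_matches_z_test_formula(self):
        eff = EffectSpec(theta0=0.5, avar_factor=1.0, sided="one-sided", alpha=0.05)
        assert required_n(eff, 0.80) == 25

    def test_roundtrip_exact_integer(self):
        fit = make_fit(beta0=-1.644854, beta1=0.1)
        for m in (100, 619, 2500):
            rho = float(special.ndtr(fit.beta0 + fit.beta1 * math.sqrt(m)))
            if rho <= 0.99:
                assert required_n(fit, rho) == m

    def test_power_cap_and_bad_slope(self):
        fit = make_fit()
        with pytest.raises(PowerCapError):
            required_n(fit, 0.995)
        with pytest.raises(InversionError):
            required_n(make_fit(beta1=-0.1), 0.8)
        with pytest.raises(InversionError):
            required_n(EffectSpec(theta0=0.0, avar_factor=1.0), 0.8)

    @settings(max_examples=200, deadline=None)
    @given(
        beta0=st.floats(-3.0, -1.0),
        beta1=st.floats(0.02, 0.3),
        rho=st.floats(0.2, 0.99),
        method=st.sampled_from(["probit_sqrt", "logit_sqrt", "wald_sqrt"]),
    )
    def test_inversion_consistency(self, beta0, beta1, rho, method):
        """predict(required_n(rho)) >= rho > predict(required_n(rho) - 1)."""
        fit = make_fit(method, beta0=beta0, beta1=beta1)
        if rho <= fit.alpha:
            return
        n_req = required_n(fit, rho)
        assert predict_power(fit, n_req).rho_hat >= rho - 1e-9
        if n_req > 1:
            assert predict_power(fit, n_req - 1).rho_hat < rho

    def test_closed_form_agrees_with_bisection(self):
        """The algebraic inversion and a generic monotone bisection land on
        the same integer over 1,000 random configurations."""
        from mspe.power_model import _bisect_smallest_n

        rng = np.random.default_rng(17)
        for _ in range(1000):
            beta0 = rng.uniform(-3, -1)
            beta1 = rng.uniform(0.02, 0.3)
            rho = rng.uniform(0.2, 0.99)
            method = ("probit_sqrt", "logit_sqrt", "probit_n", "logit_n")[
                rng.integers(4)
            ]
            if method.endswith("_n"):
                beta1 /= 10
            fit = make_fit(method, beta0=beta0, beta1=beta1)
            direct = required_n(fit, rho)
            by_bisection = _bisect_smallest_n(
                lambda m: predict_power(fit, m).rho_hat, rho
            )
            assert direct == by_bisection


class TestRequiredNLowerBound:
    def test_zero_vcov_collapses_to_point_estimate(self):
        fit = make_fit(beta0=-1.6449, beta1=0.12)
        res = required_n_lb(fit, 0.80)
        assert res.N_lb == res.N_alpha
        assert res.rho_hat_lb == pytest.approx(0.80, abs=1e-5)

    def test_wider_vcov_increases_lower_bound_only(self):
        vcov = np.array([[0.005, -2e-4], [-2e-4, 1e-5]])
        fit1 = make_fit(beta0=-1.6449, beta1=0.12, vcov=vcov)
        fit4 = make_fit(beta0=-1.6449, beta1=0.12, vcov=4 * vcov)
        r1, r4 = required_n_lb(fit1, 0.80), required_n_lb(fit4, 0.80)
        assert r1.N_alpha == r4.N_alpha
        assert r4.N_lb > r1.N_lb >= r1.N_alpha

    def test_algebraic_identity_for_probit_sqrt(self):
        """Plugging rho_hat_lb into the closed-form inversion reproduces the
        bisection result (the two formulations coincide for probit-sqrt)."""
        vcov = np.array([[0.02, -5e-4], [-5e-4, 4e-6]])
        fit = make_fit(beta0=-1.6449, beta1=0.12, vcov=vcov)
        res = required_n_lb(fit, 0.80)
        n_alg = math.ceil(
            ((stats.norm.ppf(res.rho_hat_lb) - fit.beta0) / fit.beta1) ** 2 - 1e-6
        )
        assert abs(n_alg - res.N_lb) <= 1
        assert res.rho_hat_lb > 0.80


class TestNaive:
    @staticmethod
    def records_with_rates(grid, rates, reps=100):
        rec = []
        for nj, pj in zip(grid, rates):
            k = round(pj * reps)
            rec += [SignificanceRecord(n=nj, significant=1)] * k
            rec += [SignificanceRecord(n=nj, significant=0)] * (reps - k)
        return rec

    def test_midpoint_interpolation(self):
        rec = self.records_with_rates((100, 200, 300, 400), (0.2, 0.5, 0.8, 0.95))
        fit = fit_naive(rec, alpha_rho=0.05)
        assert predict_power(fit, 150).rho_hat == pytest.approx(0.35, abs=1e-12)

    def test_interval_clipped_at_one(self):
        rec = self.records_with_rates((100, 200, 300, 400), (0.2, 0.5, 0.8, 1.0))
        fit = fit_naive(rec)
        assert fit.naive_table["ub"].iloc[3] == 1.0
        assert fit.naive_table["lb"].iloc[3] == 1.0  # p(1-p) = 0

    def test_grid_and_extrapolation_errors(self):
        rec = self.records_with_rates((100, 200, 300), (0.2, 0.5, 0.8))
        with pytest.raises(GridError):
            fit_naive(rec)
        fit = fit_naive(
            self.records_with_rates((100, 200, 300, 400), (0.2, 0.5, 0.8, 0.95))
        )
        with pytest.raises(ExtrapolationError):
            predict_power(fit, 450)
        with pytest.raises(ExtrapolationError):
            predict_power(fit, 50)

    def test_first_crossing_inversion(self):
        fit = fit_naive(
            self.records_with_rates((100, 200, 300, 400), (0.2, 0.5, 0.8, 0.95))
        )
        # linear segment 200 -> 300 crosses .65 at n = 250
        assert required_n(fit, 0.65) == 250
        res = required_n_lb(fit, 0.65)
        assert res.N_lb >= res.N_alpha
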