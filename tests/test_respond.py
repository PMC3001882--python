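import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bayesrt import (PerceptualParams, ResponseParams, RiskInputs, loss,
                     optimal_rt, posterior_risk, predicted_rt_series,
                     rt_loglik, run_recognition, simulate_rts)
from bayesrt.task import sample_outcomes_and_signals


def grid_argmin(inputs, params, t_max=10.0, step=1e-4):
    t = np.arange(0.0, t_max, step)
    return float(t[np.argmin(posterior_risk(inputs, t, params))])


class TestLoss:
    @pytest.mark.parametrize("choice,category,t,beta,expected", [
        (1, 1, 0.0, 0.5, 0.0),
        (1, 0, 0.0, 0.5, 1.0),
        (0, 0, 2.0, 0.5, 1.0),   # delay-only cost: 0.5 * 2
    ])
    def test_values(self, choice, category, t, beta, expected):
        assert loss(choice, category, t, beta) == expected

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            loss(1, 1, -0.1, 0.5)


class TestPosteriorRisk:
    def test_convex_on_correct_trials(self):
        rp = ResponseParams(beta_err=0.1, beta_sens=2.0)
        t = np.linspace(0, 5, 2001)
        r = posterior_risk(RiskInputs(delta_mu=0.8, choice=1), t, rp)
        assert np.all(np.diff(r, 2) > -1e-12)

    def test_zero_prediction_error_minimised_at_zero(self):
        rp = ResponseParams(beta_err=0.1, beta_sens=2.0)
        inputs = RiskInputs(delta_mu=0.0, choice=1)
        assert optimal_rt(inputs, rp) == 0.0
        assert grid_argmin(inputs, rp) == 0.0

    def test_closed_form_matches_grid(self):
        rp = ResponseParams(beta_err=0.1, beta_sens=1.0)
        inputs = RiskInputs(delta_mu=0.9, choice=1)
        assert abs(optimal_rt(inputs, rp) - grid_argmin(inputs, rp)) < 1e-4


class TestOptimalRT:
    def test_error_sign_trials_are_instant(self):
        rp = ResponseParams(beta_err=0.1, beta_sens=5.0)
        assert optimal_rt(RiskInputs(delta_mu=-0.8, choice=1), rp) == 0.0
        assert optimal_rt(RiskInputs(delta_mu=0.8, choice=0), rp) == 0.0

    def test_monotone_increasing_in_magnitude(self):
        # larger post-hoc prediction error = more information to absorb =
        # longer optimal deliberation (the learning-facilitation direction)
        rp = ResponseParams(beta_err=0.1, beta_sens=5.0)
        ts = [optimal_rt(RiskInputs(delta_mu=d, choice=1), rp)
              for d in (0.1, 0.5, 0.9)]
        assert ts[0] < ts[1] < ts[2]

    def test_grid_oracle_on_random_draws(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            rp = ResponseParams(beta_err=float(np.exp(rng.uniform(-4, 0))),
                                beta_sens=float(np.exp(rng.uniform(0, 4))))
            inputs = RiskInputs(delta_mu=float(rng.uniform(0.05, 1.0)),
                                choice=1)
            assert abs(optimal_rt(inputs, rp)
                       - grid_argmin(inputs, rp)) < 1e-3

    def test_global_minimiser_property(self):
        rng = np.random.default_rng(2)
        rp = ResponseParams(beta_err=0.2, beta_sens=3.0)
        inputs = RiskInputs(delta_mu=0.7, choice=1)
        t_star = optimal_rt(inputs, rp)
        t = np.linspace(0, 8, 4001)
        assert posterior_risk(inputs, t_star, rp) <= np.min(
            posterior_risk(inputs, t, rp)) + 1e-12

    def test_never_negative(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            rp = ResponseParams(beta_err=float(np.exp(rng.uniform(-4, 2))),
                                beta_sens=float(np.exp(rng.uniform(-2, 4))))
            d = float(rng.uniform(-1, 1))
            assert optimal_rt(RiskInputs(delta_mu=d, choice=1), rp) >= 0.0


class TestPredictedSeries:
    def test_learning_shortens_reaction_times(self, response_default):
        pp = PerceptualParams(model="dynamic", lam=4.0, sigma_u=0.25)
        _, u = sample_outcomes_and_signals(np.full(60, 0.9), pp, seed=4)
        t = predicted_rt_series(run_recognition(u, pp), response_default)
        assert t[:10].mean() > t[-10:].mean()

    def test_sign_flip_symmetry(self, response_default):
        pp = PerceptualParams(model="dynamic", lam=2.0)
        _, u = sample_outcomes_and_signals(np.full(40, 0.8), pp, seed=5)
        tr = run_recognition(u, pp)
        t1 = predicted_rt_series(tr, response_default)
        # belief-favoured choices make only |delta_mu| matter
        choices = (tr.delta_mu > 0).astype(int)
        t2 = predicted_rt_series(tr, response_default, choices=choices)
        assert np.allclose(t1, t2)

    def test_length_mismatch_rejected(self, response_default):
        pp = PerceptualParams(model="dynamic", lam=2.0)
        _, u = sample_outcomes_and_signals(np.full(10, 0.8), pp, seed=6)
        tr = run_recognition(u, pp)
        with pytest.raises(ValueError):
            predicted_rt_series(tr, response_default, choices=np.ones(5))

    def test_hick_like_log_linearity(self, response_default):
        eps = np.linspace(0.05, 1.0, 200)
        from bayesrt.respond import _rt_from_eps
        t = _rt_from_eps(eps, response_default)
        pos = t > 0
        slope, icept = np.polyfit(np.log(eps[pos]), t[pos], 1)
        pred = slope * np.log(eps[pos]) + icept
        ss_res = np.sum((t[pos] - pred) ** 2)
        ss_tot = np.sum((t[pos] - t[pos].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999


class TestRTNoise:
    def test_seeded_simulation_deterministic(self):
        t = np.linspace(0.1, 0.5, 100)
        assert np.array_equal(simulate_rts(t, 4.0, 9), simulate_rts(t, 4.0, 9))

    def test_residual_variance_matches_precision(self):
        t = np.zeros(10_000)
        y = simulate_rts(t, 1.0, 10)
        assert np.var(y) == pytest.approx(1.0, rel=0.05)

    def test_noiseless_limit(self):
        t = np.linspace(0.1, 0.5, 50)
        assert np.array_equal(simulate_rts(t, math.inf, 0), t)


class TestRTLoglik:
    def test_zero_residuals_equal_normalisation(self):
        t = np.linspace(0.1, 0.5, 20)
        phi = 3.7
        expected = 0.5 * 20 * (math.log(phi) - math.log(2 * math.pi))
        assert rt_loglik(t, t, phi) == pytest.approx(expected, abs=1e-12)

    def test_matches_direct_density_sum(self):
        from scipy.stats import norm
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = rng.integers(3, 30)
            t = rng.normal(0.3, 0.1, n)
            y = t + rng.normal(0, 0.2, n)
            w = rng.uniform(0.1, 1.0, n)
            phi = float(rng.uniform(0.5, 50))
            direct = float(np.sum(norm.logpdf(y, t, (phi * w) ** -0.5)))
            assert rt_loglik(y, t, phi, w) == pytest.approx(direct, abs=1e-10)

    def test_weight_changes_are_separable(self):
        t = np.linspace(0.1, 0.5, 10)
        y = t + 0.05
        w = np.ones(10)
        base = rt_loglik(y, t, 2.0, w)
        w2 = w.copy()
        w2[3] = 0.5
        changed = rt_loglik(y, t, 2.0, w2)
        per_trial = (0.5 * (math.log(2.0 * 0.5) - math.log(2 * math.pi))
                     - 0.5 * 2.0 * 0.5 * 0.05**2)
        per_trial_old = (0.5 * (math.log(2.0) - math.log(2 * math.pi))
                         - 0.5 * 2.0 * 0.05**2)
        assert changed - base == pytest.approx(per_trial - per_trial_old)

    def test_invalid_weights_rejected(self):
        t = np.ones(3)
        with pytest.raises(ValueError):
            rt_loglik(t, t, 1.0, np.array([0.5, -0.1, 1.0]))
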