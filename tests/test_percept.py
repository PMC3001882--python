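import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bayesrt import (PerceptualParams, Representation,
                     effective_learning_rate, perceptual_free_energy,
                     predict_trial, run_recognition, sigmoid, update_trial)
from bayesrt.task import sample_association_path, sample_outcomes_and_signals

from _oracles import draw_decisive, exact_log_marginal


class TestSigmoid:
    @given(st.floats(-1e4, 1e4))
    def test_complementarity(self, a):
        assert sigmoid(a) + sigmoid(-a) == pytest.approx(1.0, abs=1e-12)

    def test_midpoint_and_saturation(self):
        assert sigmoid(0.0) == 0.5
        assert sigmoid(30.0) >= 1 - 1e-9
        assert np.isfinite(sigmoid(1e6))

    @given(st.floats(-10, 10), st.floats(1e-3, 5))
    def test_strictly_increasing(self, a, h):
        # away from float saturation the logistic is strictly monotone
        assert sigmoid(a + h) > sigmoid(a)


class TestPredictTrial:
    def test_static_first_trial_prior(self):
        pp = PerceptualParams(model="static", lam=1.0)
        m, v, xi = predict_trial(None, pp)
        assert (m, v) == (0.0, 1.0)
        assert xi == 0.5

    def test_dynamic_variance_inflation(self):
        pp = PerceptualParams(model="dynamic", lam=2.0)
        prev = Representation(mu_x=0.8, mu_a=0.3, sigma2_a=0.2, xi=0.6)
        m, v, _ = predict_trial(prev, pp)
        assert m == 0.3
        assert v == pytest.approx(0.7)

    def test_infinite_precision_reduces_to_carryover(self):
        pp = PerceptualParams(model="dynamic", lam=1e14)
        prev = Representation(mu_x=0.8, mu_a=0.3, sigma2_a=0.2, xi=0.6)
        m, v, _ = predict_trial(prev, pp)
        assert v == pytest.approx(0.2, rel=1e-9)


class TestUpdateTrial:
    def test_total_symmetry_ties_to_prior(self):
        pp = PerceptualParams(model="static", lam=1.0)
        pred = predict_trial(None, pp)
        u_mid = 0.5 * (pp.eta_face + pp.eta_house)
        rep = update_trial(pred, u_mid, pp)
        assert rep.mu_x == pytest.approx(0.5)
        assert rep.mu_a == pytest.approx(0.0, abs=1e-8)

    def test_high_discriminability_resolves_category(self):
        pp = PerceptualParams(model="dynamic", lam=1.0, sigma_u=0.25)
        rng = np.random.default_rng(0)
        x, u, ok = [], [], 0
        prev = None
        for _ in range(100):
            xk = int(rng.random() < 0.7)
            uk = draw_decisive(rng, pp, xk, min_llr=7.0)
            rep = update_trial(predict_trial(prev, pp), uk, pp)
            ok += abs(rep.mu_x - xk) < 1e-3
            prev = rep
        assert ok == 100

    def test_two_trial_grid_oracle(self):
        """VB moments against dense-grid exact Bayes on random instances."""
        rng = np.random.default_rng(42)
        for _ in range(15):
            pp = PerceptualParams(
                model="static",
                lam=float(np.exp(rng.uniform(-0.7, 1.4))),
                sigma_u=float(rng.uniform(0.25, 0.5)))
            a = rng.normal(0, pp.lam**-0.5)
            xs = (rng.random(2) < sigmoid(a)).astype(int)
            us = [draw_decisive(rng, pp, x) for x in xs]
            _, mean, var = exact_log_marginal(us, pp)
            tr = run_recognition(us, pp)
            assert abs(tr.mu_a[-1] - mean) < 0.05
            assert tr.sigma2_a[-1] / var == pytest.approx(1.0, abs=0.2)


class TestFreeEnergy:
    def test_lower_bounds_grid_evidence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            pp = PerceptualParams(
                model="static",
                lam=float(np.exp(rng.uniform(-0.7, 1.4))),
                sigma_u=float(rng.uniform(0.25, 0.5)))
            u = draw_decisive(rng, pp, int(rng.random() < 0.5))
            pred = predict_trial(None, pp)
            rep = update_trial(pred, u, pp)
            f = perceptual_free_energy(rep, pred, u, pp)
            log_z, _, _ = exact_log_marginal([u], pp)
            assert f <= log_z + 1e-6

    def test_update_ascends_from_initialisation(self):
        rng = np.random.default_rng(4)
        pp = PerceptualParams(model="static", lam=1.0)
        pred = predict_trial(None, pp)
        u = draw_decisive(rng, pp, 1)
        rep = update_trial(pred, u, pp)
        init = Representation(mu_x=0.5, mu_a=pred[0], sigma2_a=pred[1],
                              xi=pred[2])
        assert (perceptual_free_energy(rep, pred, u, pp)
                >= perceptual_free_energy(init, pred, u, pp))

    def test_degenerate_likelihood_limit(self):
        # u exactly at the category mean, vanishing sensory noise, xi = 0.5:
        # the bound approaches log(0.5) plus the sensory normalisation.
        pp = PerceptualParams(model="static", lam=1.0, sigma_u=1e-3)
        pred = predict_trial(None, pp)
        rep = update_trial(pred, pp.eta_house, pp)
        f = perceptual_free_energy(rep, pred, pp.eta_house, pp)
        sensory_const = -0.5 * math.log(2 * math.pi * pp.sigma_u**2)
        assert f - sensory_const == pytest.approx(math.log(0.5), abs=0.05)


class TestRunRecognition:
    def test_static_posterior_variance_decreases(self):
        pp = PerceptualParams(model="static", lam=1.0)
        _, u = sample_outcomes_and_signals(np.full(60, 0.8), pp, seed=0)
        tr = run_recognition(u, pp)
        assert np.all(np.diff(tr.sigma2_a) < 0)

    def test_dynamic_variance_floor(self):
        pp = PerceptualParams(model="dynamic", lam=2.0)
        _, u = sample_outcomes_and_signals(np.full(120, 0.8), pp, seed=1)
        tr = run_recognition(u, pp)
        assert np.all(tr.sigma2_a >= 1.0 / (pp.lam + 0.25) - 1e-9)

    def test_tracks_volatile_association(self):
        # use the first session whose true path is informative (leaves
        # zero); on flat paths there is no association to track
        pp = PerceptualParams(model="dynamic", lam=2.0, sigma_u=0.25)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            a = sample_association_path(pp, 100, rng)
            if np.std(a) >= 1.0:
                break
        _, u = sample_outcomes_and_signals(sigmoid(a), pp, rng)
        tr = run_recognition(u, pp)
        assert np.corrcoef(tr.mu_a, a)[0, 1] > 0.8

    def test_uninformative_stimuli_keep_prior(self):
        pp = PerceptualParams(model="dynamic", lam=4.0, sigma_u=1e4)
        u = np.random.default_rng(7).normal(0, 1, 50)
        tr = run_recognition(u, pp)
        assert np.max(np.abs(tr.mu_a)) < 0.05

    def test_recognition_is_causal(self):
        pp = PerceptualParams(model="dynamic", lam=2.0)
        _, u = sample_outcomes_and_signals(np.full(40, 0.8), pp, seed=8)
        full = run_recognition(u, pp)
        edited = u.copy()
        edited[25:] = -edited[25:]
        assert np.allclose(run_recognition(edited, pp).mu_a[:25],
                           full.mu_a[:25])

    def test_static_is_dynamic_zero_volatility_limit(self):
        # dynamic with lambda -> inf versus static with the matched
        # trial-1 prior (precision 1/sigma2_0)
        dyn = PerceptualParams(model="dynamic", lam=1e10, sigma2_0=1.0)
        sta = PerceptualParams(model="static", lam=1.0)
        _, u = sample_outcomes_and_signals(np.full(50, 0.8), dyn, seed=9)
        td, ts = run_recognition(u, dyn), run_recognition(u, sta)
        assert np.allclose(td.mu_a, ts.mu_a, atol=1e-4)
        assert np.allclose(td.sigma2_a, ts.sigma2_a, rtol=1e-4)


class TestLearningRate:
    def test_zero_prediction_error_yields_nan(self):
        pp = PerceptualParams(model="dynamic", lam=1e12)
        u = np.zeros(5) + 0.5 * (pp.eta_face + pp.eta_house)
        tr = run_recognition(u, pp)
        lr = effective_learning_rate(tr)
        assert np.all(np.isnan(lr))

    def test_monotone_in_volatility(self):
        meds = []
        for ll in (-2.0, -1.0, 0.0, 1.0, 2.0):
            pp = PerceptualParams(model="dynamic", lam=float(np.exp(ll)))
            _, u = sample_outcomes_and_signals(np.full(150, 0.8), pp, seed=5)
            meds.append(np.nanmedian(effective_learning_rate(
                run_recognition(u, pp))))
        assert all(np.diff(meds) < 0)
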