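"""Independent oracles shared by the unit and acceptance suites."""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from bayesrt import sigmoid
from bayesrt.percept import _loglik_terms

GRID = np.linspace(-15.0, 15.0, 6001)


def exact_log_marginal(u_seq, pp):
    """Dense-grid log-evidence and posterior moments of the association
    under the static perceptual model, by direct numerical integration."""
    lp = -0.5 * np.log(2 * np.pi / pp.lam) - 0.5 * pp.lam * GRID**2
    for u in u_seq:
        l0, l1, _ = _loglik_terms(u, pp)
        s = sigmoid(GRID)
        lp = lp + np.logaddexp(l1 + np.log(s), l0 + np.log1p(-s))
    log_z = float(logsumexp(lp) + np.log(GRID[1] - GRID[0]))
    w = np.exp(lp - logsumexp(lp))
    mean = float(np.sum(w * GRID))
    var = float(np.sum(w * (GRID - mean) ** 2))
    return log_z, mean, var


def draw_decisive(rng, pp, x, min_llr=5.0):
    """Sensory sample whose evidence clearly favours category ``x`` (the
    strong-evidence regime of the task). The floor keeps the residual
    category uncertainty below ~1%, so that comparing the causal
    recognition filter against the acausal dense-grid smoother measures
    the variational approximation rather than the filtering-smoothing
    difference."""
    eta = pp.eta_house if x == 1 else pp.eta_face
    while True:
        u = rng.normal(eta, pp.sigma_u)
        if abs(_loglik_terms(u, pp)[2]) >= min_llr:
            return u


def regression_learning_rate(trace):
    """Least-squares slope of belief change on outcome prediction error
    (the empirical Rescorla-Wagner weight over a session)."""
    prev = np.concatenate(([0.0], trace.mu_a[:-1]))
    d = trace.mu_a - prev
    pe = trace.mu_x - sigmoid(trace.mu_a)
    return float(np.sum(d * pe) / np.sum(pe * pe))
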