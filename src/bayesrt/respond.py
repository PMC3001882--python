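"""Response model: from beliefs to reaction times through a speed-accuracy
trade-off.

A subject's decision on each trial is scored by a loss with two terms: a
unit cost for a categorisation error and a linear cost ``beta_err * t`` for
deliberating ``t`` seconds (``beta_err`` is the number of errors the subject
trades against one second of delay). Within a trial, the belief about the
outcome category relaxes exponentially -- at rate ``beta_sens`` -- from the
pre-stimulus prediction ``xi`` towards the converged posterior ``mu_x``, so
waiting buys accuracy at the price of delay. Minimising the ensuing
posterior risk gives a closed-form optimal decision time

    t* = max(0, ln(beta_sens * eps / beta_err) / beta_sens),

where ``eps`` is the post-hoc prediction error ``mu_x - xi`` signed towards
the chosen category: trials whose prediction contradicts the outcome have
``eps <= 0`` and an optimal decision time of exactly zero (errors are
emitted instantly). Observed reaction times are the optimal times plus
i.i.d. Gaussian noise with precision ``phi``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .percept import RecognitionTrace

__all__ = [
    "ResponseParams",
    "RiskInputs",
    "loss",
    "posterior_risk",
    "optimal_rt",
    "predicted_rt_series",
    "simulate_rts",
    "rt_loglik",
]


@dataclass(frozen=True)
class ResponseParams:
    """Decision constants of the response model.

    beta_err:
        Loss trade-off (errors per second of delay), > 0.
    beta_sens:
        Within-trial convergence rate of the belief towards the posterior
        (sensitivity to post-hoc prediction error), in 1/s, > 0.
    phi:
        Precision of the Gaussian reaction-time noise, in 1/s^2, > 0.
    offset:
        Optional constant non-decision (motor) delay added to every
        predicted reaction time, in seconds. Not part of the core decision
        model; defaults to 0 and is excluded from inversion by default.
    """

    beta_err: float
    beta_sens: float
    phi: float = 1.0
    offset: float = 0.0

    def __post_init__(self):
        if not (self.beta_err > 0 and self.beta_sens > 0 and self.phi > 0):
            raise ValueError("beta_err, beta_sens and phi must be > 0")
        if self.offset < 0:
            raise ValueError("offset must be >= 0")


@dataclass(frozen=True)
class RiskInputs:
    """Inputs of the posterior-risk surface for a single trial.

    delta_mu:
        Post-hoc prediction error ``mu_x - xi`` in [-1, 1].
    choice:
        The subject's categorisation (0 = face, 1 = house).
    """

    delta_mu: float
    choice: int

    def __post_init__(self):
        if abs(self.delta_mu) > 1.0 + 1e-12:
            raise ValueError("|delta_mu| must be <= 1")
        if self.choice not in (0, 1):
            raise ValueError("choice must be 0 or 1")

    @property
    def eps(self) -> float:
        """Prediction error signed towards the chosen category."""
        return (2 * self.choice - 1) * self.delta_mu


def loss(choice: int, category: int, t: float, beta_err: float) -> float:
    """Loss of announcing ``choice`` at time ``t`` when ``category`` holds:
    a binary error cost plus a linear delay penalty."""
    if t < 0:
        raise ValueError("decision time must be >= 0")
    return float(choice != category) + beta_err * t


def posterior_risk(inputs: RiskInputs, t, params: ResponseParams):
    """Expected loss of committing to ``inputs.choice`` at peristimulus
    time ``t``, under the exponentially converging within-trial belief.

    Vectorised over ``t``. When the prediction error favours the choice
    (``eps > 0``) the risk is convex in ``t`` with an interior minimum once
    ``beta_sens * eps > beta_err``; otherwise delay only ever hurts.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("decision time must be >= 0")
    eps = inputs.eps
    if eps > 0:
        base = 0.0
    elif eps < 0:
        base = 1.0
    else:
        base = 0.5
    risk = base + eps * np.exp(-params.beta_sens * t) + params.beta_err * t
    if risk.ndim == 0:
        return float(risk)
    return risk


def optimal_rt(inputs: RiskInputs, params: ResponseParams) -> float:
    """Closed-form minimiser of the posterior risk, clipped at zero.

    Zero whenever the prediction error opposes the choice (categorisation
    errors are emitted instantly) or the delay cost dominates the marginal
    accuracy gain (``beta_sens * eps <= beta_err``).
    """
    eps = inputs.eps
    z = params.beta_sens * eps / params.beta_err
    if eps <= 0.0 or z <= 1.0:
        return params.offset
    return params.offset + math.log(z) / params.beta_sens


def predicted_rt_series(trace: RecognitionTrace, params: ResponseParams,
                        choices=None) -> np.ndarray:
    """Per-trial optimal reaction times from a recognition trace.

    By default the choice on each trial is the belief-favoured category
    (the sign of the post-hoc prediction error), so ``eps = |delta_mu|``.
    Passing explicit ``choices`` (e.g. observed responses) makes trials on
    which the choice opposes the belief come out at zero.
    """
    dmu = trace.delta_mu
    if choices is None:
        eps = np.abs(dmu)
    else:
        choices = np.asarray(choices)
        if choices.shape != dmu.shape:
            raise ValueError("choices length must match the trace")
        eps = (2 * choices - 1) * dmu
    return _rt_from_eps(eps, params)


def _rt_from_eps(eps: np.ndarray, params: ResponseParams) -> np.ndarray:
    """Vectorised optimal decision time for signed prediction errors."""
    z = params.beta_sens * np.asarray(eps, dtype=float) / params.beta_err
    t = np.zeros_like(z)
    act = z > 1.0
    t[act] = np.log(z[act]) / params.beta_sens
    return t + params.offset


def simulate_rts(t_star, phi: float, seed) -> np.ndarray:
    """Add i.i.d. Gaussian motor noise of precision ``phi`` to a series of
    optimal reaction times. ``seed`` may be an int or a Generator."""
    if not (phi > 0):
        raise ValueError("phi must be > 0")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    t_star = np.asarray(t_star, dtype=float)
    if math.isinf(phi):
        return t_star.copy()
    return t_star + rng.normal(0.0, phi**-0.5, size=t_star.shape)


def rt_loglik(y, t_star, phi: float, weights=None) -> float:
    """Gaussian log-likelihood of observed reaction times.

    Each trial contributes a normal log-density with precision
    ``phi * weight_k``; down-weighting a trial (e.g. an error trial with a
    tiny weight) effectively removes it from the fit.
    """
    y = np.asarray(y, dtype=float)
    t_star = np.asarray(t_star, dtype=float)
    if y.shape != t_star.shape:
        raise ValueError("y and t_star must have equal length")
    if weights is None:
        w = np.ones_like(y)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != y.shape:
            raise ValueError("weights length mismatch")
        if np.any(w <= 0) or np.any(w > 1):
            raise ValueError("weights must lie in (0, 1]")
    if not (phi > 0):
        raise ValueError("phi must be > 0")
    r = y - t_star
    return float(np.sum(0.5 * (np.log(phi * w) - math.log(2.0 * math.pi))
                        - 0.5 * phi * w * r**2))
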