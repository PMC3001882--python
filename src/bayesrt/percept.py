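"""Perceptual models of probabilistic cue-outcome learning and their
variational Bayesian inversion (the observer's recognition process).

The observer faces a stream of scalar sensory samples ``u_k`` (projections
of face/house images), each caused by a binary category ``x_k`` (0 = face,
1 = house) through a mixture-of-Gaussians likelihood

    u_k | x_k  ~  N(eta_house, sigma_u^2)^x_k  N(eta_face, sigma_u^2)^(1-x_k)

and a Bernoulli prior on the category whose probability is the sigmoid of a
hidden cue-outcome association ``a_k``:

    x_k | a_k  ~  Bernoulli(sigmoid(a_k)).

Two perceptual models differ only in the prior on the association:

* **static** -- the association is a single constant drawn once from
  ``N(0, 1/lambda)`` (``lambda`` = prior precision);
* **dynamic** -- the association follows a Gaussian random walk with
  transition precision ``lambda`` (so ``1/lambda`` is the volatility).

Recognition is a per-trial mean-field / Laplace scheme: the posterior is
factorised as Bernoulli(mu_x) x N(mu_a, sigma2_a), and on each trial the
sufficient statistics are iterated to a fixed point of the perceptual free
energy, a lower bound on the log-evidence of that trial's sensory sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PerceptualParams",
    "Representation",
    "RecognitionTrace",
    "RecognitionError",
    "sigmoid",
    "predict_trial",
    "update_trial",
    "perceptual_free_energy",
    "run_recognition",
    "effective_learning_rate",
]

_LOG_2PI = math.log(2.0 * math.pi)

# MacKay's probit-style moment correction for a Gaussian pushed through a
# logistic: E[sigmoid(a)] ~= sigmoid(m / sqrt(1 + pi*v/8)).
_MACKAY = math.pi / 8.0


def sigmoid(a):
    """Standard logistic function, numerically safe at extreme arguments."""
    a = np.asarray(a, dtype=float)
    out = np.empty_like(a)
    pos = a >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-a[pos]))
    ea = np.exp(a[~pos])
    out[~pos] = ea / (1.0 + ea)
    if out.ndim == 0:
        return float(out)
    return out


def _sigmoid_scalar(a: float) -> float:
    if a >= 0.0:
        return 1.0 / (1.0 + math.exp(-a))
    ea = math.exp(a)
    return ea / (1.0 + ea)


def _softplus(a: float) -> float:
    if a > 30.0:
        return a
    if a < -30.0:
        return math.exp(a)
    return math.log1p(math.exp(a))


class RecognitionError(RuntimeError):
    """Raised when the per-trial coordinate updates fail to converge."""

    def __init__(self, trial: int, message: str):
        self.trial = trial
        super().__init__(f"trial {trial}: {message}")


@dataclass(frozen=True)
class PerceptualParams:
    """Constants of the observer's generative (perceptual) model.

    Parameters
    ----------
    model:
        ``"static"`` or ``"dynamic"``.
    eta_face, eta_house:
        Category means of the sensory mixture (must differ).
    sigma_u:
        Sensory standard deviation (> 0).
    lam:
        For the dynamic model, the transition precision of the association
        random walk (inverse volatility); for the static model, the prior
        precision of the fixed association. Must be > 0.
    mu0, sigma2_0:
        Initial belief about the association used by the dynamic model
        before the first trial (the static model's trial-1 prior is
        ``N(0, 1/lam)`` by definition).
    """

    model: str = "dynamic"
    eta_face: float = -1.0
    eta_house: float = 1.0
    sigma_u: float = 0.5
    lam: float = 1.0
    mu0: float = 0.0
    sigma2_0: float = 1.0

    def __post_init__(self):
        if self.model not in ("static", "dynamic"):
            raise ValueError(f"unknown perceptual model {self.model!r}")
        if not (self.sigma_u > 0):
            raise ValueError("sigma_u must be > 0")
        if not (self.lam > 0):
            raise ValueError("lam (precision) must be > 0")
        if self.eta_face == self.eta_house:
            raise ValueError("eta_face and eta_house must differ")
        if not (self.sigma2_0 > 0):
            raise ValueError("sigma2_0 must be > 0")

    @property
    def discrimination_ratio(self) -> float:
        return abs(self.eta_house - self.eta_face) / self.sigma_u


@dataclass(frozen=True)
class Representation:
    """Sufficient statistics of the observer's posterior on one trial."""

    mu_x: float       # posterior mean of the outcome category (Bernoulli)
    mu_a: float       # posterior mean of the association (Gaussian)
    sigma2_a: float   # posterior variance of the association
    xi: float         # pre-stimulus prediction of the outcome category


@dataclass
class RecognitionTrace:
    """Per-trial representations and perceptual free energies."""

    mu_x: np.ndarray
    mu_a: np.ndarray
    sigma2_a: np.ndarray
    xi: np.ndarray
    free_energy: np.ndarray
    params: PerceptualParams = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.mu_x)

    @property
    def delta_mu(self) -> np.ndarray:
        """Post-hoc prediction error mu_x - xi (drives reaction times)."""
        return self.mu_x - self.xi

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "trial": np.arange(1, len(self) + 1),
                "mu_x": self.mu_x,
                "mu_a": self.mu_a,
                "sigma2_a": self.sigma2_a,
                "xi": self.xi,
                "free_energy": self.free_energy,
            }
        )


def predict_trial(prev: Representation | None, params: PerceptualParams):
    """Prior over the association for the coming trial, and the ensuing
    pre-stimulus outcome prediction ``xi``.

    Returns ``(m, v, xi)`` -- prior mean and variance of the association,
    and the prior predictive probability of category 1, computed with the
    MacKay variance correction for the Gaussian-through-logistic integral.
    """
    if params.model == "static":
        if prev is None:
            m, v = 0.0, 1.0 / params.lam
        else:
            m, v = prev.mu_a, prev.sigma2_a
    else:
        if prev is None:
            m, v = params.mu0, params.sigma2_0 + 1.0 / params.lam
        else:
            m, v = prev.mu_a, prev.sigma2_a + 1.0 / params.lam
    if not (v > 0):
        raise ValueError("prior variance must be positive")
    xi = _sigmoid_scalar(m / math.sqrt(1.0 + _MACKAY * v))
    return m, v, xi


def _loglik_terms(u: float, params: PerceptualParams):
    """Log-densities of u under each mixture component and their ratio."""
    s2 = params.sigma_u**2
    c = -0.5 * (_LOG_2PI + math.log(s2))
    l1 = c - (u - params.eta_house) ** 2 / (2.0 * s2)   # x = 1
    l0 = c - (u - params.eta_face) ** 2 / (2.0 * s2)    # x = 0
    return l0, l1, l1 - l0


def update_trial(
    pred,
    u: float,
    params: PerceptualParams,
    tol: float = 1e-8,
    max_iter: int = 200,
    trial: int = 0,
) -> Representation:
    """Free-energy-optimal sufficient statistics for one trial.

    Coordinate ascent on the per-trial free energy: the Bernoulli moment is
    ``mu_x = sigmoid(LLR(u) + mu_a)`` (sensory log-likelihood ratio plus the
    expected association), the Gaussian mode solves the 1-D concave problem
    ``mu_x*a - softplus(a) - (a - m)^2 / (2v)`` by Newton's method, and the
    variance is the Laplace curvature ``1/(sigmoid'(mu_a) + 1/v)``.
    """
    m, v, xi = pred
    if not (v > 0):
        raise ValueError("prior variance must be positive")
    if not math.isfinite(u):
        raise ValueError("sensory sample must be finite")
    _, _, llr = _loglik_terms(u, params)

    # Substituting the Bernoulli stationarity mu_x = sigmoid(llr + mu_a)
    # into the Gaussian one turns the coordinate fixed point into a scalar
    # root problem,
    #   g(a) = sigmoid(llr+a) - sigmoid(a)
    #          - (sigma2(a)/2) s'(a) (1 - 2 sigmoid(a)) - (a - m)/v = 0,
    # with sigma2(a) = 1/(s'(a) + 1/v). The third term is the skew
    # correction coming from the second-order expansion of E[softplus(a)]
    # in the free energy (it pulls the Gaussian mean towards the heavier
    # tail of the true posterior); the bounded belief terms confine the
    # root to |a - m| <= 1.5 v + 2. Safeguarded Newton with a bisection
    # fallback inside that bracket.
    inv_v = 1.0 / v

    def g(a: float) -> float:
        s0 = _sigmoid_scalar(a)
        sp = s0 * (1.0 - s0)
        s2 = 1.0 / (sp + inv_v)
        return (_sigmoid_scalar(llr + a) - s0
                - 0.5 * s2 * sp * (1.0 - 2.0 * s0) - (a - m) * inv_v)

    def _newton_from(a0: float, lo: float, hi: float) -> float | None:
        """Quick Newton iteration; returns None if it fails to settle."""
        mu = a0
        for _ in range(30):
            val = g(mu)
            if abs(val) < tol:
                return mu
            s1 = _sigmoid_scalar(llr + mu)
            s0 = _sigmoid_scalar(mu)
            sp = s0 * (1.0 - s0)
            s2 = 1.0 / (sp + inv_v)
            dcorr = 0.5 * (s2 * sp * (1.0 - 2.0 * s0) ** 2 * (1.0 - s2 * sp)
                           - 2.0 * s2 * sp**2)
            dval = s1 * (1.0 - s1) - sp - dcorr - inv_v
            if dval >= 0:
                return None
            cand = mu - val / dval
            if not (lo < cand < hi):
                return None
            mu = cand
        return None

    def _brent_in(lo: float, hi: float) -> float | None:
        from scipy.optimize import brentq

        glo, ghi = g(lo), g(hi)
        if glo == 0.0:
            return lo
        if ghi == 0.0:
            return hi
        if glo * ghi > 0:
            return None
        return float(brentq(g, lo, hi, maxiter=200,
                            xtol=1e-12 * (1.0 + abs(lo) + abs(hi))))

    lo0, hi0 = m - 1.5 * v - 2.0, m + 1.5 * v + 2.0   # g(lo0) > 0 > g(hi0)
    roots: list[float] = []
    if v < 3.5:
        # |d/da| of the belief terms < 1/v here, so the root is unique.
        r = _newton_from(m, lo0, hi0)
        if r is None:
            r = _brent_in(lo0, hi0)
        if r is not None:
            roots.append(r)
    else:
        # Large prior variance: the stationarity condition can have several
        # solutions (the per-trial free energy is multimodal). Scan for all
        # sign changes and keep the root with the highest free energy.
        grid_a = np.linspace(lo0, hi0, 33)
        vals = [g(float(a)) for a in grid_a]
        for i in range(len(grid_a) - 1):
            if vals[i] > 0.0 >= vals[i + 1] or vals[i] <= 0.0 < vals[i + 1]:
                r = _brent_in(float(grid_a[i]), float(grid_a[i + 1]))
                if r is not None:
                    roots.append(r)
    if not roots:
        raise RecognitionError(trial, "belief update did not converge")
    if len(roots) == 1:
        mu_a = roots[0]
    else:
        best_f, mu_a = -np.inf, roots[0]
        for r in roots:
            sp = _sigmoid_scalar(r) * (1.0 - _sigmoid_scalar(r))
            cand = Representation(mu_x=_sigmoid_scalar(llr + r), mu_a=r,
                                  sigma2_a=max(1.0 / (sp + inv_v), 1e-8),
                                  xi=xi)
            f = perceptual_free_energy(cand, pred, u, params)
            if f > best_f:
                best_f, mu_a = f, r
    mu_x = _sigmoid_scalar(llr + mu_a)

    sp = _sigmoid_scalar(mu_a)
    sigma2_a = 1.0 / (sp * (1.0 - sp) + inv_v)
    sigma2_a = max(sigma2_a, 1e-8)
    # Exactly ambiguous stimulus with a symmetric prior: resolve to xi.
    if llr == 0.0 and m == 0.0:
        mu_x = xi
    return Representation(mu_x=mu_x, mu_a=mu_a, sigma2_a=sigma2_a, xi=xi)


def perceptual_free_energy(repr_: Representation, pred, u: float,
                           params: PerceptualParams) -> float:
    """Variational lower bound on the log-evidence of ``u`` for one trial.

    Expected log-joint under the factorised posterior plus the entropies of
    its Bernoulli and Gaussian factors. The intractable ``E[softplus(a)]``
    term is handled by a second-order (Laplace-consistent) expansion.
    """
    m, v, _ = pred
    mu_x, mu_a, s2 = repr_.mu_x, repr_.mu_a, repr_.sigma2_a
    l0, l1, _ = _loglik_terms(u, params)
    s = _sigmoid_scalar(mu_a)
    e_softplus = _softplus(mu_a) + 0.5 * s2 * s * (1.0 - s)
    # E[ln p(u|x)] + E[ln p(x|a)]
    f = mu_x * l1 + (1.0 - mu_x) * l0 + mu_x * mu_a - e_softplus
    # E[ln p(a | history)]
    f += -0.5 * (_LOG_2PI + math.log(v)) - ((mu_a - m) ** 2 + s2) / (2.0 * v)
    # Entropies
    if 0.0 < mu_x < 1.0:
        f += -(mu_x * math.log(mu_x) + (1.0 - mu_x) * math.log(1.0 - mu_x))
    f += 0.5 * (_LOG_2PI + 1.0 + math.log(s2))
    return f


def run_recognition(u, params: PerceptualParams, tol: float = 1e-8,
                    max_iter: int = 200) -> RecognitionTrace:
    """Sequential recognition of a single cue stream.

    Parameters
    ----------
    u:
        1-D array of sensory samples (one cue stream, trial order).
    params:
        Observer constants, including which perceptual model is in force.
    """
    u = np.asarray(u, dtype=float)
    if u.ndim != 1 or u.size == 0:
        raise ValueError("u must be a non-empty 1-D array")
    n = u.size
    mu_x = np.empty(n)
    mu_a = np.empty(n)
    s2a = np.empty(n)
    xi = np.empty(n)
    fe = np.empty(n)
    prev: Representation | None = None
    for k in range(n):
        pred = predict_trial(prev, params)
        rep = update_trial(pred, float(u[k]), params, tol=tol,
                           max_iter=max_iter, trial=k + 1)
        mu_x[k], mu_a[k], s2a[k], xi[k] = rep.mu_x, rep.mu_a, rep.sigma2_a, rep.xi
        fe[k] = perceptual_free_energy(rep, pred, float(u[k]), params)
        prev = rep
    return RecognitionTrace(mu_x=mu_x, mu_a=mu_a, sigma2_a=s2a, xi=xi,
                            free_energy=fe, params=params)


def effective_learning_rate(trace: RecognitionTrace,
                            params: PerceptualParams | None = None,
                            pe_floor: float = 1e-10) -> np.ndarray:
    """Per-trial empirical learning rate: association-belief change divided
    by the outcome prediction error (``mu_x - xi``).

    At convergence of the recognition process the update of the association
    belief is proportional to the prediction error (a Rescorla-Wagner rule)
    with a weight set by the prediction variance, i.e. by the assumed
    volatility: the stationarity condition of the per-trial update reads
    ``mu_a - mu_a_prev ~= v_pred * (mu_x - sigmoid(mu_a))``, so the ratio
    of belief change to the outcome prediction error (belief minus the
    converged association prediction) recovers the effective
    prediction-error weight. Trials whose prediction error is numerically
    zero return NaN.
    """
    params = params or trace.params
    prev_mu = np.concatenate(([params.mu0 if params.model == "dynamic" else 0.0],
                              trace.mu_a[:-1]))
    d_mu = trace.mu_a - prev_mu
    pe = trace.mu_x - sigmoid(trace.mu_a)
    out = np.full(len(trace), np.nan)
    ok = np.abs(pe) > pe_floor
    out[ok] = d_mu[ok] / pe[ok]
    return out
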