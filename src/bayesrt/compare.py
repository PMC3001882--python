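"""Model comparison: single-subject log Bayes factors and group-level
random-effects Bayesian model selection (RFX BMS).

Free energies from the inversion are lower bounds on log model evidences,
so their difference is an approximate log Bayes factor. At the group level,
each subject is allowed to have drawn their "true" model from an unknown
multinomial; a variational scheme yields the Dirichlet posterior over model
frequencies, from which expected frequencies and exceedance probabilities
(the probability that one model is more frequent than any other) follow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma
from scipy.stats import beta as beta_dist

__all__ = [
    "BMSResult",
    "log_bayes_factor",
    "is_strong_evidence",
    "group_bms",
    "exceedance_probability",
]

STRONG_EVIDENCE_THRESHOLD = 3.0


def log_bayes_factor(f_a: float, f_b: float) -> float:
    """Approximate log Bayes factor of model a over model b (difference of
    free energies); zero means identical evidence."""
    if not (np.isfinite(f_a) and np.isfinite(f_b)):
        raise ValueError("free energies must be finite")
    return float(f_a - f_b)


def is_strong_evidence(lbf: float) -> bool:
    """Conventional decision rule: |log Bayes factor| >= 3 counts as
    strong evidence for one model over the other."""
    return abs(lbf) >= STRONG_EVIDENCE_THRESHOLD


@dataclass
class BMSResult:
    model_names: tuple[str, ...]
    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_probabilities: np.ndarray
    assignment_probs: np.ndarray  # subjects x models

    def to_dict(self) -> dict:
        return {
            "model_names": list(self.model_names),
            "dirichlet_alpha": self.dirichlet_alpha.tolist(),
            "expected_frequencies": self.expected_frequencies.tolist(),
            "exceedance_probabilities":
                self.exceedance_probabilities.tolist(),
        }


def _as_evidence_matrix(table):
    if isinstance(table, pd.DataFrame):
        names = tuple(str(c) for c in table.columns)
        F = table.to_numpy(dtype=float)
    else:
        F = np.asarray(table, dtype=float)
        names = tuple(f"model_{i}" for i in range(F.shape[1]))
    if F.ndim != 2 or F.shape[0] < 1 or F.shape[1] < 2:
        raise ValueError("evidence table must be subjects x (>=2) models")
    if not np.all(np.isfinite(F)):
        raise ValueError("evidence table must be finite")
    return F, names


def group_bms(table, alpha0: float = 1.0, n_samples: int = 1_000_000,
              seed: int = 0, tol: float = 1e-8, max_iter: int = 500
              ) -> BMSResult:
    """Random-effects BMS over an evidence table (rows = subjects,
    columns = models, entries = free energies).

    Variational updates of the Dirichlet posterior over model frequencies;
    exceedance probabilities use the closed Beta form for two models and
    seeded Monte-Carlo sampling otherwise. Only within-subject evidence
    differences matter: adding a constant to a subject's row is a no-op.
    """
    F, names = _as_evidence_matrix(table)
    n_sub, n_mod = F.shape
    alpha = np.full(n_mod, float(alpha0))
    F = F - F.max(axis=1, keepdims=True)
    for _ in range(max_iter):
        log_u = F + (digamma(alpha) - digamma(alpha.sum()))
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        u /= u.sum(axis=1, keepdims=True)
        alpha_new = alpha0 + u.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    expected = alpha / alpha.sum()
    xp = exceedance_probability(alpha, n_samples=n_samples, seed=seed)
    return BMSResult(model_names=names, dirichlet_alpha=alpha,
                     expected_frequencies=expected,
                     exceedance_probabilities=xp, assignment_probs=u)


def exceedance_probability(alpha, n_samples: int = 1_000_000,
                           seed: int = 0) -> np.ndarray:
    """P(frequency of model m exceeds all others) under Dirichlet(alpha).

    Two models: exact via the regularised incomplete Beta function.
    More models: Monte-Carlo over Dirichlet draws with a fixed seed.
    """
    alpha = np.asarray(alpha, dtype=float)
    if alpha.ndim != 1 or alpha.size < 2 or np.any(alpha <= 0):
        raise ValueError("alpha must be a vector of positive reals")
    if alpha.size == 2:
        p1 = float(beta_dist.sf(0.5, alpha[0], alpha[1]))
        return np.array([p1, 1.0 - p1])
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=int(n_samples))
    winners = np.argmax(draws, axis=1)
    return np.bincount(winners, minlength=alpha.size) / draws.shape[0]
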