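"""Monte-Carlo validation harness.

Two simulation series probe the whole pipeline with known ground truth:
series A draws observers that use the *static* perceptual model, series B
observers that use the *dynamic* one. For each simulated session the true
log-parameters are drawn uniformly from boxes in log space, a stimulus
stream is sampled from the observer's own generative model (a constant
association for series A, a random walk for series B), the observer's
recognition and optimal reaction times are simulated without
categorisation errors, reaction-time noise is added at a controlled
signal-to-noise ratio (SNR, in dB of the signal-power to noise-variance
ratio), and the response model is inverted under *both* perceptual
models. Recorded per simulation: the free-energy difference between the
two fitted models and the log-space sum-of-squared-errors (SSE) of the
parameter estimates under the true model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .invert import InversionConfig, SessionData, invert_response_model
from .percept import (PerceptualParams, Representation, predict_trial,
                      sigmoid, update_trial)
from .respond import ResponseParams, _rt_from_eps
from .task import sample_association_path

__all__ = [
    "MCConfig",
    "MCCellResult",
    "snr_to_noise",
    "simulate_error_free_session",
    "run_mc_cell",
    "sse_score",
    "summarize_tables",
]

_SERIES_MODEL = {"A": "static", "B": "dynamic"}


@dataclass(frozen=True)
class MCConfig:
    """One Monte-Carlo series' configuration."""

    series: str = "B"
    n_sims: int = 50
    n_trials: int = 100
    snr_db_levels: tuple[float, ...] = (40.0, 20.0, 0.0)
    sample_halfwidth: float = 2.0   # uniform log-parameter range around prior means
    seed: int = 0
    n_starts: int = 4               # inversion starts per model fit
    eta_face: float = -1.0
    eta_house: float = 1.0
    sigma_u: float = 0.5
    min_signal_sd: float = 0.02     # s; redraw sessions whose deterministic
                                    # RT modulation is below the scale of
                                    # learning-induced facilitation

    def __post_init__(self):
        if self.series not in _SERIES_MODEL:
            raise ValueError("series must be 'A' or 'B'")
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if not all(np.isfinite(self.snr_db_levels)):
            raise ValueError("snr levels must be finite")

    @property
    def true_model(self) -> str:
        return _SERIES_MODEL[self.series]


@dataclass
class MCCellResult:
    """Per-simulation outcomes of one (series, SNR) cell."""

    series: str
    snr_db: float
    delta_f: np.ndarray            # F_dynamic - F_static per simulation
    true_wins: np.ndarray          # bool, true model had the higher F
    sse_percept: np.ndarray        # squared log-error of the perceptual parameter
    sse_response: np.ndarray       # summed squared log-error of the response pair
    theta_true: np.ndarray = field(repr=False, default=None)
    theta_hat: np.ndarray = field(repr=False, default=None)
    n_resampled: int = 0
    n_failed: int = 0

    @property
    def delta_f_true(self) -> np.ndarray:
        """Free-energy difference in favour of the true model."""
        sign = 1.0 if self.series == "B" else -1.0
        return sign * self.delta_f

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "series": self.series,
            "snr_db": self.snr_db,
            "sim": np.arange(1, len(self.delta_f) + 1),
            "delta_f": self.delta_f,
            "delta_f_true": self.delta_f_true,
            "true_model_wins": self.true_wins,
            "sse_percept": self.sse_percept,
            "sse_response": self.sse_response,
        })


def snr_to_noise(t_star, snr_db: float) -> float:
    """Noise precision achieving a target SNR in dB: ten times the log10
    ratio of the deterministic reaction-time signal power (mean square) to
    the noise variance. With second-scale reaction times this makes "0 dB"
    correspond to noise of roughly unit variance."""
    t_star = np.asarray(t_star, dtype=float)
    sig_pow = float(np.mean(t_star**2))
    if sig_pow <= 0 or np.var(t_star) <= 1e-12 * sig_pow:
        raise ValueError("degenerate reaction-time signal: SNR undefined")
    noise_var = sig_pow / 10.0 ** (snr_db / 10.0)
    return 1.0 / noise_var


def simulate_error_free_session(p_outcome, percept: PerceptualParams,
                                rng, max_redraw: int = 200):
    """Simulate a cue stream and the observer's recognition of it, with no
    categorisation errors.

    Outcomes are drawn from the given per-trial probabilities; the sensory sample
    of a trial is redrawn (sequential rejection) if a misleading draw would
    leave the converged belief on the wrong side of 0.5, emulating the
    error-free sessions of the validation study. Returns ``(x, u, trace
    arrays)`` where the trace arrays are (mu_x, mu_a, sigma2_a, xi).
    """
    p = np.asarray(p_outcome, dtype=float)
    n = p.size
    x = np.empty(n, dtype=int)
    u = np.empty(n)
    stats = np.empty((n, 4))
    prev: Representation | None = None
    for k in range(n):
        x[k] = int(rng.random() < p[k])
        eta = percept.eta_house if x[k] == 1 else percept.eta_face
        pred = predict_trial(prev, percept)
        for _ in range(max_redraw):
            u_k = rng.normal(eta, percept.sigma_u)
            rep = update_trial(pred, float(u_k), percept, trial=k + 1)
            if abs(rep.mu_x - x[k]) < 0.5:
                break
        else:
            raise RuntimeError(f"could not draw an unambiguous sample "
                               f"at trial {k + 1}")
        u[k] = u_k
        stats[k] = (rep.mu_x, rep.mu_a, rep.sigma2_a, rep.xi)
        prev = rep
    return x, u, stats


# Uniform log-parameter sampling boxes. Response parameters share one box
# in both series. The perceptual boxes differ: static observers are drawn
# around unit prior precision -- the neighbourhood of the dynamic model's
# zero-volatility limit, which is where the static model is genuinely
# nested in the dynamic one and where its prior (worth about one trial of
# evidence) leaves almost no footprint in reaction times; dynamic
# observers span volatilities two log-units either side of 1.
_LAM_BOX = {"static": (-1.0, 1.0), "dynamic": (-2.0, 2.0)}
_RESPONSE_CENTRES = np.array([-2.0, 2.0])


def _draw_true_theta(rng, cfg: MCConfig) -> np.ndarray:
    lam_lo, lam_hi = _LAM_BOX[cfg.true_model]
    resp = _RESPONSE_CENTRES + rng.uniform(-cfg.sample_halfwidth,
                                           cfg.sample_halfwidth, 2)
    return np.concatenate(([rng.uniform(lam_lo, lam_hi)], resp))


def sse_score(estimated, true) -> float:
    """Sum of squared differences between estimated and true
    log-parameters."""
    estimated = np.asarray(estimated, dtype=float)
    true = np.asarray(true, dtype=float)
    if estimated.shape != true.shape:
        raise ValueError("length mismatch")
    return float(np.sum((estimated - true) ** 2))


def _simulate_one(sim_rng, cfg: MCConfig, snr_db: float):
    """One synthetic session at the target SNR; redraws parameter vectors
    whose optimal-RT series is degenerate (no signal variance)."""
    n_resampled = 0
    for _ in range(50):
        theta = _draw_true_theta(sim_rng, cfg)
        percept = PerceptualParams(model=cfg.true_model,
                                   lam=float(np.exp(theta[0])),
                                   eta_face=cfg.eta_face,
                                   eta_house=cfg.eta_house,
                                   sigma_u=cfg.sigma_u)
        # stimuli from the observer's own generative model: a constant
        # association (series A) or a random walk (series B)
        a_true = sample_association_path(percept, cfg.n_trials, sim_rng)
        p = np.clip(sigmoid(a_true), 1e-9, 1.0 - 1e-9)
        x, u, stats = simulate_error_free_session(p, percept, sim_rng)
        eps = np.abs(stats[:, 0] - stats[:, 3])
        rp = ResponseParams(beta_err=float(np.exp(theta[1])),
                            beta_sens=float(np.exp(theta[2])))
        t_star = _rt_from_eps(eps, rp)
        if (np.std(t_star) > cfg.min_signal_sd
                and int(np.sum(t_star > 0)) >= 10):
            phi = snr_to_noise(t_star, snr_db)
            y = t_star + sim_rng.normal(0.0, phi**-0.5, size=t_star.shape)
            return theta, u, y, n_resampled
        n_resampled += 1
    raise RuntimeError("could not draw a non-degenerate parameter vector")


def run_mc_cell(cfg: MCConfig, snr_db: float) -> MCCellResult:
    """Run all simulations of one (series, SNR) cell: generate, add noise,
    invert under both perceptual models, score."""
    series_code = 0 if cfg.series == "A" else 1
    delta_f = np.full(cfg.n_sims, np.nan)
    wins = np.zeros(cfg.n_sims, dtype=bool)
    sse_p = np.full(cfg.n_sims, np.nan)
    sse_r = np.full(cfg.n_sims, np.nan)
    th_true = np.full((cfg.n_sims, 3), np.nan)
    th_hat = np.full((cfg.n_sims, 3), np.nan)
    n_resampled = 0
    n_failed = 0
    for i in range(cfg.n_sims):
        sim_rng = np.random.default_rng(
            [cfg.seed, series_code, int(round(snr_db * 10)) + 10_000, i])
        try:
            theta, u, y, nr = _simulate_one(sim_rng, cfg, snr_db)
            n_resampled += nr
            data = SessionData(u=u, y=y, eta_face=cfg.eta_face,
                               eta_house=cfg.eta_house, sigma_u=cfg.sigma_u)
            icfg = InversionConfig(n_starts=cfg.n_starts, seed=i)
            fits = {m: invert_response_model(data, m, config=icfg)
                    for m in ("static", "dynamic")}
            df = fits["dynamic"].free_energy - fits["static"].free_energy
            delta_f[i] = df
            wins[i] = (df > 0) if cfg.true_model == "dynamic" else (df < 0)
            est = fits[cfg.true_model].theta_mean
            sse_p[i] = sse_score(est[:1], theta[:1])
            sse_r[i] = sse_score(est[1:], theta[1:])
            th_true[i] = theta
            th_hat[i] = est
        except (RuntimeError, ValueError):
            n_failed += 1
    ok = np.isfinite(delta_f)
    return MCCellResult(series=cfg.series, snr_db=snr_db,
                        delta_f=delta_f[ok], true_wins=wins[ok],
                        sse_percept=sse_p[ok], sse_response=sse_r[ok],
                        theta_true=th_true[ok], theta_hat=th_hat[ok],
                        n_resampled=n_resampled, n_failed=n_failed)


def summarize_tables(cells) -> dict[str, pd.DataFrame]:
    """Summaries over a grid of cells: mean free-energy difference in
    favour of the true model per (series, SNR), and mean SSE per (series,
    SNR, parameter group). Missing cells leave explicit NaN gaps."""
    series_all = sorted({c.series for c in cells})
    snr_all = sorted({c.snr_db for c in cells}, reverse=True)
    df_tab = pd.DataFrame(index=snr_all, columns=series_all, dtype=float)
    rows = []
    for c in cells:
        df_tab.loc[c.snr_db, c.series] = float(np.mean(c.delta_f_true))
        rows.append({"series": c.series, "snr_db": c.snr_db,
                     "group": "perceptual",
                     "mean_sse": float(np.mean(c.sse_percept))})
        rows.append({"series": c.series, "snr_db": c.snr_db,
                     "group": "response",
                     "mean_sse": float(np.mean(c.sse_response))})
    df_tab.index.name = "snr_db"
    sse_tab = (pd.DataFrame(rows)
               .pivot(index=["group", "snr_db"], columns="series",
                      values="mean_sse")
               .sort_index(ascending=[True, False]))
    return {"delta_f": df_tab, "sse": sse_tab}
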