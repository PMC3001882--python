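"""Synthetic associative-learning sessions.

Generates the stimulus stream of a probabilistic audio-visual association
task: two interleaved cue streams, each organised in blocks of trials
within which the cue-outcome association is constant, alternating between
"predictive" blocks (association away from chance) and "random" blocks
(association exactly 0.5). Block lengths are drawn uniformly from a range
(28-40 trials by default). The marginal outcome frequency over a balanced
schedule is 0.5, so outcome identity alone is unpredictable.

Alternatively, sessions can be generated directly from the observer's own
generative model (a constant or random-walk association on the logit
scale), which is what the Monte-Carlo benchmark uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .percept import PerceptualParams, sigmoid

__all__ = [
    "ScheduleConfig",
    "generate_schedule",
    "schedule_to_probs",
    "sample_association_path",
    "sample_outcomes_and_signals",
    "simulate_session",
    "write_trials_csv",
]


@dataclass(frozen=True)
class ScheduleConfig:
    """Layout of one session's block schedule (per cue stream)."""

    n_trials: int = 140
    block_len_range: tuple[int, int] = (28, 40)
    association_levels: tuple[float, ...] = (0.9, 0.7)
    include_random_blocks: bool = True
    n_cues: int = 2
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.block_len_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid block_len_range")
        if self.n_trials < lo:
            raise ValueError("n_trials smaller than the minimum block length")
        if not all(0.0 < p < 1.0 for p in self.association_levels):
            raise ValueError("association_levels must lie in (0, 1)")
        if self.n_cues < 1:
            raise ValueError("n_cues must be >= 1")


def generate_schedule(cfg: ScheduleConfig, rng=None) -> list[tuple[int, float]]:
    """Block plan for one cue stream: a list of ``(length, p_outcome)``.

    Predictive blocks cycle through ``association_levels``; when random
    blocks are requested every second block has ``p_outcome = 0.5``. The
    last block is truncated so the lengths sum to ``n_trials`` exactly.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    lo, hi = cfg.block_len_range
    blocks: list[tuple[int, float]] = []
    covered = 0
    i_level = 0
    predictive = True
    while covered < cfg.n_trials:
        length = int(rng.integers(lo, hi + 1))
        length = min(length, cfg.n_trials - covered)
        if predictive:
            p = cfg.association_levels[i_level % len(cfg.association_levels)]
            i_level += 1
        else:
            p = 0.5
        blocks.append((length, float(p)))
        covered += length
        if cfg.include_random_blocks:
            predictive = not predictive
    return blocks


def schedule_to_probs(blocks: list[tuple[int, float]]) -> np.ndarray:
    """Expand a block plan into a per-trial outcome-probability series."""
    return np.concatenate([np.full(n, p) for n, p in blocks])


def sample_association_path(params: PerceptualParams, n: int, seed) -> np.ndarray:
    """Ground-truth association path on the logit scale.

    Dynamic model: Gaussian random walk started at 0 with innovation
    variance ``1/lam``. Static model: a single draw from ``N(0, 1/lam)``
    repeated on every trial.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    sd = params.lam**-0.5
    if params.model == "static":
        return np.full(n, rng.normal(0.0, sd))
    return np.cumsum(rng.normal(0.0, sd, size=n))


def sample_outcomes_and_signals(p_outcome, params: PerceptualParams, seed):
    """Sample outcome categories and sensory signals given per-trial
    outcome probabilities (either a schedule or ``sigmoid(a_true)``)."""
    p = np.asarray(p_outcome, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("outcome probabilities must lie in (0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(
        seed, np.random.Generator) else seed
    x = (rng.random(p.shape) < p).astype(int)
    eta = np.where(x == 1, params.eta_house, params.eta_face)
    u = rng.normal(eta, params.sigma_u)
    return x, u


@dataclass
class _CueStream:
    cue: int
    a_true: np.ndarray
    p_outcome: np.ndarray
    category: np.ndarray
    signal: np.ndarray


def simulate_session(cfg: ScheduleConfig, params: PerceptualParams,
                     mode: str = "schedule") -> pd.DataFrame:
    """Full synthetic session as a tidy per-trial table.

    ``mode="schedule"`` draws outcomes from the block schedule (``a_true``
    is the logit of the scheduled probability); ``mode="generative"`` draws
    an association path from the perceptual model instead. Cue streams are
    generated independently and interleaved uniformly at random. One master
    seed (``cfg.seed``) drives per-component child streams.
    """
    if mode not in ("schedule", "generative"):
        raise ValueError("mode must be 'schedule' or 'generative'")
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(3 * cfg.n_cues + 1)
    streams: list[_CueStream] = []
    for c in range(cfg.n_cues):
        r_sched = np.random.default_rng(children[3 * c])
        r_path = np.random.default_rng(children[3 * c + 1])
        r_out = np.random.default_rng(children[3 * c + 2])
        if mode == "schedule":
            blocks = generate_schedule(cfg, r_sched)
            p = schedule_to_probs(blocks)
            if c % 2 == 1:
                # mirror the association for every second cue so the
                # marginal outcome frequency stays at chance
                p = 1.0 - p
            a_true = np.log(p / (1.0 - p))
        else:
            a_true = sample_association_path(params, cfg.n_trials, r_path)
            p = sigmoid(a_true)
        x, u = sample_outcomes_and_signals(p, params, r_out)
        streams.append(_CueStream(c + 1, a_true, p, x, u))

    r_mix = np.random.default_rng(children[-1])
    order = np.concatenate([np.full(cfg.n_trials, s.cue) for s in streams])
    r_mix.shuffle(order)
    pos = {s.cue: 0 for s in streams}
    rows = []
    for k, cue in enumerate(order, start=1):
        s = streams[cue - 1]
        i = pos[cue]
        rows.append((k, cue, s.a_true[i], s.p_outcome[i],
                     int(s.category[i]), s.signal[i]))
        pos[cue] += 1
    return pd.DataFrame(rows, columns=["trial", "cue", "a_true", "p_outcome",
                                       "category", "signal"])


def write_trials_csv(df: pd.DataFrame, path) -> None:
    """Write a session table as RFC-4180 CSV (trials 1-based)."""
    df.to_csv(path, index=False)
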