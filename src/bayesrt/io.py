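"""Trial-file I/O and run configuration.

Trial files are plain CSV (RFC 4180, UTF-8, "." decimal), one row per
trial, sorted by trial within cue:

    trial,cue,category,signal,rt,error

``rt`` is in seconds unless ``units="ms"`` is passed; ``error`` flags
categorisation-error trials, which are conventionally stored with a
reaction time of zero and are down-weighted to a tiny likelihood weight at
read time (effectively removing them from the fit without disturbing the
trial-by-trial learning structure).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .invert import SessionData

__all__ = [
    "DEFAULT_ERROR_WEIGHT",
    "read_trials",
    "write_trials",
    "RunConfig",
    "load_config",
]

DEFAULT_ERROR_WEIGHT = 1e-8
_REQUIRED_COLS = ("trial", "cue", "category", "signal", "rt", "error")


def read_trials(path, units: str = "s",
                error_weight: float = DEFAULT_ERROR_WEIGHT,
                eta_face: float = -1.0, eta_house: float = 1.0,
                sigma_u: float = 0.5) -> dict[str, SessionData]:
    """Read a trial CSV and split it into per-cue data streams.

    Error trials (``error == 1``) get their reaction time forced to zero
    and a likelihood weight of ``error_weight``; all other trials get
    weight 1. Returns a mapping from cue id to :class:`SessionData`.
    """
    if units not in ("s", "ms"):
        raise ValueError("units must be 's' or 'ms'")
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df.index[~df["error"].isin([0, 1])]
    if len(bad):
        raise ValueError(f"{path}: invalid error flag at row {bad[0] + 2}")
    rt = df["rt"].to_numpy(dtype=float)
    if units == "ms":
        rt = rt / 1000.0
    if np.any(rt[df["error"] == 0] < 0):
        raise ValueError(f"{path}: negative reaction time")
    df = df.assign(rt_s=rt)
    out: dict[str, SessionData] = {}
    for cue, g in df.groupby("cue", sort=True):
        g = g.sort_values("trial")
        err = g["error"].to_numpy(dtype=int)
        y = g["rt_s"].to_numpy(dtype=float).copy()
        y[err == 1] = 0.0
        w = np.where(err == 1, error_weight, 1.0)
        out[str(cue)] = SessionData(
            u=g["signal"].to_numpy(dtype=float), y=y, weights=w,
            eta_face=eta_face, eta_house=eta_house, sigma_u=sigma_u)
    return out


def write_trials(df: pd.DataFrame, path, units: str = "s") -> None:
    """Write a per-trial table with the canonical columns; ``rt`` values
    are converted if ``units="ms"`` is requested."""
    df = df.copy()
    if "error" not in df.columns:
        df["error"] = 0
    if units == "ms" and "rt" in df.columns:
        df["rt"] = df["rt"] * 1000.0
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Schema-validated run configuration (YAML)."""

    model: str = "dynamic"
    seed: int = 0
    units: str = "s"
    n_trials: int = 140
    block_len_range: tuple[int, int] = (28, 40)
    association_levels: tuple[float, ...] = (0.9, 0.7)
    include_random_blocks: bool = True
    n_cues: int = 2
    eta_face: float = -1.0
    eta_house: float = 1.0
    sigma_u: float = 0.5
    lam: float = 1.0
    beta_err: float = 0.135
    beta_sens: float = 7.4
    snr_db: float = 0.0
    error_weight: float = DEFAULT_ERROR_WEIGHT
    extra: dict = field(default_factory=dict)


def load_config(path) -> RunConfig:
    """Load a YAML configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping")
    known = set(RunConfig.__dataclass_fields__) - {"extra"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("block_len_range", "association_levels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)
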