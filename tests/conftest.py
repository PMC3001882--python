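"""Shared fixtures: small synthetic sessions with known ground truth."""

from __future__ import annotations

import numpy as np
import pytest

from bayesrt import (InversionConfig, MCConfig, PerceptualParams,
                     ResponseParams, SessionData, invert_response_model)
from bayesrt.bench import _simulate_one


@pytest.fixture(scope="session")
def session_40db():
    """A dynamic-observer session at 40 dB with its true log-parameters."""
    rng = np.random.default_rng([5, 0])
    theta, u, y, _ = _simulate_one(rng, MCConfig(series="B", seed=5), 40.0)
    return theta, SessionData(u=u, y=y)


@pytest.fixture(scope="session")
def fit_40db(session_40db):
    theta, data = session_40db
    res = invert_response_model(data, "dynamic",
                                config=InversionConfig(n_starts=4, seed=0))
    return theta, data, res


@pytest.fixture
def percept_default():
    return PerceptualParams(model="dynamic", lam=2.0)


@pytest.fixture
def response_default():
    return ResponseParams(beta_err=0.135, beta_sens=7.4)
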