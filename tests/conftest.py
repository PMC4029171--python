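"""Shared fixtures: small embryos and deterministic RNGs."""

import numpy as np
import pytest

from gastrusim.model_state import Params, initialize_embryo


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """A 60-cell embryo: fast enough for per-test construction."""
    p = Params()
    p.n_initial_epiblast = 60
    p.n_initial_sae = 8
    p.equil_iters_per_tick = 20
    p.oi_step_um = 1.0
    return p


@pytest.fixture
def tiny_embryo(tiny_params):
    return initialize_embryo(tiny_params, seed=7)


@pytest.fixture
def default_embryo():
    """The standard 1000-cell initial state (initialization only)."""
    return initialize_embryo(Params(), seed=3)
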