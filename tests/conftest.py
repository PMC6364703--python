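import copy

import pytest

from dielfba import fixtures as fx
from dielfba.assemble import assemble
from dielfba.optimize import solve_cascade


@pytest.fixture(scope="session")
def toy_spec():
    return fx.ToySpec()  # K=4, 2 light TPMs


@pytest.fixture(scope="session")
def toy_base(toy_spec):
    return fx.make_toy_gsm(toy_spec)


@pytest.fixture(scope="session")
def toy_config(toy_spec):
    return fx.make_toy_config(toy_spec)


@pytest.fixture(scope="session")
def _toy_model_master(toy_base, toy_config):
    return assemble(toy_base, toy_config)


@pytest.fixture
def toy_model(_toy_model_master):
    """A fresh, mutable copy of the assembled K=4 toy diel model."""
    return copy.deepcopy(_toy_model_master)


@pytest.fixture(scope="session")
def toy_cascade(_toy_model_master):
    """Solved cascade on the unscaled K=4 toy (read-only)."""
    return solve_cascade(copy.deepcopy(_toy_model_master))


@pytest.fixture(scope="session")
def toy_expr(toy_base, toy_spec):
    return fx.toy_expression(toy_base, toy_spec.n_tpm, seed=11)
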