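"""Shared fixtures: a session-scoped modelling stack at reduced problem sizes.

The session setup uses a 20k-sample training corpus with 500 RBF centers and
3k-draw target derivations — enough internal-model fidelity for the behaviour
under test while keeping the suite fast.  Everything is rebuilt from seeds at
test time; no stored fixture data.
"""

import numpy as np
import pytest

from speechplan.experiments import ExperimentConfig
from speechplan.io import build_setup
from speechplan.planner import SamplerConfig


@pytest.fixture(scope="session")
def setup():
    return build_setup(
        seed=0,
        n_train=20000,
        n_centers=500,
        n_derive=6000,
        derive_chains=12,
        derive_burn=500,
    )


@pytest.fixture(scope="session")
def plant(setup):
    return setup.plant


@pytest.fixture(scope="session")
def maps(setup):
    return setup.maps


@pytest.fixture(scope="session")
def inventory(setup):
    return setup.inventory


@pytest.fixture()
def fast_sampler():
    return SamplerConfig(chains=6, burn=300, draws=300, seed=11)


@pytest.fixture()
def experiment_config():
    return ExperimentConfig(sampler=SamplerConfig(chains=10, burn=500, draws=500))


@pytest.fixture()
def rng():
    # fresh, identical stream per test: deterministic and order-independent
    return np.random.default_rng(20240917)
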