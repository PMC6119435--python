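import numpy as np
import pytest

from iriscea import default_iris_parameters, toy_models


@pytest.fixture(scope="session")
def national():
    """The pooled national base case (default U-row reading)."""
    return default_iris_parameters()


@pytest.fixture(scope="session")
def national_complement():
    """The pooled national set with the U row read as printed exits."""
    return default_iris_parameters(stay_mode="complement")


@pytest.fixture(scope="session")
def toys():
    return toy_models()


@pytest.fixture()
def rng():
    return np.random.default_rng(977)


def _microsimulate(P, start, n_cycles, n_individuals, rng):
    """Independent trace oracle: simulate individuals one transition at a
    time and tabulate occupancy fractions."""
    states = rng.choice(len(start), size=n_individuals, p=start)
    occ = np.zeros((n_cycles + 1, len(start)))
    occ[0] = np.bincount(states, minlength=len(start)) / n_individuals
    cum = np.cumsum(P, axis=1)
    for c in range(1, n_cycles + 1):
        u = rng.random(n_individuals)
        states = (u[:, None] > cum[states]).sum(axis=1)
        occ[c] = np.bincount(states, minlength=len(start)) / n_individuals
    return occ


@pytest.fixture(scope="session")
def microsimulate():
    return _microsimulate
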