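import numpy as np
import pytest

from hergfit.fitting_io import default_fitting_spec
from hergfit.model import ModelConstants
from hergfit.protocol import default_fixture_protocol
from hergfit.synthetic import default_truth, make_problem


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def fixture_protocol():
    return default_fixture_protocol()


@pytest.fixture(scope="session")
def full_spec():
    return default_fitting_spec()


@pytest.fixture(scope="session")
def coarse_problem():
    """A quickly evaluable bound problem: default truth sampled every 20 ms."""
    problem, truth = make_problem(dt=20.0)
    return problem, truth


@pytest.fixture()
def theta_truth(coarse_problem):
    problem, truth = coarse_problem
    return np.array([getattr(truth.params, n) for n in problem.free_names])
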