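import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from solvshell.core import Frame
from solvshell.templates import (
    purine_template,
    pyrimidine_template,
    solute_only_topology,
    urea_template,
    water_template,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def purine():
    return purine_template()


@pytest.fixture(scope="session")
def pyrimidine():
    return pyrimidine_template()


@pytest.fixture(scope="session")
def urea():
    return urea_template()


@pytest.fixture(scope="session")
def water():
    return water_template()


@pytest.fixture(scope="session")
def purine_topology(purine):
    return solute_only_topology(purine)


@pytest.fixture()
def purine_frame(purine):
    """The purine alone, centered in a 60 A cube (no wrapping effects)."""
    return Frame(purine.coords + 30.0, np.full(3, 60.0))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260920)
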