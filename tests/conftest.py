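import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=25,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from neodh.fixtures import generate_fixture
from neodh.functionals import get_functional
from neodh.provider import build_integrals
from neodh.runner import RunConfig, run_single_point
from neodh.scf import run_neo_scf


@pytest.fixture(scope="session")
def h2_quantum():
    return generate_fixture("h2_quantum")


@pytest.fixture(scope="session")
def h2_bundle(h2_quantum):
    return build_integrals(h2_quantum.molecule, h2_quantum.basis,
                           grid_level=3, with_grid=True, with_df=True)


@pytest.fixture(scope="session")
def h2_neo_b3lyp(h2_quantum, h2_bundle):
    """Converged NEO-B3LYP (full epc-17.2, no MP2 admixture) on the H2
    fixture; shared across tests."""
    state, parts = run_neo_scf(functional=get_functional("neo-b3lyp"),
                               bundle=h2_bundle)
    return state, parts


@pytest.fixture(scope="session")
def h2_neo_b2plyp(h2_quantum, h2_bundle):
    """Full NEO double-hybrid single point on the H2 fixture."""
    return run_single_point(h2_quantum.molecule, RunConfig(
        functional="neo-b2plyp", basis=h2_quantum.basis),
        bundle=h2_bundle)


@pytest.fixture(scope="session")
def toy2x2():
    return generate_fixture("toy2x2")
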