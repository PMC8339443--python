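"""Shared fixtures: seeded Monte Carlo photon-record sets at test scale.

The session-scoped ``records`` fixture is the workhorse ensemble used by the
correlation/activation/acceptance tests (2e6 launched photons, a few hundred
detected).  ``tiny_records`` is a fast set for I/O and edge-case tests.
"""

import numpy as np
import pytest
from hypothesis import settings

from dcsim.mc_transport import (
    ActivationRegion,
    DetectionGeometry,
    OpticalMedium,
    run_mc,
)

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

SESSION_SEED = 123
SESSION_N_PHOTONS = 2_000_000
TINY_N_PHOTONS = 200_000


@pytest.fixture(scope="session")
def medium():
    return OpticalMedium()  # mu_s'=1/mm, mu_a=0.01/mm, 800 nm


@pytest.fixture(scope="session")
def geometry():
    return DetectionGeometry()  # rho=30 mm, r=2 mm


@pytest.fixture(scope="session")
def region():
    return ActivationRegion()  # 10x10x4 mm box centred at (15, 0, 15) mm


@pytest.fixture(scope="session")
def records(medium, geometry, region):
    """Main detected-photon ensemble at the default cerebral parameter set."""
    rec = run_mc(medium, geometry, region, SESSION_N_PHOTONS, seed=SESSION_SEED)
    assert rec.n_detected > 100, "session fixture unexpectedly sparse"
    return rec


@pytest.fixture(scope="session")
def tiny_records(medium, geometry, region):
    return run_mc(medium, geometry, region, TINY_N_PHOTONS, seed=7)


@pytest.fixture(scope="session")
def whole_medium_records(medium, geometry):
    """Same photons as ``tiny_records`` but tallied against the whole half-space."""
    return run_mc(
        medium, geometry, ActivationRegion.whole_medium(), TINY_N_PHOTONS, seed=7
    )
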