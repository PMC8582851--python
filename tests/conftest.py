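import numpy as np
import pytest

import esvpipe as ep


@pytest.fixture(scope="session")
def coeffs():
    return ep.load_coefficients()


@pytest.fixture(scope="session")
def small_bundle():
    """A 30x30 default-scenario study area shared by read-only tests."""
    return ep.generate_bundle(ep.GridSpec(30, 30), ep.Scenario(seed=7))


@pytest.fixture()
def single_class_composition():
    """Factory: a 4x4 composition that is 100% one land class everywhere."""

    def make(land_class: str, year: str = "2015") -> ep.LandComposition:
        fr = np.zeros((6, 4, 4))
        fr[ep.LAND_CLASSES.index(land_class)] = 1.0
        return ep.LandComposition(fr, ep.GridSpec(4, 4), year)

    return make
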