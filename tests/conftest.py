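import logging

import numpy as np
import pytest

import vasodose as vd

logging.getLogger("vasodose").setLevel(logging.ERROR)

#: canonical small test organ: four territories of decreasing size
FOUR_REGIONS = {"anterior": 0.4, "dorsal": 0.3, "ventral": 0.2, "posterior": 0.1}


@pytest.fixture(scope="session")
def fixture4():
    return vd.generate_fixture_brain(vd.FixtureConfig(fractions=dict(FOUR_REGIONS)))


@pytest.fixture(scope="session")
def fixture13():
    return vd.generate_fixture_brain(vd.FixtureConfig())


@pytest.fixture(scope="session")
def small_vasculature(fixture4):
    """One grown 4-region organ shared by the structural tests."""
    vasc = vd.build_organ_vasculature(fixture4, 120, vd.GrowthConfig(seed=1))
    return vasc


@pytest.fixture()
def sphere_region():
    def inside(p):
        p = np.atleast_2d(p)
        return (p**2).sum(axis=1) < 1.0

    def margin(p):
        p = np.atleast_2d(p)
        return 1.0 - np.sqrt((p**2).sum(axis=1))

    return vd.RegionDomain(
        name="sphere",
        inside_fn=inside,
        margin_fn=margin,
        bounds=np.array([[-1.0, -1.0, -1.0], [1.0, 1.0, 1.0]]),
        volume_fraction_target=1.0,
    )
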