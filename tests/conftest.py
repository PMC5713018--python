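import pytest

import shallowsea as ss


@pytest.fixture(scope="session")
def bands8():
    return ss.default_bandset()


@pytest.fixture(scope="session")
def bands6(bands8):
    return bands8.subset(6)


@pytest.fixture(scope="session")
def lib():
    return ss.default_library()


@pytest.fixture(scope="session")
def geom():
    return ss.Geometry(sun_zenith_deg=30.0, view_zenith_deg=10.0)


@pytest.fixture(scope="session")
def grid():
    return ss.default_grid()


@pytest.fixture(scope="session")
def forward6(bands6, lib, geom):
    return ss.ForwardModel(bands6, lib, geom)


@pytest.fixture(scope="session")
def small_scene():
    """A 16x16 noiseless depth-gradient scene reused across tests."""
    cfg = ss.SceneConfig(shape=(16, 16), seed=7, depth_kind="gradient",
                         depth_range=(0.5, 8.0))
    return ss.generate(cfg)
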