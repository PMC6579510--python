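import numpy as np
import pytest

from orbitrack import OrbitConfig, PSFModel, build_lut


@pytest.fixture(scope="session")
def psf():
    return PSFModel()


@pytest.fixture(scope="session")
def cfg():
    return OrbitConfig(dark_orbit_factor=2, count_threshold=30.0)


@pytest.fixture(scope="session")
def lut_f(psf, cfg):
    return build_lut(psf, cfg.orbit_radius, "lateral", cfg.n_sectors)


@pytest.fixture(scope="session")
def lut_g(psf, cfg):
    return build_lut(psf, cfg.orbit_radius, "axial", cfg.n_sectors)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
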