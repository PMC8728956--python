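import mcvox
import pytest


def _cfg(kind, photons=None, seed=None):
    return mcvox.parse_config(mcvox.make_fixture(kind, photons=photons, seed=seed))


@pytest.fixture(scope="session")
def cube_config():
    return _cfg("homogeneous_cube")


@pytest.fixture(scope="session")
def cube_result(cube_config):
    return mcvox.run_simulation(cube_config)


@pytest.fixture(scope="session")
def slab_result():
    return mcvox.run_simulation(_cfg("layered_slab"))


@pytest.fixture(scope="session")
def sphere_config():
    return _cfg("embedded_sphere")


@pytest.fixture(scope="session")
def sphere_result(sphere_config):
    return mcvox.run_simulation(sphere_config)


@pytest.fixture(scope="session")
def sphere_result_4workers(sphere_config):
    return mcvox.run_simulation(sphere_config, workers=4)


@pytest.fixture(scope="session")
def diffusion_result():
    """The infinite-medium validation condition at its full photon count."""
    return mcvox.run_simulation(_cfg("infinite_cyclic"))
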