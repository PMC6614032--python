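import numpy as np
import pytest

import urbheat as uh

#  fixed seeds so every run of the suite sees the same draws
SEED_DESK = 20170
SEED_TINY = 4242


@pytest.fixture(scope="session")
def desk_config():
    return uh.default_config(seed=SEED_DESK)


@pytest.fixture(scope="session")
def desk_run(desk_config):
    """The default synthetic study: 6 models, 2 scenarios, 50 cities,
    0.5 degC monthly noise."""
    return uh.run_pipeline(desk_config)


@pytest.fixture(scope="session")
def noiseless_run():
    """Same study with noise switched off: recovery should be exact."""
    cfg = uh.default_config(seed=SEED_DESK, noise_sd=0.0)
    return uh.run_pipeline(cfg)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast two-model configuration for structural pipeline tests."""
    return uh.default_config(
        seed=SEED_TINY,
        n_cities=12,
        models=[
            {"id": "a", "n_lat": 24, "n_lon": 48},
            {"id": "b", "n_lat": 32, "n_lon": 64},
        ],
    )


@pytest.fixture(scope="session")
def tiny_run(tiny_config):
    return uh.run_pipeline(tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(99)
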