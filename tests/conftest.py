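import numpy as np
import pytest

from onoffrf import ModelParams


@pytest.fixture(scope="session")
def params() -> ModelParams:
    return ModelParams()


@pytest.fixture(scope="session")
def short_params() -> ModelParams:
    """Reduced-duration parameters for fast dynamical tests."""
    return ModelParams(
        n_steps_pre=2000,
        n_steps_sound=2000,
        t_young=200,
        t_adult=2000,
        snapshot_times=(0, 200, 1000, 2000),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
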