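import numpy as np
import pytest

from lilbid.synthetic import SyntheticConfig, calibration_points


@pytest.fixture
def small_config():
    """A reduced simulated run (fast) with the default truth law."""
    return SyntheticConfig(n_droplets=60, seed=7)


@pytest.fixture
def cal_points():
    return calibration_points(SyntheticConfig())


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
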