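import numpy as np
import pytest

import scfsol
from scfsol.synthetic import NoiseSpec, SurfaceParams, generate_dataset


@pytest.fixture(scope="session")
def bundled():
    return scfsol.load_dataset("bundled")


@pytest.fixture(scope="session")
def noiseless_synthetic():
    """Deterministic synthetic dataset on the study grid, no noise."""
    return generate_dataset(SurfaceParams(), noise=NoiseSpec(sigma=0.0, seed=0))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
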