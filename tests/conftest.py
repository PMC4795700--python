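import numpy as np
import pytest

import gefcycle as gc


@pytest.fixture(scope="session")
def fixture_bundle():
    return gc.default_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_bundles(n, seed0=0, **kwargs):
    """Seeded synthetic bundles for property sweeps."""
    return [gc.sample_params(seed0 + i, **kwargs) for i in range(n)]
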