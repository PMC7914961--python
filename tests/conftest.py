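import numpy as np
import pytest

import mdea


@pytest.fixture(scope="session")
def fixtures():
    """Deterministic small series shared across the suite."""
    return mdea.make_fixtures(seed=0)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
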