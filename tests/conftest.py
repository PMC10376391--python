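import numpy as np
import pytest

from dkitex import BValueScheme


@pytest.fixture(scope="session")
def scheme() -> BValueScheme:
    """The default 13 b-value acquisition scheme."""
    return BValueScheme.default()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230745)
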