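import numpy as np
import pytest

from hemodual import HemoParams, PRIOR_MEANS


@pytest.fixture(scope="session")
def mean_params() -> HemoParams:
    """Balloon parameters at the prior means."""
    return HemoParams(**PRIOR_MEANS)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
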