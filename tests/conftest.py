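import numpy as np
import pytest

from atriasim import make_baseline_params, rest_state


@pytest.fixture(scope="session")
def baseline():
    return make_baseline_params()


@pytest.fixture(scope="session")
def rest(baseline):
    """Single-cell quiescent steady state of the modified model (cached)."""
    return rest_state(baseline)


@pytest.fixture()
def rng():
    return np.random.default_rng(20120223)
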