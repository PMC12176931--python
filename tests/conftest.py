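import numpy as np
import pytest

import knotpgm as kp


@pytest.fixture
def grid():
    return kp.TimeGrid.default()


@pytest.fixture
def population():
    return kp.default_population()


@pytest.fixture
def small_params(grid):
    """A small, well-conditioned parameter set used across oracle tests."""
    return kp.PGMParameters(
        alpha=np.array([10.0, 1.0, -0.5]),
        omega_eta=np.array(
            [[4.0, 0.5, 0.2], [0.5, 0.4, 0.1], [0.2, 0.1, 0.3]]
        ),
        sigma2_eps=np.array([1.0, 1.5, 2.0, 1.0, 0.5, 1.2, 0.8]),
        gamma=2.5,
    )
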