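import numpy as np
import pytest

from flockscale import synthetic


@pytest.fixture(scope="session")
def positions_100():
    """Representative uniform position set, N=100 in 800x800 um."""
    return synthetic.generate_positions(100, "uniform", (0, 800, 0, 800), seed=1)


@pytest.fixture(scope="session")
def positions_3():
    """Tiny all-to-all triangle used by the quadrature oracles."""
    return synthetic.PositionSet(
        np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.0]]), (0, 20, 0, 20)
    )


@pytest.fixture(scope="session")
def meanfield_200():
    """N=200 uniform positions for the mean-field (all-to-all) experiments."""
    return synthetic.generate_positions(200, "uniform", (0, 800, 0, 800), seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
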