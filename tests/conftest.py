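import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from asterwave import synth
from asterwave.params import Grid1D, ModelParams


@pytest.fixture(scope="session")
def unstable_params() -> ModelParams:
    """Extract-like truth on the unstable side of the phase boundary."""
    return synth.extract_like()


@pytest.fixture(scope="session")
def stable_params() -> ModelParams:
    """Bead-like truth on the stable side."""
    return synth.bead_like()


@pytest.fixture(scope="session")
def grid() -> Grid1D:
    return Grid1D(200.0, 128)


@pytest.fixture(scope="session")
def steady_pair_unstable(unstable_params, grid):
    from asterwave.continuum import symmetric_pair_profile

    return symmetric_pair_profile(unstable_params, grid)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
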