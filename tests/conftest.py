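import numpy as np
import pytest

from spheroquant import (
    InvasionSimParams,
    generate_spheroid_stack,
    max_project,
)


@pytest.fixture(scope="session")
def pairs_stack():
    """Projected image + ground truth for a 3-contacting-pairs fixture."""
    params = InvasionSimParams(n_cells=6, n_contacting_pairs=3, seed=0)
    stack, truth = generate_spheroid_stack(params)
    return max_project(stack), truth


@pytest.fixture(scope="session")
def separated_stack():
    """Projected image + ground truth with 20 well-separated nuclei."""
    params = InvasionSimParams(n_cells=20, seed=11)
    stack, truth = generate_spheroid_stack(params)
    return max_project(stack), truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
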