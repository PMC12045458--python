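import logging

import numpy as np
import pytest

from lumpedear import (
    Stimulus,
    assemble_matrices,
    default_grid,
    get_builtin,
    solve_response,
)

# silence the substitution warnings emitted by the adopted parameter sets
logging.getLogger("lumpedear").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def fitted():
    return get_builtin("fitted")


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def bc_response(fitted, grid):
    """Bone-conduction response of the fitted model on the default grid."""
    return solve_response(
        assemble_matrices(fitted), Stimulus(mode="BC", amplitude=1.0), grid, fitted
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
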