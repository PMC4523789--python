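"""Shared fixtures: small tasks/grids sized for exhaustive oracle checks."""

import numpy as np
import pytest

from quicksdt.engine import ParameterGrid, build_prior, default_prior
from quicksdt.tasks import make_task


@pytest.fixture
def small_qyn_task():
    """qYN task over five contrast levels."""
    return make_task("qYN", contrasts=np.geomspace(0.02, 0.5, 5))


@pytest.fixture
def small_grid():
    """27-node (3 x 3 x 3) qYN parameter grid for brute-force comparisons."""
    return ParameterGrid(
        {
            "tau": np.geomspace(0.03, 0.4, 3),
            "gamma": np.geomspace(1.0, 3.0, 3),
            "lam": np.linspace(0.2, 1.8, 3),
        }
    )


@pytest.fixture
def small_prior(small_qyn_task, small_grid):
    return build_prior(small_grid, default_prior(small_qyn_task, small_grid))
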