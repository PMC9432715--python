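import numpy as np
import pytest

from cryptcomp import (
    build_generator,
    default_time_grid,
    exemplary_tissue,
    generate_incidence,
    solve_absorption,
)


@pytest.fixture(scope="session")
def colon_tissue():
    """Representative colon parameter set (well-mixed niche)."""
    return exemplary_tissue("colon")


@pytest.fixture(scope="session")
def colon_grid():
    return default_time_grid()


@pytest.fixture(scope="session")
def colon_curves(colon_tissue, colon_grid):
    return solve_absorption(build_generator(colon_tissue.niche), colon_grid)


@pytest.fixture(scope="session")
def noise_free_table(colon_tissue):
    """Synthetic incidence table with counts set to their expectations."""
    return generate_incidence(colon_tissue, noise="none")
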