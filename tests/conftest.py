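import numpy as np
import pytest

from nichecast import (
    VirtualSpecies,
    generate_env_stack,
    generate_strata,
)


@pytest.fixture(scope="session")
def env50():
    """A 50x50 current-scenario world, autocorrelation length 3 cells."""
    return generate_env_stack((50, 50), cell_size=10.0,
                              autocorrelation_length=30.0, seed=101)


@pytest.fixture(scope="session")
def strata50():
    return generate_strata((50, 50), 5, seed=102)


@pytest.fixture(scope="session")
def warm_species():
    """A virtual species with a mid-grid climatic optimum."""
    return VirtualSpecies(
        "warm",
        {"BIO5": (33.0, 5.0), "BIO6": (5.0, 5.0), "BIO12": (650.0, 400.0)},
    )


def rook_morans_i(field: np.ndarray) -> float:
    """Direct Moran's I over rook (4-neighbour) adjacency.

    Computed straight from the definition: (n/W) * sum_ij w_ij z_i z_j /
    sum_i z_i^2 with z the centred field, as an independent oracle for the
    spatial-autocorrelation checks.
    """
    z = field - field.mean()
    num = 2.0 * ((z[:, :-1] * z[:, 1:]).sum() + (z[:-1, :] * z[1:, :]).sum())
    rows, cols = field.shape
    w_total = 2 * (rows * (cols - 1) + cols * (rows - 1))
    return (field.size / w_total) * num / (z**2).sum()
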