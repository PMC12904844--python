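import numpy as np
import pytest

from topoccu.raster import ElevationGrid
from topoccu.simulate import generate_landscape, make_truth, simulate_survey


def plane_grid(gx=0.0, gy=0.0, n=7, cell=1.0, z0=100.0):
    """Elevation plane z = z0 + gx * x_east + gy * y_north."""
    vals = np.fromfunction(lambda r, c: z0 + gx * c * cell + gy * (n - 1 - r) * cell, (n, n))
    return ElevationGrid(values=vals, cell_size=cell)


@pytest.fixture(scope="session")
def small_landscape():
    """A 15-site synthetic landscape shared across tests (hourly solar step)."""
    grid, covs = generate_landscape(15, seed=7, solar_step_minutes=60.0)
    return grid, covs


@pytest.fixture(scope="session")
def small_survey(small_landscape):
    """Truth + records + deployments for the small landscape."""
    _, covs = small_landscape
    truth = make_truth(covs, n_species=6, variable="ruggedness", seed=7)
    records, deployments = simulate_survey(truth, covs, n_occasions=10)
    return truth, records, deployments
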