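import numpy as np
import pytest

from envconn import inverse as inv
from envconn import simulate as sim
from envconn.rois import load_network_table


@pytest.fixture(scope="session")
def table():
    return load_network_table()


@pytest.fixture(scope="session")
def montage32():
    return sim.synthetic_montage(32)


@pytest.fixture(scope="session")
def leadfield_small(montage32):
    """Coarse 18 mm grid: fast enough for per-test inverse work."""
    _, pos = montage32
    grid = inv.make_source_grid(18.0)
    return inv.build_spherical_leadfield(pos, grid=grid, spacing=18.0)


@pytest.fixture(scope="session")
def operator_small(leadfield_small):
    return inv.compute_eloreta_operator(leadfield_small)


@pytest.fixture(scope="session")
def leadfield_roi(montage32, table):
    """13 mm grid with the 21 ROI centres appended as exact nodes."""
    _, pos = montage32
    grid = inv.make_source_grid(13.0, include_points=table.coords_head)
    return inv.build_spherical_leadfield(pos, grid=grid, spacing=13.0)


@pytest.fixture(scope="session")
def operator_roi(leadfield_roi):
    return inv.compute_eloreta_operator(leadfield_roi)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
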