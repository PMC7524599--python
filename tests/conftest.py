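import numpy as np
import pytest

from swmpam.geometry import ScanGeometry
from swmpam.phantom import make_grid_chart


@pytest.fixture(scope="session")
def grid_chart():
    """Canonical 200x200 grid chart, pitch 20 px, line width 2 px."""
    return make_grid_chart(200, 200, 20, 2)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def toy_geometry(n: int, n_time: int = 32) -> ScanGeometry:
    """Scan geometry matching an n x n lateral raster at the default steps."""
    return ScanGeometry(scan_area_mm=(n * 4e-3, n * 6e-3))


@pytest.fixture()
def geometry16():
    return toy_geometry(16)
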