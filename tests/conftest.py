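import numpy as np
import pytest

from marct.ct_sim import ScanGeometry
from marct.io import RunConfig
from marct.materials import load_attenuation_table, load_spectrum
from marct.phantom import GridSpec
from marct.study import run_study
from marct.volumes import Volume


@pytest.fixture(scope="session")
def table():
    return load_attenuation_table()


@pytest.fixture(scope="session")
def spectrum():
    return load_spectrum()


@pytest.fixture(scope="session")
def study_grid():
    """Desk-scale study grid: 128x128 at 3 mm, single slice for unit tests."""
    return GridSpec(n_xy=128, spacing_mm=3.0, n_slices=1)


@pytest.fixture(scope="session")
def study_geometry():
    return ScanGeometry.for_grid(128, 3.0, n_views=180)


@pytest.fixture(scope="session")
def study_report():
    """One full two-metal study at the default configuration (seeded)."""
    return run_study(RunConfig(master_seed=1))


def water_volume(n=64, spacing=3.0, value=0.0):
    half = n * spacing / 2.0
    return Volume(np.full((1, n, n), value), (2.5, spacing, spacing),
                  (-1.25, -half, -half))
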