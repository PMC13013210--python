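import numpy as np
import pytest

from simmermap.grid import Grid
from simmermap.synthetic import ScenarioConfig, make_scenario

TRANSFORM = (500_000.0, 250.0, 0.0, 4_100_000.0, 0.0, -250.0)
CRS = "EPSG:32636"


def make_grid(values, nodata=-9999.0, crs=CRS, transform=TRANSFORM):
    return Grid(np.asarray(values), transform, crs, nodata=nodata)


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic world, generated once per session."""
    return make_scenario(ScenarioConfig())


@pytest.fixture(scope="session")
def small_bundle():
    """A miniature world for fast interpolation/exposure tests."""
    return make_scenario(ScenarioConfig(shape=(40, 40), n_stations=25, n_zones=4,
                                        total_population=10_000))
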