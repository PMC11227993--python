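import numpy as np
import pytest

from ntpipe import AtlasGeometry, Bold4D, CohortSpec, default_toy_atlas, simulate_cohort


@pytest.fixture(scope="session")
def toy_atlas():
    return default_toy_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """One modest planted cohort shared across read-only tests."""
    return simulate_cohort(CohortSpec(n_cn=12, n_ad=12, seed=20240101))


def make_bold(series_grid: np.ndarray, tr_s: float = 2.2) -> Bold4D:
    """Wrap an (x, y, z, t) array in a Bold4D with a matching 4 mm geometry."""
    dims = series_grid.shape[:3]
    geom = AtlasGeometry(dims, (4.0, 4.0, 4.0), (0.0, 0.0, 0.0))
    return Bold4D(values=series_grid, tr_s=tr_s, geometry=geom)


@pytest.fixture
def bold_factory():
    return make_bold
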