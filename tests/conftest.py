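import numpy as np
import pytest

from roamlight import make_design


@pytest.fixture(scope="session")
def tiny_design():
    """Desk-scale design: full 8-run block structure on a small grid."""
    return make_design({"grid_dims": (10, 12, 8), "n_volumes_per_run": 56})


@pytest.fixture(scope="session")
def micro_design():
    """Smallest valid session: 2 runs, short grid, for fast GLM checks."""
    return make_design({"grid_dims": (8, 8, 6), "n_volumes_per_run": 50,
                        "n_runs": 2})


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
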