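import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def grid243():
    """The instrument's wavelength grid: 243 bands, 550-1700 nm at 4.77 nm."""
    return 550.0 + 4.77 * np.arange(243)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotations(n_control, n_salinity, day=18):
    rows = []
    for i in range(n_control):
        rows.append({"genotype": "IR29", "treatment": "control", "day": day,
                     "replicate": i + 1})
    for i in range(n_salinity):
        rows.append({"genotype": "IR29", "treatment": "salinity", "day": day,
                     "replicate": i + 1})
    return pd.DataFrame(rows)


@pytest.fixture
def small_sim_config():
    """Down-scaled images; experiment structure unchanged."""
    from hsion import SimulationConfig

    return SimulationConfig(image_height=32, image_width=32, seed=11)
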