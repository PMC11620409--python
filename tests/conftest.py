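import numpy as np
import pytest

from pxrfkit import simulate
from pxrfkit.lines import default_line_table


@pytest.fixture(scope="session")
def line_table():
    return default_line_table()


@pytest.fixture(scope="session")
def small_study():
    """One fish + one bird specimen, two dwell times: enough structure for
    ingestion, QC and thickness without a long simulation."""
    cfg = simulate.default_config(
        n_specimens=1, taxa=("fish", "bird"), seed=42, dwell_times=(20.0, 80.0)
    )
    records, truth = simulate.simulate_study(cfg)
    return cfg, records, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
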