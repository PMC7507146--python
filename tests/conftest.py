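import numpy as np
import pandas as pd
import pytest

from streamstoich.simulate import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic world shared by read-only tests."""
    config = SyntheticConfig(
        n_sites=30, obs_per_site=15, n_timeseries_sites=2, timeseries_obs=120, seed=11
    )
    return generate_dataset(config)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_sample_frame(rows):
    """Wide ingest-dialect frame from a list of dicts (helper for tests)."""
    frame = pd.DataFrame(rows)
    if "date" in frame.columns:
        frame["date"] = pd.to_datetime(frame["date"])
    return frame
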