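import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def golden():
    with (DATA_DIR / "golden_records.json").open() as fh:
        return json.load(fh)


@pytest.fixture(scope="session")
def example_slow5_path():
    return DATA_DIR / "example.slow5"


@pytest.fixture(scope="session")
def synthetic_reads():
    """Small seeded PromethION-like dataset shared by analysis tests."""
    from exzd import SyntheticModel, simulate_dataset

    return simulate_dataset(SyntheticModel(), num_reads=20, read_length_mean=3000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
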