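import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from restrans.simulate import GeneratorConfig, generate_dataset


@pytest.fixture
def tiny_table():
    """4 samples x 3 ASVs with simple presence structure."""
    return pd.DataFrame(
        [[3, 0, 5], [1, 2, 0], [0, 0, 7], [4, 4, 4]],
        index=["S1", "S2", "S3", "S4"],
        columns=["A1", "A2", "A3"],
    )


@pytest.fixture
def two_pop_meta():
    """2 populations x 2 field samples."""
    return pd.DataFrame(
        {
            "population": ["A", "A", "B", "B"],
            "source": ["field"] * 4,
            "timepoint": [np.nan] * 4,
            "tank": [np.nan] * 4,
        },
        index=pd.Index(["A1s", "A2s", "B1s", "B2s"], name="sample_id"),
    )


def small_config(**kwargs):
    """Scaled-down study design for fast unit tests."""
    defaults = dict(
        n_populations=3,
        n_field_per_pop=3,
        garden_timepoints_days=(1.0, 2.0, 7.0, 14.0),
        n_garden_per_pop_per_timepoint=2,
        n_tanks_per_pop=2,
        n_resident_asvs_per_pop=8,
        n_shared_core_asvs=10,
        n_transient_pool_asvs=30,
        seed=202,
    )
    defaults.update(kwargs)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="session")
def default_dataset():
    """One default-condition dataset shared by the whole suite."""
    return generate_dataset(GeneratorConfig(seed=101))


@pytest.fixture(scope="session")
def small_dataset():
    return generate_dataset(small_config())
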