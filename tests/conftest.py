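import numpy as np
import pandas as pd
import pytest

from faire_memory.region_core import RegionCountMatrix, make_sample_meta
from faire_memory.synthetic_data import SyntheticDatasetSpec, generate_dataset


@pytest.fixture(scope="session")
def small_spec():
    return SyntheticDatasetSpec(seed=7, n_regions=200)


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    """200-region fixture with reads and sequences, shared across tests."""
    return generate_dataset(small_spec, with_reads=True, with_sequences=True)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_counts(values: dict, region_ids=None) -> RegionCountMatrix:
    """Helper: RegionCountMatrix from {sample: list-of-counts}."""
    df = pd.DataFrame(values)
    if region_ids is not None:
        df.index = region_ids
    else:
        df.index = [f"r{i}" for i in range(len(df))]
    return RegionCountMatrix(df, make_sample_meta(df.columns))
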