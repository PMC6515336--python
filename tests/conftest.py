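import numpy as np
import pandas as pd
import pytest

from diliqsar.descriptors import DescriptorMatrix
from diliqsar.standardize import standardize_dataset
from diliqsar.synthetic_fixtures import (
    SyntheticSpec,
    generate_synthetic_dataset,
    toy_smiles_fixture,
)


@pytest.fixture(scope="session")
def toy_records():
    return toy_smiles_fixture()


@pytest.fixture(scope="session")
def toy_standardized(toy_records):
    records, report = standardize_dataset(toy_records)
    return records, report


@pytest.fixture(scope="session")
def small_signal_dataset():
    """Balanced 2-class Gaussian descriptor set with clear signal."""
    spec = SyntheticSpec(n=300, n_features=20, signal=2.0, n_informative=4, seed=42)
    return generate_synthetic_dataset(spec)


def make_matrix(values: np.ndarray, ids=None, names=None) -> DescriptorMatrix:
    """Helper for hand-built descriptor matrices in tests."""
    values = np.asarray(values, dtype=float)
    ids = ids or [f"c{i}" for i in range(values.shape[0])]
    names = names or [f"f{i}" for i in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(ids, name="compound_id"), columns=names)
    return DescriptorMatrix(df, {n: "test" for n in names}, "test")
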