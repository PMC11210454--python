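import numpy as np
import pandas as pd
import pytest

from cqdiff import CqMatrix, SampleMetadata, SyntheticConfig, simulate_cq_dataset


def make_cq(values, roles=None, samples=None, assays=None) -> CqMatrix:
    """Build a small CqMatrix from a 2-D list (np.nan = not detected)."""
    arr = np.asarray(values, dtype=float)
    samples = samples or [f"s{i+1}" for i in range(arr.shape[0])]
    assays = assays or [f"a{j+1}" for j in range(arr.shape[1])]
    return CqMatrix(pd.DataFrame(arr, index=samples, columns=assays), roles or {})


@pytest.fixture
def tiny_cq():
    return make_cq(
        [[24.0, 20.0, 30.0, 28.0], [25.0, 21.0, 31.0, 29.0]],
        roles={"a1": "reference", "a2": "hemolysis_marker", "a3": "target", "a4": "target"},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """One study-scale synthetic dataset (84 assays, 10 vs 10) with two
    injected effects, shared across tests that only read it."""
    cfg = SyntheticConfig(
        effects={"synthetic-miR-001": -2.0, "synthetic-miR-002": 1.0}, seed=2024
    )
    return simulate_cq_dataset(cfg)


@pytest.fixture
def groups_10v10():
    ids = [f"case{i+1:02d}" for i in range(10)] + [f"ctrl{i+1:02d}" for i in range(10)]
    return pd.Series(["case"] * 10 + ["control"] * 10, index=ids)
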