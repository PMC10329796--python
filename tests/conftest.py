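import numpy as np
import pytest

from florabias import (
    FamilyCount,
    FloraTable,
    ModelConfig,
    load_reference_counts,
    load_reference_table,
)


@pytest.fixture(scope="session")
def reference_table() -> FloraTable:
    return load_reference_counts()


@pytest.fixture(scope="session")
def reference_frame():
    return load_reference_table()


@pytest.fixture(scope="session")
def default_config() -> ModelConfig:
    return ModelConfig()


def random_flora(rng: np.random.Generator, n_families: int = 30) -> FloraTable:
    """A small random counts table for property tests."""
    counts = []
    for i in range(n_families):
        n = int(rng.integers(1, 2000))
        x = int(rng.binomial(n, rng.uniform(0.0, 0.2)))
        counts.append(FamilyCount(family=f"Fam{i:03d}", n_total=n, x_used=x))
    return FloraTable.from_counts(counts)
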