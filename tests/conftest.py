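import numpy as np
import pytest

from zfqsar.datasets import (
    load_drug_registry,
    load_internal_concentration_table,
    load_k_reference,
)
from zfqsar.descriptors import DescriptorMatrix


@pytest.fixture(scope="session")
def registry():
    return load_drug_registry()


@pytest.fixture(scope="session")
def registry_by_id(registry):
    return {r.drug_id: r for r in registry}


@pytest.fixture(scope="session")
def dose_response_sets():
    return load_internal_concentration_table()


@pytest.fixture(scope="session")
def k_reference():
    return load_k_reference()


def random_design(rng, n, p, prefix="x"):
    """Well-conditioned random descriptor matrix for regression tests."""
    return DescriptorMatrix(
        compound_ids=[f"c{i:03d}" for i in range(n)],
        descriptor_names=[f"{prefix}{j:02d}" for j in range(p)],
        values=rng.standard_normal((n, p)),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
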