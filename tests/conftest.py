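import numpy as np
import pytest

from diaglass import (
    FeatureTable,
    datasets,
    gen_earlystage_like,
    gen_pima_like,
    gen_toy_embeddings,
    gen_toy_kg,
)
from diaglass.preprocessing import zscore_apply, zscore_fit


@pytest.fixture(scope="session")
def toy_kg():
    return gen_toy_kg()


@pytest.fixture(scope="session")
def toy_embeddings():
    return gen_toy_embeddings()


@pytest.fixture(scope="session")
def earlystage():
    return gen_earlystage_like(datasets.default_earlystage_spec())


@pytest.fixture(scope="session")
def earlystage_scaled(earlystage):
    return zscore_apply(earlystage, zscore_fit(earlystage))


@pytest.fixture(scope="session")
def pima():
    return gen_pima_like(datasets.default_pima_spec())


@pytest.fixture()
def tiny_table():
    """3 rows, 2 continuous features, both classes present."""
    return FeatureTable(
        ["a", "b"],
        np.array([[1.0, 10.0], [2.0, 20.0], [3.0, 60.0]]),
        np.array([0, 1, 1]),
        ["continuous", "continuous"],
    )
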