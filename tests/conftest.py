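import numpy as np
import pytest

from gastrumatch import SimSpec, generate_dataset
from gastrumatch.preprocess import lognormalize


@pytest.fixture(scope="session")
def small_spec():
    return SimSpec(
        n_genes=600,
        n_types=3,
        cells_per_type=60,
        n_markers_per_type=30,
        type_effect=2.5,
        doublet_rate=0.05,
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_spec):
    return generate_dataset(small_spec)


@pytest.fixture(scope="session")
def small_norm(small_dataset):
    adata, _ = small_dataset
    return lognormalize(adata)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
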