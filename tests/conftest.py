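import numpy as np
import pytest

from p450nnc import (
    SyntheticSpec,
    generate_qsar,
    train_benchmark_cascade,
)


@pytest.fixture(scope="session")
def benchmark_dataset():
    """The default planted benchmark (600 compounds, 40 descriptors, 5 informative)."""
    return generate_qsar(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def benchmark_model(benchmark_dataset):
    """Cascade trained once on the benchmark's modeling half; shared across tests."""
    return train_benchmark_cascade(benchmark_dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
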