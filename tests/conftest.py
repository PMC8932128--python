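import numpy as np
import pytest

from rhythmrank import SamplingDesign, SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def yeast_design() -> SamplingDesign:
    """Cell-cycle microarray-style grid: 16 min sampling, 94 min period."""
    return SamplingDesign.regular(period=94.0, interval=16.0, duration=254.0)


@pytest.fixture(scope="session")
def circadian_design() -> SamplingDesign:
    """12 samples spanning one 24 h cycle at 2 h resolution."""
    return SamplingDesign.regular(period=24.0, interval=2.0, duration=22.0, unit="h")


@pytest.fixture(scope="session")
def small_sim():
    """A small labeled synthetic transcriptome shared across tests."""
    return simulate_dataset(SimConfig(n_genes=400, n_core=10, n_output=60,
                                      n_tf_extra=40, seed=1234))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
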