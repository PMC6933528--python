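import numpy as np
import pytest

from somnet import ModelParameters, run_simulation


@pytest.fixture(scope="session")
def params() -> ModelParameters:
    """The packaged reference configuration."""
    return ModelParameters()


@pytest.fixture(scope="session")
def short_params(params) -> ModelParameters:
    """A 60 s workload for fast end-to-end tests (coarser grid)."""
    return params.replace(duration=60.0, dt=0.01)


@pytest.fixture(scope="session")
def control_run_24h(params):
    """The noise-free 24 h reference trajectory at dt = 1 ms.

    Integrated on the full 1 ms grid; stored every 100th sample (0.1 s) to
    keep memory bounded.  Shared across the qualitative-cycle and
    periodicity tests (it is deterministic).
    """
    return run_simulation(params, seed=None, store_stride=100)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
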