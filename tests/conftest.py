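import numpy as np
import pytest

from embryolnc.simdata import SimConfig, simulate_all


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(seed=7)


@pytest.fixture(scope="session")
def sim_bundle(sim_config):
    """One full synthetic dataset shared across tests (read-only)."""
    annotation, truth, matrix, sheet, fixture = simulate_all(sim_config)
    return {
        "config": sim_config,
        "annotation": annotation,
        "truth": truth,
        "matrix": matrix,
        "sheet": sheet,
        "fixture": fixture,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
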