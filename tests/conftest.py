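import numpy as np
import pytest

import ewcomm as e
from ewcomm.preprocess import epoch_recording, leakage_correct


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_connectome():
    return e.generate_connectome(6, 0.5, seed=11)


@pytest.fixture(scope="session")
def small_recording(small_connectome):
    cfg = e.SimulationConfig(
        n_regions=6, duration_s=40.0, connection_density=0.5, seed=11
    )
    rec, truth = e.simulate_recording(small_connectome, cfg)
    return rec, truth


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    rec, _ = small_recording
    return np.stack([leakage_correct(x) for x in epoch_recording(rec)])


@pytest.fixture(scope="session")
def small_analysis(small_recording, small_connectome):
    rec, _ = small_recording
    return e.analyze_recording(rec, small_connectome, n_surrogates=25, surrogate_seed=5)
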