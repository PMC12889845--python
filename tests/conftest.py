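import numpy as np
import pytest

from mwcpm import ScenarioConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_sim():
    """One modest simulated dataset from the study design (n=120)."""
    cfg = ScenarioConfig(n=120, beta=0.5, tau=0.5, seed=7)
    data = generate_dataset(cfg, np.random.default_rng(7))
    return data
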