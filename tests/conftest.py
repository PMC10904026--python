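import numpy as np
import pytest

import braincat as bc


@pytest.fixture(scope="session")
def battery10():
    """Full 10-category battery (60 instances)."""
    return bc.generate_stimulus_set(7)


@pytest.fixture(scope="session")
def battery2():
    """Small 2-category battery (12 instances) for protocol tests."""
    return bc.generate_stimulus_set(3, n_categories=2)


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free parameters with a gentle, unit-scale stimulation drive."""
    return bc.ModelParams(noise_amp=0.0, stim_strength=2.0)


@pytest.fixture(scope="session")
def model_a():
    """One untrained instantiation with default parameters."""
    return bc.initialize_model(rng_seed=42)
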