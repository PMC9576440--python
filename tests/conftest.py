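import numpy as np
import pytest
from hypothesis import settings

from ctlungseg import PhantomSpec, generate_phantom_case

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def clean_phantom():
    """Small defect-free phantom: two pristine lungs, no noise."""
    spec = PhantomSpec(
        n_slices=8, slice_size=192, artifact_level=0.0,
        dropout_probability=0.0, noise_sigma=0.0, seed=11,
    )
    return generate_phantom_case(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    """Phantom with default streaks, dropout and noise."""
    return generate_phantom_case(PhantomSpec(n_slices=8, slice_size=192, seed=5))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
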