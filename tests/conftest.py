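import pytest

from coronin.simulate import ErrorModel, SimParams, simulate_family


@pytest.fixture(scope="session")
def noise_free_family():
    """A 20-species family with no planted defects."""
    return simulate_family(SimParams(seed=20, error_model=ErrorModel()))


@pytest.fixture(scope="session")
def noisy_family():
    """A 20-species family with the default defect rates."""
    return simulate_family(SimParams(seed=8))
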