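import pytest

from icpsde import CSFModelParams, DEFAULT_PARAMS


@pytest.fixture(scope="session")
def defaults() -> CSFModelParams:
    """Reference physiological parameter set (E=0.15, R=7, p_b=8, I=1.5, sigma=0.5)."""
    return DEFAULT_PARAMS


@pytest.fixture
def noise_free(defaults) -> CSFModelParams:
    return defaults.replace(sigma=0.0)
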