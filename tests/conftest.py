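import pytest

from sedenz.synth import default_truth


@pytest.fixture
def noiseless_truth():
    """Study-layout truth with sigma_F = 0: every generated value is an
    exact deterministic function of the truth parameters."""
    return default_truth(seed=0, sigma_f=0.0)


@pytest.fixture
def noisy_truth():
    return default_truth(seed=42, sigma_f=20.0)
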