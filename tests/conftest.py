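import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def clean_panicle():
    """One noise-free synthetic panicle shared across tests."""
    from spikescan.synthetic import SyntheticPanicleSpec, generate_panicle

    spec = SyntheticPanicleSpec(seed=7, n_branches=8, target_snpp=100, noise_sd=0.0)
    img, truth = generate_panicle(spec)
    return spec, img, truth


@pytest.fixture(scope="session")
def noisy_panicle():
    """One default-noise synthetic panicle shared across tests."""
    from spikescan.synthetic import SyntheticPanicleSpec, generate_panicle

    spec = SyntheticPanicleSpec(seed=11, n_branches=9, target_snpp=130)
    img, truth = generate_panicle(spec)
    return spec, img, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
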