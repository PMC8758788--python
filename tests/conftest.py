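import warnings

import numpy as np
import pytest

from ladscape.pipeline import analyze_bundle
from ladscape.simulate import SyntheticSpec, generate

warnings.filterwarnings(
    "ignore", message="Precision loss occurred", category=RuntimeWarning
)


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study bundle (noisy negative-binomial counts)."""
    return generate(SyntheticSpec(seed=1))


@pytest.fixture(scope="session")
def results(bundle):
    """Full pipeline analysis of the default bundle (expensive; shared)."""
    return analyze_bundle(bundle)


@pytest.fixture(scope="session")
def bundle_nf():
    """Noise-free variant of the default bundle (deterministic counts)."""
    return generate(SyntheticSpec(seed=1, noise_free=True))


@pytest.fixture(scope="session")
def results_nf(bundle_nf):
    return analyze_bundle(bundle_nf)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
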