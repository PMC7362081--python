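import numpy as np
import pytest

from mfrelease.synthetic import GeneratorConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """Default synthetic panel (noise on), seed 0: (profiles, manifest)."""
    return generate_panel(GeneratorConfig(), seed=0)


@pytest.fixture(scope="session")
def noise_free_panel():
    """Noise-free panel exercising the full protocol-emulation path."""
    cfg = GeneratorConfig(noise_rel=0.0)
    return generate_panel(cfg, seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
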