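import numpy as np
import pytest
from dataclasses import replace

from meltfp import study
from meltfp.synth import make_default_panel


@pytest.fixture(scope="session")
def default_panel():
    return make_default_panel(1)


@pytest.fixture(scope="session")
def noiseless_panel(default_panel):
    """Default panel with every stochastic component switched off."""
    return replace(default_panel, tm_jitter_sd=0.0, noise_sd=0.0,
                   amplitude_jitter_cv=0.0)


@pytest.fixture(scope="session")
def small_panel_factory():
    """Panels restricted to the five reference species, for Monte-Carlo."""
    def make(seed, **overrides):
        p = make_default_panel(seed)
        return replace(p, species=study.REFERENCE_SPECIES, **overrides)
    return make


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
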