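import numpy as np
import pytest
from hypothesis import settings

from simstress.synth import RRModulationSpec, generate_rr

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def constant_rr():
    """A clean constant 800 ms series covering 300 s."""
    series, _ = generate_rr(RRModulationSpec(mean_rr=800.0, duration=300.0, seed=0))
    return series


@pytest.fixture
def lf_modulated_rr():
    """A noise-free series with a single 30 ms LF modulation at 0.095 Hz."""
    spec = RRModulationSpec(amp_lf=30.0, freq_lf=0.095, duration=300.0, seed=0)
    series, truth = generate_rr(spec)
    return series, truth
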