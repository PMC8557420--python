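import numpy as np
import pytest

from admixpulse import PulseParams


@pytest.fixture
def neandertal_pulse() -> PulseParams:
    """t_m = 1500, t_d = 1000 (k = 36): the canonical old-pulse scenario."""
    return PulseParams.from_duration(1500.0, 1000.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_210_901)
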