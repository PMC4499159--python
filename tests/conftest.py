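import numpy as np
import pytest

from berquant import SyntheticConfig, generate_titration


@pytest.fixture
def noiseless_curve():
    """Noise-free titration at a representative ground truth."""
    cfg = SyntheticConfig(ec50=84.0, hill_n=1.8, f0=100.0, fold_change=2.8, cv=0.0)
    curve, truth = generate_titration(cfg)
    return curve, truth


@pytest.fixture
def rng():
    return np.random.default_rng(20150526)
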