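import numpy as np
import pytest

from popinfo import sample_population


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def small_population():
    return sample_population(12, np.random.default_rng(42))


def random_psd(rng, n, cond_floor=0.05):
    """Well-conditioned random PSD matrix (shared test helper)."""
    g = rng.standard_normal((n, n))
    return g @ g.T / n + cond_floor * np.eye(n)
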