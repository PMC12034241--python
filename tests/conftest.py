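import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_symmetric(rng: np.random.Generator, n: int,
                     density: float = 1.0) -> np.ndarray:
    """Random symmetric non-negative matrix (optionally sparsified)."""
    m = rng.uniform(0.1, 2.0, (n, n))
    if density < 1.0:
        mask = rng.random((n, n)) < density
        m = m * mask
    m = np.triu(m)
    return m + np.triu(m, 1).T
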