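import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def unit_square():
    """Corners of the unit square in the z=0 plane: one H1 loop."""
    return np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0]], dtype=float)


@pytest.fixture
def circle12():
    """12 equally spaced points on the unit circle."""
    th = 2 * np.pi * np.arange(12) / 12
    return np.column_stack([np.cos(th), np.sin(th), np.zeros(12)])


def random_diagram(rng, n_max=10):
    """Random finite persistence diagram as an (n, 2) array."""
    n = int(rng.integers(0, n_max + 1))
    birth = rng.uniform(0, 5, n)
    death = birth + rng.uniform(0, 5, n)
    return np.column_stack([birth, death]) if n else np.empty((0, 2))
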