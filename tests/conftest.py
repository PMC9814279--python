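import numpy as np
import pytest

from qfric import LatticeSpec, build_hexagonal, build_square


@pytest.fixture
def square_surface():
    """4x4 checkerboard square lattice at q = 0.1 e (1.0 x 1.0 nm cell)."""
    return build_square(LatticeSpec("square", 4, 4, q=0.1))


@pytest.fixture
def hex_surface():
    """2x2 para-decorated honeycomb at q = 0.2 e."""
    return build_hexagonal(LatticeSpec("hexagonal", 2, 2, q=0.2))


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)
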