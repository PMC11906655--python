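import numpy as np
import pytest

from trapwalk import ResponseProfile, TrapArena


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def circle_arena():
    """The small circular-field demonstration arena: radius 25, trap radius 5."""
    return TrapArena("circle", extent=25.0, trap_radius=5.0)


@pytest.fixture
def square_arena():
    """The main experiment arena: square of side 50, trap radius 5."""
    return TrapArena("square", extent=50.0, trap_radius=5.0)


@pytest.fixture
def constant_profile():
    """Constant-response baseline: r = 0.5, s = 1."""
    return ResponseProfile(0.5, 1.0)
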