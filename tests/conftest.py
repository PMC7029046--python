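import numpy as np
import pytest

from bedplane.geometry import Window
from bedplane.pattern_core import PointPattern


@pytest.fixture
def unit_square():
    return Window.rectangle(0.0, 0.0, 1.0, 1.0)


@pytest.fixture
def square10():
    return Window.rectangle(0.0, 0.0, 10.0, 10.0)


@pytest.fixture
def holed_square():
    """2x2 square with a centred 1x1 hole (area 3)."""
    return Window(
        [(0, 0), (2, 0), (2, 2), (0, 2)],
        holes=[[(0.5, 0.5), (1.5, 0.5), (1.5, 1.5), (0.5, 1.5)]],
        raster_size=512,
    )


@pytest.fixture
def l_shaped():
    """Concave hexagonal window with one rectangular hole."""
    return Window(
        [(0, 0), (4, 0), (4, 2), (2, 2), (2, 4), (0, 4)],
        holes=[[(0.5, 0.5), (1.5, 0.5), (1.5, 1.2), (0.5, 1.2)]],
        raster_size=512,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)


@pytest.fixture
def csr_pattern(square10, rng):
    """~100-point uniform pattern on the 10x10 window."""
    return PointPattern(square10, square10.uniform_points(100, rng))
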