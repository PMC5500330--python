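import numpy as np
import pytest

from peptfpi import CLStream, GridSpec, ScannerModel


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def scanner():
    return ScannerModel()


@pytest.fixture
def fov_grid():
    """Default 2 mm grid covering the Inveon-like FOV."""
    return GridSpec.from_cylinder(80.5, 63.5, 2.0)


def random_stream(rng, n=1000, t_max_ms=300_000, extent=80.0):
    """Random but valid CL stream for round-trip and windowing tests."""
    t = rng.integers(0, t_max_ms, size=n)
    p1 = rng.uniform(-extent, extent, size=(n, 3))
    p2 = rng.uniform(-extent, extent, size=(n, 3))
    return CLStream.from_arrays(t, p1, p2)


@pytest.fixture
def make_random_stream(rng):
    return lambda **kw: random_stream(rng, **kw)
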